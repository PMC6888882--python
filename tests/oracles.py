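"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def profile_oracle(strings, d_max, trim):
    """Naive double loop over (center, partner) ordered pairs.

    For every substitution inside the trimmed region and every offset +-d
    whose partner also lies inside the trimmed region, tally the partner's
    symbol.  Alignments shorter than 2*trim + 2 contribute nothing.
    """
    n1 = np.zeros(d_max, dtype=np.int64)
    n0 = np.zeros(d_max, dtype=np.int64)
    for x in strings:
        x = list(x)
        n = len(x)
        if n < 2 * trim + 2:
            continue
        for i in range(trim, n - trim):
            if x[i] != 1:
                continue
            for d in range(1, d_max + 1):
                for j in (i - d, i + d):
                    if trim <= j < n - trim:
                        if x[j] == 1:
                            n1[d - 1] += 1
                        else:
                            n0[d - 1] += 1
    return n1, n0


def avalanche_oracle(events, contact, time_window, self_links):
    """Partition events by transitive closure of the link relation."""
    n = len(events)
    adj = [[False] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            i, t = events[a]
            j, u = events[b]
            spatial = bool(contact[i][j]) or (self_links and i == j)
            if spatial and abs(t - u) <= time_window:
                adj[a][b] = True
    # transitive closure (Floyd-Warshall style reachability)
    reach = [row[:] for row in adj]
    for a in range(n):
        reach[a][a] = True
    for k in range(n):
        for a in range(n):
            if reach[a][k]:
                for b in range(n):
                    if reach[k][b]:
                        reach[a][b] = True
    components = []
    assigned = [False] * n
    for a in range(n):
        if assigned[a]:
            continue
        comp = {b for b in range(n) if reach[a][b]}
        for b in comp:
            assigned[b] = True
        components.append(frozenset((events[b][0], events[b][1]) for b in comp))
    return set(components)
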