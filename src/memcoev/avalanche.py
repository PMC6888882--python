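"""Spatio-temporal substitution avalanches.

A time-series of equal-length sequences (e.g. yearly consensus sequences of a
viral protein, or binned simulation output) is reduced to a binary mutation
matrix m[i, t].  The substitution events (i, t) with m = 1 become nodes of an
undirected graph: two events are linked when their sites are in structural
contact (optionally also when they are the *same* site) and their times
differ by at most ``time_window`` units.  An avalanche is a connected
component of that graph; components of size <= 2 are classified as minor.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .contact_model import ContactMap
from .errors import InvalidInputError

#: Events whose times differ by at most this many units may be linked.
DEFAULT_TIME_WINDOW = 2
#: Components with more than this many events are avalanches; smaller are minor.
MINOR_MAX_SIZE = 2
#: Default number of time bins when discretizing simulated trajectories
#: (comparable to the 33 yearly consensus sequences of the influenza series).
DEFAULT_N_TIME_BINS = 33


@dataclass(frozen=True)
class MutationMatrix:
    """Binary matrix m[i, t]: site i changed during transition/bin t."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 2:
            raise InvalidInputError("mutation matrix must be 2-D (sites x times)")
        if ((v != 0) & (v != 1)).any():
            raise InvalidInputError("mutation matrix entries must be 0 or 1")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def events(self) -> np.ndarray:
        """Array of (site, time) pairs with m = 1, in row-major order."""
        ii, tt = np.nonzero(self.values)
        return np.column_stack([ii, tt])


@dataclass(frozen=True)
class AvalanchePartition:
    """Connected-component labels over substitution events.

    ``labels[j]`` is the component of ``events[j]``; ``sizes[c]`` the number
    of events in component c; an event belongs to an avalanche when its
    component has >= 3 events, otherwise to a minor cluster.
    """

    events: np.ndarray
    labels: np.ndarray
    sizes: np.ndarray

    @property
    def n_components(self) -> int:
        return self.sizes.shape[0]

    def component_members(self, c: int) -> np.ndarray:
        return self.events[self.labels == c]

    def classification(self) -> np.ndarray:
        """Per-event label: 'avalanche' or 'minor'."""
        return np.where(self.sizes[self.labels] > MINOR_MAX_SIZE, "avalanche", "minor")

    def as_sets(self) -> set[frozenset]:
        """Partition as a set of frozensets of (site, time) tuples."""
        out: dict[int, set] = {}
        for (i, t), c in zip(self.events, self.labels):
            out.setdefault(int(c), set()).add((int(i), int(t)))
        return {frozenset(v) for v in out.values()}


def consensus_sequence(sequences: Sequence[str]) -> str:
    """Position-wise most common residue; ties broken lexicographically."""
    seqs = list(sequences)
    if not seqs:
        raise InvalidInputError("no sequences given")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise InvalidInputError("sequences must have equal length")
    out = []
    for pos in range(n):
        counts = Counter(s[pos] for s in seqs)
        best = max(counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
        out.append(best[0])
    return "".join(out)


def mutation_matrix_from_series(series: Sequence[str]) -> MutationMatrix:
    """Mutation matrix from a time-ordered series of equal-length sequences.

    m[i, t] = 1 iff the sequence at time t+1 differs from the one at time t
    at site i; a series of T sequences yields T-1 transitions.
    """
    seqs = list(series)
    if len(seqs) < 2:
        raise InvalidInputError("need at least two time points")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise InvalidInputError("sequences must have equal length")
    m = np.zeros((n, len(seqs) - 1), dtype=np.uint8)
    for t in range(len(seqs) - 1):
        a, b = seqs[t], seqs[t + 1]
        for i in range(n):
            if a[i] != b[i]:
                m[i, t] = 1
    return MutationMatrix(m)


def mutation_matrix_from_events(events: Iterable, L: int, total_time: float,
                                n_bins: int = DEFAULT_N_TIME_BINS) -> MutationMatrix:
    """Discretize simulated substitution events into time bins.

    ``events`` yields objects with ``site`` and ``time`` attributes (or
    (site, time) pairs); times in [0, total_time] map onto ``n_bins`` equal
    bins, the right edge inclusive in the last bin.
    """
    if n_bins < 1 or total_time <= 0:
        raise InvalidInputError("need n_bins >= 1 and total_time > 0")
    m = np.zeros((L, n_bins), dtype=np.uint8)
    for ev in events:
        site, time = (ev.site, ev.time) if hasattr(ev, "site") else (ev[0], ev[1])
        b = min(int(time / total_time * n_bins), n_bins - 1)
        if not (0 <= site < L):
            raise InvalidInputError(f"event site {site} out of range for L={L}")
        m[site, b] = 1
    return MutationMatrix(m)


def detect_avalanches(m: MutationMatrix, cmap: ContactMap,
                      time_window: int = DEFAULT_TIME_WINDOW,
                      self_links: bool = True) -> AvalanchePartition:
    """Partition substitution events into avalanches.

    Events (i, t) and (j, t') are linked iff |t - t'| <= time_window and
    either contact(i, j) = 1 or (``self_links`` and i = j).  Components are
    found on the sparse event graph.
    """
    if cmap.L != m.n_sites:
        raise InvalidInputError(
            f"contact map length {cmap.L} != mutation matrix sites {m.n_sites}"
        )
    if time_window < 0:
        raise InvalidInputError("time_window must be non-negative")
    ev = m.events()
    n = ev.shape[0]
    if n == 0:
        return AvalanchePartition(events=ev, labels=np.zeros(0, dtype=int),
                                  sizes=np.zeros(0, dtype=int))
    sites, times = ev[:, 0], ev[:, 1]
    close = np.abs(times[:, None] - times[None, :]) <= time_window
    linked = cmap.matrix[np.ix_(sites, sites)]
    if self_links:
        linked = linked | (sites[:, None] == sites[None, :])
    adj = close & linked
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return AvalanchePartition(events=ev, labels=labels, sizes=np.bincount(labels))


def pad_unmapped_sites(cmap: ContactMap, unmapped: Iterable[int]) -> ContactMap:
    """Connect structurally unmapped sites to their along-chain neighbors.

    Alignment columns with no residue in the reference structure get contacts
    to positions i-1 and i+1 (within bounds) so they can still join
    avalanches through the chain.
    """
    unmapped = sorted(set(int(i) for i in unmapped))
    if any(i < 0 or i >= cmap.L for i in unmapped):
        raise InvalidInputError("unmapped sites must lie in [0, L)")
    m = cmap.matrix.copy()
    for i in unmapped:
        for j in (i - 1, i + 1):
            if 0 <= j < cmap.L:
                m[i, j] = m[j, i] = True
    return ContactMap(m)
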