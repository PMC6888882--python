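"""Two-branch divergence simulations from a common equilibrated ancestor.

Two chains inherit the same equilibrated last-mutation times, split at time
zero, and then evolve independently (no cross-branch coupling).  Sequence
identity of a measured window is the fraction of window sites never
substituted in either branch — a lower bound, since back and convergent
mutations are ignored.  Ensembles of such runs, binned by identity, feed the
alignment statistics and the parameter fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .contact_model import ContactMap, SiteClasses
from .errors import InvalidInputError
from .rate_dynamics import ChainState, Params, SimulationConfig, equilibrate, step

logger = logging.getLogger(__name__)

#: Stand-in sequence-length distribution (uniform, inclusive bounds) used when
#: no empirical length distribution is supplied.
DEFAULT_LENGTH_RANGE = (80, 300)

#: The four identity windows analyzed throughout: 60-62%, 70-72%, 80-82%, 90-92%.
DEFAULT_IDENTITY_BINS = ((0.60, 0.62), (0.70, 0.72), (0.80, 0.82), (0.90, 0.92))


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: str  # "A" or "B"
    site: int
    time: float  # memory-time units since the split


@dataclass
class DivergenceResult:
    """Outcome of one two-branch run.

    ``counts_a``/``counts_b`` are per-site substitution counts over the whole
    chain; ``mutated`` marks sites substituted in at least one branch;
    ``identity`` is measured on ``window`` only.  ``reached_target`` is False
    when the run hit ``max_time`` first.
    """

    events: list[SubstitutionEvent]
    counts_a: np.ndarray
    counts_b: np.ndarray
    mutated: np.ndarray
    identity: float
    window: tuple[int, int]
    seed: int | None
    reached_target: bool
    n_steps: int
    multi_substitution_steps: int
    identity_trajectory: list[tuple[float, float]]

    @property
    def alignment(self) -> np.ndarray:
        """Binary branch-vs-branch alignment over the window (1 = substitution)."""
        start, length = self.window
        return self.mutated[start:start + length].astype(np.uint8)

    @property
    def multi_substitution_fraction(self) -> float:
        """Fraction of time steps with >= 2 substitutions (both branches pooled)."""
        return self.multi_substitution_steps / self.n_steps if self.n_steps else 0.0

    def window_counts(self, branch: str) -> np.ndarray:
        start, length = self.window
        counts = self.counts_a if branch == "A" else self.counts_b
        return counts[start:start + length]


def _evolve_pair(
    cmap: ContactMap,
    params: Params,
    config: SimulationConfig,
    ancestor: ChainState,
    window: tuple[int, int],
    checkpoints: Sequence[float],
    rng_a: np.random.Generator,
    rng_b: np.random.Generator,
    classes: SiteClasses | None = None,
    record_events: bool = True,
):
    """Lock-step evolution of both branches down to the lowest checkpoint.

    ``checkpoints`` must be identity values sorted in decreasing order; a
    snapshot (window alignment + per-branch window counts) is captured at the
    first step whose window identity is <= each checkpoint.
    """
    start, length = window
    state_a = ancestor.copy()
    state_b = ancestor.copy()
    mutated = np.zeros(cmap.L, dtype=bool)
    n_mut_window = 0
    identity = 1.0
    trajectory = [(0.0, 1.0)]
    events: list[SubstitutionEvent] = []
    snapshots: dict[float, dict] = {}
    pending = list(checkpoints)
    n_steps = 0
    multi = 0

    while pending and state_a.time < config.max_time:
        hits_a = step(state_a, cmap, params, config, rng_a, classes)
        hits_b = step(state_b, cmap, params, config, rng_b, classes)
        n_steps += 1
        if hits_a.size + hits_b.size >= 2:
            multi += 1
        if record_events:
            t = state_a.time
            events.extend(SubstitutionEvent("A", int(s), t) for s in hits_a)
            events.extend(SubstitutionEvent("B", int(s), t) for s in hits_b)
        changed = False
        for hits in (hits_a, hits_b):
            if hits.size:
                new = hits[~mutated[hits]]
                if new.size:
                    mutated[new] = True
                    n_mut_window += int(((new >= start) & (new < start + length)).sum())
                    changed = True
        if changed:
            identity = 1.0 - n_mut_window / length
            trajectory.append((state_a.time, identity))
            while pending and identity <= pending[0]:
                cp = pending.pop(0)
                snapshots[cp] = {
                    "alignment": mutated[start:start + length].astype(np.uint8),
                    "counts_a": state_a.counts[start:start + length].copy(),
                    "counts_b": state_b.counts[start:start + length].copy(),
                    "chain_counts_a": state_a.counts.copy(),
                    "chain_counts_b": state_b.counts.copy(),
                    "identity": identity,
                    "time": state_a.time,
                }
    return {
        "snapshots": snapshots,
        "state_a": state_a,
        "state_b": state_b,
        "mutated": mutated,
        "identity": identity,
        "events": events,
        "trajectory": trajectory,
        "n_steps": n_steps,
        "multi": multi,
        "reached": not pending,
    }


def simulate_divergence(
    cmap: ContactMap,
    params: Params,
    config: SimulationConfig,
    target_identity: float,
    window: tuple[int, int] | None = None,
    classes: SiteClasses | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> DivergenceResult:
    """Equilibrate an ancestor, split, and evolve until the window identity
    first drops to ``target_identity`` (or ``max_time``, flagged).

    ``window`` defaults to the whole chain.  ``seed`` overrides
    ``config.seed``; three independent streams are derived from it
    (equilibration, branch A, branch B).
    """
    if not (0.0 < target_identity < 1.0):
        raise InvalidInputError("target_identity must be in (0, 1)")
    if window is None:
        window = (0, cmap.L)
    start, length = window
    if length < 1 or start < 0 or start + length > cmap.L:
        raise InvalidInputError(f"window {window} out of range for L={cmap.L}")

    if seed is None:
        seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_eq, rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(3))

    ancestor = equilibrate(cmap, params, config, rng_eq, classes)
    out = _evolve_pair(cmap, params, config, ancestor, window,
                       [target_identity], rng_a, rng_b, classes)
    return DivergenceResult(
        events=out["events"],
        counts_a=out["state_a"].counts,
        counts_b=out["state_b"].counts,
        mutated=out["mutated"],
        identity=out["identity"],
        window=window,
        seed=seed if isinstance(seed, int) else None,
        reached_target=out["reached"],
        n_steps=out["n_steps"],
        multi_substitution_steps=out["multi"],
        identity_trajectory=out["trajectory"],
    )


@dataclass
class EnsembleBin:
    """Pooled per-bin results of an ensemble: one entry per crossing replicate.

    ``counts`` holds per-site substitution counts over the measured window
    (branch A then branch B per replicate); ``chain_counts`` the same over
    the whole evolved chain.  Identity is controlled on the window only, so
    chain counts are the less stopping-conditioned sample for among-site
    rate-variability statistics.
    """

    bin: tuple[float, float]
    alignments: list[np.ndarray] = field(default_factory=list)
    counts: list[np.ndarray] = field(default_factory=list)  # A then B per replicate
    chain_counts: list[np.ndarray] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    n_replicates: int = 0

    def pooled_counts(self, chain: bool = False) -> np.ndarray:
        src = self.chain_counts if chain else self.counts
        if not src:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(src)


def run_ensemble(
    map_source: Sequence[tuple[ContactMap, SiteClasses | None]],
    lengths: Sequence[int],
    params: Params,
    config: SimulationConfig,
    identity_bins: Sequence[tuple[float, float]] = DEFAULT_IDENTITY_BINS,
    n_reps: int = 10,
    seed: int | None = 0,
    length_weights: Sequence[float] | None = None,
) -> Mapping[tuple[float, float], EnsembleBin]:
    """Ensemble of divergence runs pooled per identity bin.

    For each replicate a length is drawn from ``lengths`` (optionally
    weighted), a sufficiently long map is drawn, a window is placed uniformly
    at random, and the pair is evolved past the deepest bin; the state is
    snapshotted as the window identity first crosses each bin's midpoint
    (the stand-in for stopping "at the average identity of the corresponding
    alignment set").  Replicates with no long-enough map are skipped with a
    warning.  Deterministic given ``seed``.
    """
    bins = [tuple(b) for b in identity_bins]
    for lo, hi in bins:
        if not (0.0 < lo < hi < 1.0):
            raise InvalidInputError(f"bad identity bin ({lo}, {hi})")
    for (lo1, hi1), (lo2, hi2) in zip(sorted(bins), sorted(bins)[1:]):
        if hi1 > lo2:
            raise InvalidInputError("identity bins overlap")
    bins_desc = sorted(bins, key=lambda b: -(b[0] + b[1]))
    checkpoints = [(lo + hi) / 2.0 for lo, hi in bins_desc]

    out = {b: EnsembleBin(bin=b) for b in bins}
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_reps + 1)
    master = np.random.default_rng(children[0])

    for rep in range(n_reps):
        length = int(master.choice(np.asarray(lengths), p=length_weights))
        eligible = [j for j, (m, _) in enumerate(map_source) if m.L >= length]
        rng_eq, rng_a, rng_b = (np.random.default_rng(s) for s in children[rep + 1].spawn(3))
        if not eligible:
            warnings.warn(f"replicate {rep}: no contact map of length >= {length}; skipped")
            continue
        cmap, classes = map_source[eligible[int(master.integers(len(eligible)))]]
        start = int(master.integers(0, cmap.L - length + 1))
        window = (start, length)
        ancestor = equilibrate(cmap, params, config, rng_eq, classes)
        res = _evolve_pair(cmap, params, config, ancestor, window, checkpoints,
                           rng_a, rng_b, classes, record_events=False)
        for b, cp in zip(bins_desc, checkpoints):
            snap = res["snapshots"].get(cp)
            if snap is None:
                continue
            eb = out[b]
            eb.alignments.append(snap["alignment"])
            eb.counts.append(snap["counts_a"])
            eb.counts.append(snap["counts_b"])
            eb.chain_counts.append(snap["chain_counts_a"])
            eb.chain_counts.append(snap["chain_counts_b"])
            eb.identities.append(snap["identity"])
            eb.times.append(snap["time"])
            eb.n_replicates += 1
        logger.info("replicate %d: L=%d window=%s bins reached=%d",
                    rep, length, window, len(res["snapshots"]))
    return out
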