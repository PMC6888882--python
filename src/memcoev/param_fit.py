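"""Fitting (J, r0) by RMSD between conditional substitution profiles.

The coupling J and baseline rate r0 (or, for the two-class model, the shared
J and the unstructured baseline) are chosen to minimize the root-mean-square
displacement between the model's conditional profiles P(d) and reference
profiles, jointly over the analyzed identity bins and restricted to chain
distances d below ``d_max``.  The objective is evaluated by re-simulating the
divergence ensemble at each candidate point under common random numbers
(identical seed streams at every point), which removes most Monte-Carlo
noise from the comparison; a coarse log-grid search is followed by a
derivative-free Nelder-Mead refinement on log-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .alignment_stats import DEFAULT_D_MAX, DEFAULT_TRIM, ConditionalProfile, conditional_profile
from .contact_model import ContactMap, SiteClasses
from .divergence_sim import run_ensemble
from .errors import FitFailureError, InvalidInputError
from .rate_dynamics import ModelParams, SimulationConfig, TwoClassParams

#: Search bounds (J, then r0), log-spaced grid defaults.
DEFAULT_BOUNDS = ((1e-3, 1.0), (1e-5, 1e-1))
#: Objective value charged when a candidate point fails to populate a bin
#: within max_time (dominates any attainable profile RMSD, which is <= 1).
UNREACHED_PENALTY = 10.0


@dataclass(frozen=True)
class FitObjectiveSpec:
    """Everything an objective evaluation needs, seeds included."""

    identity_bins: tuple[tuple[float, float], ...]
    reference: Mapping[tuple[float, float], ConditionalProfile]
    map_source: Sequence[tuple[ContactMap, SiteClasses | None]]
    lengths: Sequence[int]
    n_reps: int
    config: SimulationConfig
    d_max: int = DEFAULT_D_MAX
    trim: int = DEFAULT_TRIM
    seed: int = 0


@dataclass
class FitResult:
    J: float
    r0: float
    objective: float
    model_family: str
    trace: list[tuple[float, float, float]] = field(default_factory=list)


def profile_rmsd(model, reference, d_max: int = DEFAULT_D_MAX) -> float:
    """RMSD between profiles over all (bin, d) cells with d = 1..d_max-1.

    ``model`` and ``reference`` are mappings bin -> ConditionalProfile (a
    single profile pair is also accepted).  Any NaN cell in the required
    range is an error: an undefined P(d) must not silently enter the fit.
    """
    if isinstance(model, ConditionalProfile):
        model = {None: model}
    if isinstance(reference, ConditionalProfile):
        reference = {None: reference}
    if set(model) != set(reference):
        raise InvalidInputError("model and reference must cover the same bins")
    sq = []
    for b in reference:
        pm, pr = model[b].p, reference[b].p
        if pm.shape[0] < d_max - 1 or pr.shape[0] < d_max - 1:
            raise InvalidInputError(f"profiles must define P(d) up to d={d_max - 1}")
        pm, pr = pm[: d_max - 1], pr[: d_max - 1]
        if np.isnan(pm).any() or np.isnan(pr).any():
            raise InvalidInputError(f"undefined P(d) in bin {b}")
        sq.append((pm - pr) ** 2)
    return float(np.sqrt(np.concatenate(sq).mean()))


def ensemble_profiles(
    map_source,
    lengths,
    params,
    config: SimulationConfig,
    identity_bins,
    n_reps: int,
    seed: int,
    d_max: int = DEFAULT_D_MAX,
    trim: int = DEFAULT_TRIM,
) -> dict[tuple[float, float], ConditionalProfile]:
    """Run an ensemble and return one pooled profile per populated bin."""
    ens = run_ensemble(map_source, lengths, params, config, identity_bins,
                       n_reps=n_reps, seed=seed)
    return {
        b: conditional_profile(eb.alignments, d_max=d_max, trim=trim)
        for b, eb in ens.items()
        if eb.alignments
    }


def _make_params(model_family: str, J: float, r0: float):
    if model_family == "one-class":
        return ModelParams(r0=r0, J=J)
    if model_family == "two-class":
        return TwoClassParams(r0_unstructured=r0, J=J)
    raise InvalidInputError(f"unknown model family {model_family!r}")


def optimize_params(
    spec: FitObjectiveSpec,
    model_family: str = "one-class",
    bounds=DEFAULT_BOUNDS,
    grid_shape: tuple[int, int] | None = (5, 5),
    simplex_maxfev: int = 40,
    start: tuple[float, float] | None = None,
) -> FitResult:
    """Coarse log-grid search then Nelder-Mead refinement of (J, r0).

    Every objective evaluation re-runs the ensemble with ``spec.seed`` as the
    common-random-numbers seed, so repeated evaluation at a point is
    bit-identical.  A point whose ensemble fails to populate some bin is
    charged ``UNREACHED_PENALTY``.  With ``grid_shape=None`` and
    ``simplex_maxfev=0`` only ``start`` is evaluated (degenerate budget).
    """
    (j_lo, j_hi), (r_lo, r_hi) = bounds
    trace: list[tuple[float, float, float]] = []

    def evaluate(J: float, r0: float) -> float:
        params = _make_params(model_family, J, r0)
        try:
            profiles = ensemble_profiles(
                spec.map_source, spec.lengths, params, spec.config,
                spec.identity_bins, spec.n_reps, spec.seed,
                d_max=spec.d_max, trim=spec.trim,
            )
            missing = [b for b in spec.identity_bins if tuple(b) not in profiles]
            if missing:
                obj = UNREACHED_PENALTY
            else:
                obj = profile_rmsd(
                    {tuple(b): profiles[tuple(b)] for b in spec.identity_bins},
                    {tuple(b): spec.reference[tuple(b)] for b in spec.identity_bins},
                    spec.d_max,
                )
        except InvalidInputError:
            obj = UNREACHED_PENALTY
        trace.append((float(J), float(r0), float(obj)))
        return obj

    candidates: list[tuple[float, float]] = []
    if start is not None:
        candidates.append(tuple(start))
    if grid_shape is not None:
        n_j, n_r = grid_shape
        for J in np.logspace(np.log10(j_lo), np.log10(j_hi), n_j):
            for r0 in np.logspace(np.log10(r_lo), np.log10(r_hi), n_r):
                candidates.append((float(J), float(r0)))
    if not candidates:
        raise FitFailureError("no candidate points: provide a grid or a start point")

    best = None
    for J, r0 in candidates:
        obj = evaluate(J, r0)
        if best is None or obj < best[2]:
            best = (J, r0, obj)

    if simplex_maxfev > 0:
        lb = np.log10([j_lo, r_lo])
        ub = np.log10([j_hi, r_hi])

        def fun(x):
            xc = np.clip(x, lb, ub)
            return evaluate(10.0 ** xc[0], 10.0 ** xc[1])

        x0 = np.log10([best[0], best[1]])
        minimize(fun, x0, method="Nelder-Mead",
                 options={"maxfev": simplex_maxfev, "xatol": 1e-3,
                          "fatol": 1e-12, "initial_simplex": np.array([
                              x0, x0 + [0.25, 0.0], x0 + [0.0, 0.25]])})
        best = min(trace, key=lambda t: t[2])

    return FitResult(J=best[0], r0=best[1], objective=best[2],
                     model_family=model_family, trace=trace)
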