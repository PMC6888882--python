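"""Alignment-level statistics of substitution patterns.

Pairwise alignments are reduced to binary strings (0 = persistence, 1 =
substitution).  From pools of such strings this module computes

* the along-chain conditional substitution profile
  P(d) = N1(d) / (N0(d) + N1(d)), where N1(d)/N0(d) count substitutions and
  persistences observed at chain distance d from a substitution;
* the histogram of substitutions per site and its weighted least-squares fit
  to a negative binomial p(k | alpha, <k>), the distribution implied by
  Gamma-mixed Poisson rates, with the mean constrained to the data and only
  the shape parameter alpha free;
* the overlap ratio (sites hit >= 2 times over sites hit >= 1 time), a
  summary of molecular-clock overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .errors import FitFailureError, InvalidInputError, UndefinedResultError

#: Residues trimmed from each end of every alignment (boundary effects).
DEFAULT_TRIM = 5
#: Largest along-chain distance used in profile fits ("d shorter than 30").
DEFAULT_D_MAX = 30

_LOG_ALPHA_BOUNDS = (np.log(1e-3), np.log(1e6))


@dataclass(frozen=True)
class BinaryAlignment:
    """A pairwise alignment encoded as 0/1 symbols plus its identity."""

    symbols: np.ndarray
    identity: float
    source: str = ""

    def __post_init__(self):
        arr = np.asarray(self.symbols, dtype=np.uint8)
        if arr.ndim != 1:
            raise InvalidInputError("symbols must be one-dimensional")
        if ((arr != 0) & (arr != 1)).any():
            raise InvalidInputError("symbols must be 0 or 1")
        arr.setflags(write=False)
        object.__setattr__(self, "symbols", arr)

    def __len__(self) -> int:
        return self.symbols.shape[0]


def binarize_alignment(seq_a: str, seq_b: str, source: str = "") -> BinaryAlignment:
    """Translate an ungapped pairwise alignment into 0/1 symbols.

    0 where the paired residues are identical, 1 otherwise; identity is the
    fraction of 0s.  Gap characters are rejected: only ungapped blocks are
    analyzed.
    """
    if len(seq_a) != len(seq_b):
        raise InvalidInputError("aligned sequences must have equal length")
    if len(seq_a) == 0:
        raise InvalidInputError("empty alignment")
    if "-" in seq_a or "-" in seq_b or "." in seq_a or "." in seq_b:
        raise InvalidInputError("gap characters are not allowed (ungapped blocks only)")
    symbols = np.array([0 if a == b else 1 for a, b in zip(seq_a, seq_b)], dtype=np.uint8)
    return BinaryAlignment(symbols, identity=1.0 - symbols.mean(), source=source)


@dataclass(frozen=True)
class ConditionalProfile:
    """Counts and ratio per along-chain distance d = 1..d_max.

    ``p`` is NaN where no pair was observed (undefined, never silently 0).
    """

    d: np.ndarray
    n1: np.ndarray
    n0: np.ndarray
    trim: int

    @property
    def p(self) -> np.ndarray:
        tot = self.n0 + self.n1
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, self.n1 / np.where(tot > 0, tot, 1), np.nan)

    @property
    def d_max(self) -> int:
        return int(self.d[-1])


def _symbols_of(a) -> np.ndarray:
    if isinstance(a, BinaryAlignment):
        return a.symbols
    arr = np.asarray(a, dtype=np.uint8)
    if arr.ndim != 1 or ((arr != 0) & (arr != 1)).any():
        raise InvalidInputError("alignments must be 1-D arrays of 0/1 symbols")
    return arr


def conditional_profile(alignments: Iterable, d_max: int = DEFAULT_D_MAX,
                        trim: int = DEFAULT_TRIM) -> ConditionalProfile:
    """Pooled conditional substitution profile over a set of alignments.

    For every substitution at a trimmed-region position i and every offset
    ±d with the partner position also inside the trimmed region, the
    partner's symbol increments N1(d) or N0(d).  Ordered pairs are counted in
    both directions; the ratio P(d) is invariant under that convention.
    Alignments shorter than 2*trim + 2 cannot contribute and are skipped; if
    none is long enough an error is raised.
    """
    if d_max < 1:
        raise InvalidInputError("d_max must be >= 1")
    if trim < 0:
        raise InvalidInputError("trim must be non-negative")
    n1 = np.zeros(d_max, dtype=np.int64)
    n0 = np.zeros(d_max, dtype=np.int64)
    used = 0
    for a in alignments:
        x = _symbols_of(a)
        n = x.shape[0]
        if n < 2 * trim + 2:
            continue
        used += 1
        xt = x[trim:n - trim].astype(np.int64)
        m = xt.shape[0]
        for d in range(1, min(d_max, m - 1) + 1):
            left, right = xt[:-d], xt[d:]
            both = int((left & right).sum())
            n1[d - 1] += 2 * both
            n0[d - 1] += int(left.sum()) + int(right.sum()) - 2 * both
    if used == 0:
        raise InvalidInputError(
            f"no alignment longer than the trimmed minimum 2*trim+1 = {2 * trim + 1}"
        )
    return ConditionalProfile(d=np.arange(1, d_max + 1), n1=n1, n0=n0, trim=trim)


@dataclass(frozen=True)
class Histogram:
    """Tally of substitutions per site: ``n_k[k]`` sites with k substitutions."""

    n_k: np.ndarray

    @property
    def n_sites(self) -> float:
        return float(self.n_k.sum())

    @property
    def freqs(self) -> np.ndarray:
        return self.n_k / self.n_k.sum()

    @property
    def mean_k(self) -> float:
        ks = np.arange(self.n_k.shape[0])
        return float((ks * self.n_k).sum() / self.n_k.sum())


def substitution_histogram(counts) -> Histogram:
    """Histogram of per-site substitution counts (all branches pooled).

    Accepts one array of counts or an iterable of arrays (concatenated).
    """
    if not isinstance(counts, np.ndarray):
        parts = [np.atleast_1d(np.asarray(c)) for c in counts]
        counts = np.concatenate(parts) if parts else np.asarray([])
    counts = np.asarray(counts)
    if counts.size == 0:
        raise InvalidInputError("empty input: no per-site counts")
    if counts.ndim != 1:
        counts = counts.ravel()
    if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
        counts_int = counts.astype(np.int64)
        if (counts_int < 0).any() or not np.allclose(counts, counts_int):
            raise InvalidInputError("counts must be non-negative integers")
        counts = counts_int
    return Histogram(np.bincount(counts))


def negbinom_pmf(k, alpha: float, mean_k: float):
    """Negative-binomial pmf p(k | alpha, <k>), evaluated in log-space.

        p(k) = Gamma(alpha+k) / (Gamma(alpha) k!) *
               (<k>/(<k>+alpha))^k * (alpha/(<k>+alpha))^alpha

    alpha -> infinity recovers Poisson(<k>); mean_k = 0 degenerates to a
    point mass at k = 0.
    """
    if alpha <= 0:
        raise InvalidInputError("alpha must be positive")
    if mean_k < 0:
        raise InvalidInputError("mean_k must be non-negative")
    k = np.asarray(k)
    scalar = k.ndim == 0
    k = np.atleast_1d(k).astype(np.int64)
    if (k < 0).any():
        raise InvalidInputError("k must be non-negative")
    if mean_k == 0.0:
        out = (k == 0).astype(float)
    else:
        logp = (
            gammaln(alpha + k) - gammaln(alpha) - gammaln(k + 1.0)
            + k * (np.log(mean_k) - np.log(mean_k + alpha))
            + alpha * (np.log(alpha) - np.log(mean_k + alpha))
        )
        out = np.exp(logp)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class NegBinomFit:
    """Fitted shape parameter with the data-constrained mean."""

    alpha: float
    mean_k: float
    rms_residual: float
    n_sites: float


def fit_alpha(histogram: Histogram, mean_k: float | None = None) -> NegBinomFit:
    """Weighted least-squares fit of the shape parameter alpha.

    The mean is constrained to the data (or an explicit ``mean_k``) and only
    alpha is optimized, by bounded minimization on log alpha.  Bin weights
    follow Poisson counting errors: sigma_k = sqrt(n_k)/N, with one
    pseudo-count (sigma = 1/N) for empty bins inside the fitted range; bins
    beyond the last occupied k are excluded.  ``rms_residual`` is the
    unweighted rms of frequency residuals over the fitted bins.
    """
    n_k = np.asarray(histogram.n_k, dtype=float)
    occupied = np.flatnonzero(n_k > 0)
    if occupied.size < 2:
        raise FitFailureError("need at least two occupied bins to fit alpha")
    if mean_k is None:
        mean_k = histogram.mean_k
    if mean_k <= 0:
        raise FitFailureError("mean_k must be positive to fit alpha")

    kmax = int(occupied[-1])
    n_fit = n_k[: kmax + 1]
    N = n_k.sum()
    f = n_fit / N
    sigma = np.where(n_fit > 0, np.sqrt(np.maximum(n_fit, 1.0)), 1.0) / N
    ks = np.arange(kmax + 1)

    def objective(log_alpha: float) -> float:
        pmf = negbinom_pmf(ks, float(np.exp(log_alpha)), mean_k)
        return float((((f - pmf) / sigma) ** 2).sum())

    res = minimize_scalar(objective, bounds=_LOG_ALPHA_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    alpha = float(np.exp(res.x))
    resid = f - negbinom_pmf(ks, alpha, mean_k)
    return NegBinomFit(
        alpha=alpha,
        mean_k=float(mean_k),
        rms_residual=float(np.sqrt((resid**2).mean())),
        n_sites=float(N),
    )


def overlap_ratio(counts) -> float:
    """Sites substituted >= 2 times over sites substituted >= 1 time."""
    counts = np.concatenate([np.atleast_1d(np.asarray(c)) for c in counts]) \
        if not isinstance(counts, np.ndarray) else np.asarray(counts)
    mutated = int((counts >= 1).sum())
    if mutated == 0:
        raise UndefinedResultError("overlap ratio undefined: no mutated sites")
    return float((counts >= 2).sum()) / mutated
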