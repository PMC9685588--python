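"""Separation-quality objectives.

All scores operate on a set of peaks described by apex retention time and
base width.  Resolution between two peaks is the standard

    Rs = 2 * |tR_b - tR_a| / (w_a + w_b)

using widths at the base (4 sigma for Gaussian peaks).  "Neighboring"
always means adjacent in elution order; a chromatogram with n peaks has
n - 1 neighboring pairs.

The headline objectives, all "lower is better" on [0, 1]:

* resolution score ``o_rs``: each adjacent Rs is capped at 2 (larger
  values buy nothing) and the capped sum is mapped so that 0 means every
  adjacent pair fully resolved and 1 means total coelution;
* time score ``o_t``: last elution time as a fraction of the budget;
* performance score ``o_perf = w_Rs * o_rs + w_t * o_t`` with default
  weights 1.00 and 0.05, so resolution dominates until it saturates.

Two further objectives serve the Bayesian-optimization branch: the number
of connected components (clusters of peaks chained by adjacent Rs < 1.5,
plus the separated peaks — a count to maximize) and the product of all
adjacent resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ScoreWeights",
    "ScoreReport",
    "pairwise_resolution",
    "sum_rs_capped",
    "resolution_score",
    "time_score",
    "performance_score",
    "connected_components",
    "product_resolution",
    "score_peaks",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Weights and thresholds of the performance objectives."""

    w_rs: float = 1.00
    w_t: float = 0.05
    rs_cap: float = 2.0
    cc_threshold: float = 1.5

    def __post_init__(self) -> None:
        for name in ("w_rs", "w_t", "rs_cap", "cc_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ScoreReport:
    """All objectives of one chromatogram, as logged per MDI."""

    n_peaks: int
    sum_rs: float
    o_rs: float
    o_t: float
    o_perf: float
    n_connected_components: int
    prod_rs: float
    t_last_elution: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_sorted_arrays(
    t_r: Sequence[float], widths: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t_r, dtype=float)
    w = np.asarray(widths, dtype=float)
    if t.shape != w.shape:
        raise ValueError("retention times and widths must have equal length")
    if t.size and np.any(w <= 0):
        raise ValueError("all base widths must be > 0")
    order = np.argsort(t, kind="stable")
    return t[order], w[order]


def pairwise_resolution(t_a: float, w_a: float, t_b: float, w_b: float) -> float:
    """Baseline resolution between two peaks from apexes and base widths."""
    if w_a <= 0 or w_b <= 0:
        raise ValueError("base widths must be > 0")
    return 2.0 * abs(t_b - t_a) / (w_a + w_b)


def adjacent_resolutions(
    t_r: Sequence[float], widths: Sequence[float]
) -> np.ndarray:
    """Rs of the n-1 neighboring pairs, peaks taken in elution order."""
    t, w = _as_sorted_arrays(t_r, widths)
    if t.size < 2:
        return np.empty(0)
    return 2.0 * np.diff(t) / (w[:-1] + w[1:])


def sum_rs_capped(
    t_r: Sequence[float], widths: Sequence[float], cap: float = 2.0
) -> float:
    """Adapted resolution sum: each adjacent Rs contributes at most ``cap``."""
    rs = adjacent_resolutions(t_r, widths)
    return float(np.minimum(rs, cap).sum())


def resolution_score(
    t_r: Sequence[float], widths: Sequence[float], cap: float = 2.0
) -> float:
    """Normalized resolution objective on [0, 1]; 0 ideal, 1 full coelution.

    With n peaks the capped sum ranges over [0, cap*(n-1)]; the score is the
    shortfall from the ideal, normalized.  A chromatogram showing one peak
    or none carries no separation information and scores 1, so an optimizer
    can never profit from losing peaks.
    """
    t = np.asarray(t_r, dtype=float)
    if t.size <= 1:
        return 1.0
    ideal = cap * (t.size - 1)
    return float((ideal - sum_rs_capped(t_r, widths, cap)) / ideal)


def time_score(t_last_elution: float, t_max: float) -> float:
    """Analysis-time objective: last elution over budget, clipped to [0, 1]."""
    if t_last_elution < 0:
        raise ValueError("t_last_elution must be >= 0")
    if not t_max > 0:
        raise ValueError("t_max must be > 0")
    return min(t_last_elution / t_max, 1.0)


def performance_score(
    o_rs: float, o_t: float, weights: ScoreWeights = ScoreWeights()
) -> float:
    """Weighted performance objective ``w_Rs*o_rs + w_t*o_t`` (lower is better)."""
    return weights.w_rs * o_rs + weights.w_t * o_t


def connected_components(
    t_r: Sequence[float], widths: Sequence[float], threshold: float = 1.5
) -> int:
    """Count peak clusters plus separated peaks.

    Adjacent peaks with Rs below ``threshold`` belong to the same cluster;
    on a line this makes the component count n minus the number of
    under-resolved adjacent pairs.
    """
    t = np.asarray(t_r, dtype=float)
    if t.size == 0:
        return 0
    rs = adjacent_resolutions(t_r, widths)
    return int(t.size - np.count_nonzero(rs < threshold))


def product_resolution(
    t_r: Sequence[float], widths: Sequence[float], cap: float | None = None
) -> float:
    """Product of all adjacent resolutions (1 for n <= 1, 0 on full coelution)."""
    rs = adjacent_resolutions(t_r, widths)
    if cap is not None:
        rs = np.minimum(rs, cap)
    return float(np.prod(rs)) if rs.size else 1.0


def score_peaks(
    t_r: Sequence[float],
    widths: Sequence[float],
    t_max: float,
    weights: ScoreWeights = ScoreWeights(),
) -> ScoreReport:
    """Evaluate every objective on one peak set and assemble the report."""
    t, w = _as_sorted_arrays(t_r, widths)
    t_last = float(t[-1]) if t.size else 0.0
    o_rs = resolution_score(t, w, weights.rs_cap)
    o_t = time_score(t_last, t_max)
    return ScoreReport(
        n_peaks=int(t.size),
        sum_rs=sum_rs_capped(t, w, weights.rs_cap),
        o_rs=o_rs,
        o_t=o_t,
        o_perf=performance_score(o_rs, o_t, weights),
        n_connected_components=connected_components(t, w, weights.cc_threshold),
        prod_rs=product_resolution(t, w),
        t_last_elution=t_last,
    )
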