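"""Retention laws and retention-time / peak-width prediction.

The workhorse is the linear-solvent-strength (LSS) law

    k(phi) = k0 * exp(-S * phi)

with an optional quadratic extension ``k = k0 * exp(-S*phi + S2*phi**2)``.
Under a programmed gradient the retention time follows from the classical
migration integral: the analyte leaves the column at ``tR = t0 + tau``
where ``tau`` solves

    integral_0^tau dt / k(phi_eff(t)) = t0,

``phi_eff`` being the programmed profile delayed by the dwell time.  For
the LSS law every linear piece of the profile integrates in closed form,
so multistep gradients need no numerical quadrature; the quadratic law
uses composite Gauss-Legendre quadrature per ramp.

Peak widths use a plate-count model in the spirit of gradient peak
compression treatments: ``w = 4*t0*(1 + k_e)*G / sqrt(N)`` at the base,
with ``k_e`` the retention factor at the composition experienced at
elution and ``G`` an optional compression factor in (0, 1].  Predictions
are floored at 0.3 min at the base as a safety margin so the optimizer
never overestimates a separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .gradient import GradientProgram, InstrumentConfig

__all__ = [
    "WIDTH_FLOOR_MIN",
    "RetentionModel",
    "PlateEstimate",
    "ElutionState",
    "k_of_phi",
    "predict_elution",
    "predict_retention_time",
    "compression_factor",
    "predict_peak_width",
    "estimate_plate_number",
    "fit_retention_model",
    "FIT_BOUNDS_LOG10_K0",
    "FIT_BOUNDS_S",
    "FIT_BOUNDS_S2",
]

#: minimum predicted base width (min); measured/true widths are never floored
WIDTH_FLOOR_MIN = 0.3

FIT_BOUNDS_LOG10_K0 = (-2.0, 6.0)  # k0 in [1e-2, 1e6]
FIT_BOUNDS_S = (0.5, 100.0)
FIT_BOUNDS_S2 = (-50.0, 50.0)
PLATE_BOUNDS = (1e2, 1e7)


@dataclass(frozen=True)
class RetentionModel:
    """Per-analyte retention coefficients.

    ``model_kind`` is ``"lss"`` (S2 forced to 0) or ``"quadratic"``.
    ``sse`` carries the sum of squared retention-time residuals of the fit
    that produced the model (0 for a constructed truth model); the two
    flags mark fits from degenerate designs or with large residuals.
    """

    k0: float
    S: float
    S2: float = 0.0
    model_kind: str = "lss"
    sse: float = 0.0
    ill_conditioned: bool = False
    poor_fit: bool = False

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")
        if not self.S > 0:
            raise ValueError(f"S must be > 0, got {self.S}")
        if self.model_kind not in ("lss", "quadratic"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "lss" and self.S2 != 0.0:
            raise ValueError("lss model must have S2 = 0")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


@dataclass(frozen=True)
class PlateEstimate:
    """Plate number fitted from scouting-run peak widths."""

    N: float
    analyte_id: str = ""
    at_bound: bool = False

    def __post_init__(self) -> None:
        if not self.N > 0:
            raise ValueError(f"plate number must be > 0, got {self.N}")


@dataclass(frozen=True)
class ElutionState:
    """Where and how an analyte elutes under a given program."""

    t_R: float  # retention time from injection (min)
    phi_e: float  # composition experienced at elution
    k_e: float  # retention factor at phi_e
    slope_e: float  # local gradient slope dphi/dt at elution (1/min)


def k_of_phi(model: RetentionModel, phi: float) -> float:
    """Retention factor at modifier fraction ``phi``."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    expo = -model.S * phi
    if model.model_kind == "quadratic":
        expo += model.S2 * phi * phi
    return model.k0 * math.exp(expo)


def _inv_k(model: RetentionModel, phi: float) -> float:
    """1 / k(phi) without the domain check (internal integrand)."""
    expo = -model.S * phi
    if model.model_kind == "quadratic":
        expo += model.S2 * phi * phi
    return math.exp(-expo) / model.k0


# 16-point Gauss-Legendre nodes/weights on [0, 1], for the quadratic law
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _piece_integral(model: RetentionModel, phi0: float, slope: float, dt: float) -> float:
    """Integral of dt'/k over one linear piece starting at phi0, length dt."""
    if dt <= 0:
        return 0.0
    if slope == 0.0 or model.S * abs(slope) * dt < 1e-14:
        return dt * _inv_k(model, phi0)
    if model.model_kind == "lss":
        # int exp(S*(phi0 + b t))/k0 dt = exp(S*phi0) * expm1(S*b*dt) / (k0*S*b)
        sb = model.S * slope
        return math.exp(model.S * phi0) * math.expm1(sb * dt) / (model.k0 * sb)
    # quadratic law: composite Gauss-Legendre, subdividing long ramps
    n_sub = max(1, int(math.ceil(dt / 0.25)))
    h = dt / n_sub
    total = 0.0
    for i in range(n_sub):
        t_lo = i * h
        ts = t_lo + _GL_X * h
        phis = phi0 + slope * ts
        vals = np.exp(model.S * phis - model.S2 * phis * phis) / model.k0
        total += h * float(np.dot(_GL_W, vals))
    return total


def _solve_within_piece(
    model: RetentionModel, phi0: float, slope: float, dur: float, remaining: float
) -> float:
    """Time into a piece at which the migration integral gains ``remaining``."""
    if slope == 0.0:
        return remaining * k_of_phi(model, min(max(phi0, 0.0), 1.0))
    if model.model_kind == "lss":
        sb = model.S * slope
        arg = remaining * model.k0 * sb * math.exp(-model.S * phi0)
        return math.log1p(arg) / sb
    hi = dur if math.isfinite(dur) else remaining * model.k0 * 10.0 + 1.0
    return brentq(
        lambda d: _piece_integral(model, phi0, slope, d) - remaining, 0.0, hi, xtol=1e-12
    )


def predict_elution(
    model: RetentionModel, program: GradientProgram, instrument: InstrumentConfig
) -> ElutionState:
    """Solve the migration integral for one analyte under one program.

    The purge segment holds phi = 1 indefinitely, where k is finite, so
    elution always completes; a degenerate all-zero program is simply an
    isocratic hold at phi_1 followed by the purge.
    """
    if not instrument.t0 > 0:
        raise ValueError("instrument dead time t0 must be > 0")
    target = instrument.t0
    acc = 0.0
    for t_start, dur, phi0, slope in program.pieces(instrument.tD):
        contrib = _piece_integral(model, phi0, slope, dur) if math.isfinite(dur) else math.inf
        if acc + contrib >= target or not math.isfinite(dur):
            d = _solve_within_piece(model, phi0, slope, dur, target - acc)
            tau = t_start + d
            phi_e = phi0 + slope * d
            return ElutionState(
                t_R=tau + instrument.t0,
                phi_e=phi_e,
                k_e=k_of_phi(model, min(max(phi_e, 0.0), 1.0)),
                slope_e=slope,
            )
        acc += contrib
    raise RuntimeError("unreachable: purge piece is infinite")


def predict_retention_time(
    model: RetentionModel, program: GradientProgram, instrument: InstrumentConfig
) -> float:
    """Retention time (min, from injection) under a multistep gradient."""
    return predict_elution(model, program, instrument).t_R


def compression_factor(S: float, slope_e: float, t0: float, k_e: float) -> float:
    """Classical LSS gradient peak-compression factor G in (0, 1].

    ``p = S*b*t0*k_e/(1+k_e)`` with ``b`` the gradient slope at elution;
    isocratic elution (b = 0) gives G = 1.
    """
    p = S * slope_e * t0 * k_e / (1.0 + k_e)
    if p <= 0:
        return 1.0
    return math.sqrt(1.0 + p + p * p / 3.0) / (1.0 + p)


def predict_peak_width(
    model: RetentionModel,
    plate: PlateEstimate,
    program: GradientProgram,
    instrument: InstrumentConfig,
    t_R: float | None = None,
    floor: float = WIDTH_FLOOR_MIN,
    compression: bool = False,
) -> float:
    """Predicted base peak width (min), floored at ``floor``.

    ``w_model = 4*t0*(1+k_e)*G / sqrt(N)``; pass ``floor=0`` for the raw
    model width (used when simulating ground truth, which is never floored).
    """
    if not plate.N > 0:
        raise ValueError("plate number must be > 0")
    state = predict_elution(model, program, instrument)
    if t_R is not None and abs(t_R - state.t_R) > 1e-6:
        # caller supplied a retention time (e.g. observed); trust the model's
        # elution composition but keep their t_R out of the width formula —
        # width depends on k_e and N only
        pass
    G = (
        compression_factor(model.S, state.slope_e, instrument.t0, state.k_e)
        if compression
        else 1.0
    )
    w_model = 4.0 * instrument.t0 / math.sqrt(plate.N) * (1.0 + state.k_e) * G
    return max(w_model, floor)


def estimate_plate_number(
    observations: Sequence[tuple[GradientProgram, float]],
    model: RetentionModel,
    instrument: InstrumentConfig,
    analyte_id: str = "",
    compression: bool = False,
    bounds: tuple[float, float] = PLATE_BOUNDS,
    floor: float | None = None,
) -> PlateEstimate:
    """Fit N to observed base widths across scouting runs.

    The unfloored width model is linear in ``1/sqrt(N)``, so the
    least-squares minimizer is closed-form; N is clipped to ``bounds`` and
    flagged when it lands on a bound.  If the observations come from a
    pipeline that reports widths no smaller than ``floor``, pass it: when
    every observed width sits at that floor the data only bound N from
    below, and the flagged upper bound is returned instead of a spurious
    point estimate.
    """
    if len(observations) == 0:
        raise ValueError("at least one width observation is required")
    if floor is not None and all(w <= floor * (1 + 1e-9) for _, w in observations):
        return PlateEstimate(N=bounds[1], analyte_id=analyte_id, at_bound=True)
    coeffs = []
    widths = []
    for program, w_obs in observations:
        state = predict_elution(model, program, instrument)
        G = (
            compression_factor(model.S, state.slope_e, instrument.t0, state.k_e)
            if compression
            else 1.0
        )
        coeffs.append(4.0 * instrument.t0 * (1.0 + state.k_e) * G)
        widths.append(w_obs)
    c = np.asarray(coeffs)
    w = np.asarray(widths)
    x = float(np.dot(c, w) / np.dot(c, c))  # x = 1/sqrt(N)
    if x <= 0:
        return PlateEstimate(N=bounds[1], analyte_id=analyte_id, at_bound=True)
    n_hat = 1.0 / (x * x)
    n_clip = min(max(n_hat, bounds[0]), bounds[1])
    return PlateEstimate(N=n_clip, analyte_id=analyte_id, at_bound=n_clip != n_hat)


def _distinct_programs(observations: Sequence[tuple[GradientProgram, float]]) -> int:
    seen = set()
    for program, _ in observations:
        seen.add((program.phis, program.holds, program.ramps))
    return len(seen)


def fit_retention_model(
    observations: Sequence[tuple[GradientProgram, float]],
    instrument: InstrumentConfig,
    model_kind: str = "lss",
    rng: np.random.Generator | None = None,
    n_starts: int = 20,
    max_evals: int = 3000,
    sse_per_point_warn: float = 0.04,
) -> RetentionModel:
    """Fit (k0, S[, S2]) to (program, observed tR) pairs.

    Runs ``n_starts`` independent bounded local least-squares minimizations
    (L-BFGS-B over log10 k0 and S[, S2], each capped at ``max_evals``
    objective evaluations) from randomized starting points and keeps the
    lowest-SSE fit.  Starting k0 values are log-uniform over the bounds.

    A design with fewer distinct programs than free parameters cannot pin
    the coefficients down; the returned model is then flagged
    ``ill_conditioned`` (duplicated observations are data, not an error).
    """
    if model_kind not in ("lss", "quadratic"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    n_par = 2 if model_kind == "lss" else 3
    if len(observations) < n_par:
        raise ValueError(
            f"{model_kind} fit needs >= {n_par} observations, got {len(observations)}"
        )
    rng = np.random.default_rng() if rng is None else rng
    ill = _distinct_programs(observations) < n_par

    programs = [p for p, _ in observations]
    t_obs = np.array([t for _, t in observations], dtype=float)

    def objective(theta: np.ndarray) -> float:
        k0 = 10.0 ** theta[0]
        s = theta[1]
        s2 = theta[2] if n_par == 3 else 0.0
        m = RetentionModel(
            k0=k0, S=s, S2=s2, model_kind="quadratic" if n_par == 3 else "lss"
        )
        sse = 0.0
        for prog, t_o in zip(programs, t_obs):
            r = predict_retention_time(m, prog, instrument) - t_o
            sse += r * r
        return sse

    bounds = [FIT_BOUNDS_LOG10_K0, FIT_BOUNDS_S]
    if n_par == 3:
        bounds.append(FIT_BOUNDS_S2)
    best_theta, best_sse = None, math.inf
    for _ in range(n_starts):
        theta0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": max_evals},
        )
        if res.fun < best_sse:
            best_sse, best_theta = float(res.fun), np.asarray(res.x)
    assert best_theta is not None
    poor = best_sse / len(observations) > sse_per_point_warn
    return RetentionModel(
        k0=10.0 ** best_theta[0],
        S=float(best_theta[1]),
        S2=float(best_theta[2]) if n_par == 3 else 0.0,
        model_kind=model_kind,
        sse=best_sse,
        ill_conditioned=ill,
        poor_fit=poor,
    )
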