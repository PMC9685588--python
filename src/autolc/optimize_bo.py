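"""Bayesian-optimization strategy over three-step gradients.

The model-free alternative to retention modeling: no peak tracking, no
retention fits.  The gradient is restricted to a three-step shape that
starts at a preset ``phi_init`` held until ``t_init = 0.25`` min, ramps to
``phi_A`` at ``t_A``, on to ``phi_B`` at ``t_B``, and ends at a preset
``phi_final`` at ``t_final`` — so only (phi_A, phi_B, t_A, t_B) are
optimized.  Each iteration a Gaussian-process surrogate (Matérn-5/2) is
fitted to the chromatogram-derived objective observed so far and the next
gradient maximizes expected improvement.  The ordering constraints
``phi_A <= phi_B`` and ``t_A <= t_B`` are enforced by optimizing in a unit
box whose coordinate pairs are sorted before mapping to parameters, so
every proposal is feasible by construction.

Objectives (all computed on peaks detected in the baseline-corrected
total-intensity trace, all to maximize): the number of connected
components (peak clusters at Rs < 1.5 plus separated peaks — the default,
it approximates the number of resolved species), the detected-peak count,
and the product of all adjacent resolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .chromsignal import ChromatogramMS, detect_peaks_tic
from .gradient import GradientProgram, InstrumentConfig
from .scores import connected_components, product_resolution

__all__ = [
    "BOGradientParams",
    "BOState",
    "BOMDIRecord",
    "to_program",
    "bo_objective",
    "propose_next",
    "run_bo_loop",
    "best_mdi",
]

OBJECTIVE_KINDS = ("connected_components", "n_peaks", "product_rs")

T_INIT_MIN = 0.25


@dataclass(frozen=True)
class BOGradientParams:
    """The four optimized parameters plus the preset anchors."""

    phi_A: float
    phi_B: float
    t_A: float
    t_B: float
    phi_init: float = 0.05
    t_init: float = T_INIT_MIN
    phi_final: float = 1.0
    t_final: float = 20.0

    def __post_init__(self) -> None:
        if not self.phi_init <= self.phi_A <= self.phi_B <= self.phi_final:
            raise ValueError(
                f"compositions must satisfy phi_init <= phi_A <= phi_B <= phi_final, got "
                f"{self.phi_init} <= {self.phi_A} <= {self.phi_B} <= {self.phi_final}"
            )
        if not self.t_init <= self.t_A <= self.t_B <= self.t_final:
            raise ValueError(
                f"times must satisfy t_init <= t_A <= t_B <= t_final, got "
                f"{self.t_init} <= {self.t_A} <= {self.t_B} <= {self.t_final}"
            )

    def as_unit(self) -> np.ndarray:
        """Map to the unit box used by the surrogate (sorted-pair transform)."""
        d_phi = self.phi_final - self.phi_init
        d_t = self.t_final - self.t_init
        return np.array(
            [
                (self.phi_A - self.phi_init) / d_phi,
                (self.phi_B - self.phi_init) / d_phi,
                (self.t_A - self.t_init) / d_t,
                (self.t_B - self.t_init) / d_t,
            ]
        )

    @classmethod
    def from_unit(
        cls,
        u: np.ndarray,
        phi_init: float = 0.05,
        phi_final: float = 1.0,
        t_init: float = T_INIT_MIN,
        t_final: float = 20.0,
    ) -> "BOGradientParams":
        """Any point of [0, 1]^4 maps to a feasible parameter set: each
        coordinate pair is sorted before scaling."""
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        u_phi = np.sort(u[:2])
        u_t = np.sort(u[2:])
        return cls(
            phi_A=phi_init + u_phi[0] * (phi_final - phi_init),
            phi_B=phi_init + u_phi[1] * (phi_final - phi_init),
            t_A=t_init + u_t[0] * (t_final - t_init),
            t_B=t_init + u_t[1] * (t_final - t_init),
            phi_init=phi_init,
            t_init=t_init,
            phi_final=phi_final,
            t_final=t_final,
        )


def to_program(params: BOGradientParams) -> GradientProgram:
    """Express the three-step gradient in the 5-segment program encoding.

    Hold at ``phi_init`` for ``t_init``, then linear pieces through
    (t_A, phi_A), (t_B, phi_B), (t_final, phi_final); the two unused
    segments collapse to zero length.
    """
    return GradientProgram(
        phis=(
            params.phi_init,
            params.phi_A,
            params.phi_B,
            params.phi_final,
            params.phi_final,
            params.phi_final,
        ),
        holds=(params.t_init, 0.0, 0.0, 0.0, 0.0),
        ramps=(
            params.t_A - params.t_init,
            params.t_B - params.t_A,
            params.t_final - params.t_B,
            0.0,
            0.0,
        ),
        label="bo",
    )


def bo_objective(
    chrom: ChromatogramMS,
    kind: str = "connected_components",
    min_snr: float = 10.0,
    min_points: int = 5,
    cc_threshold: float = 1.5,
) -> float:
    """Chromatogram-derived objective to maximize (no tracking, no models)."""
    if kind not in OBJECTIVE_KINDS:
        raise ValueError(f"kind must be one of {OBJECTIVE_KINDS}, got {kind!r}")
    peaks = detect_peaks_tic(chrom, min_snr=min_snr, min_points=min_points, baseline=True)
    if not peaks:
        warnings.warn("no peaks detected; objective is 0", stacklevel=2)
        return 0.0
    t_r = [p.t_R for p in peaks]
    widths = [p.base_width for p in peaks]
    if kind == "connected_components":
        return float(connected_components(t_r, widths, threshold=cc_threshold))
    if kind == "n_peaks":
        return float(len(peaks))
    return product_resolution(t_r, widths)


@dataclass
class BOState:
    """Everything the proposer needs: observations and the box presets."""

    observations: list[tuple[BOGradientParams, float]] = field(default_factory=list)
    phi_init: float = 0.05
    phi_final: float = 1.0
    t_init: float = T_INIT_MIN
    t_final: float = 20.0

    def add(self, params: BOGradientParams, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError("objective values must be finite")
        self.observations.append((params, value))


def _expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, best: float, xi: float = 0.0
) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best - xi) / sigma
    return (mu - best - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def propose_next(
    state: BOState,
    rng: np.random.Generator,
    n_candidates: int = 4096,
    duplicate_tol: float = 1e-6,
    explore: float = 0.05,
) -> BOGradientParams:
    """Fit the GP surrogate and return the expected-improvement maximizer.

    The acquisition is maximized over random samples of the unit box (every
    point of which maps to a feasible gradient); candidates closer than
    ``duplicate_tol`` (in the unit box) to a previous observation are
    excluded.  ``explore`` adds the usual scale-free exploration margin to
    expected improvement (a fraction of the observed objective range), which
    keeps the few-iteration search from stalling on plateaus of
    integer-valued objectives.  If the surrogate fit fails, a random
    feasible draw is returned instead (logged as a warning).
    """
    if not state.observations:
        raise ValueError("propose_next needs at least one observation")
    x = np.array([p.as_unit() for p, _ in state.observations])
    # sorted-pair transform: canonicalize so duplicates are detected in
    # the same representation the candidates use
    x[:, :2] = np.sort(x[:, :2], axis=1)
    x[:, 2:] = np.sort(x[:, 2:], axis=1)
    y = np.array([v for _, v in state.observations], dtype=float)

    cand = rng.random((n_candidates, 4))
    cand[:, :2] = np.sort(cand[:, :2], axis=1)
    cand[:, 2:] = np.sort(cand[:, 2:], axis=1)

    def as_params(u: np.ndarray) -> BOGradientParams:
        return BOGradientParams.from_unit(
            u, state.phi_init, state.phi_final, state.t_init, state.t_final
        )

    try:
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=np.full(4, 0.3), nu=2.5
        ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-10, 1e1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31 - 1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(x, y)
        mu, sigma = gp.predict(cand, return_std=True)
        xi = explore * float(y.max() - y.min())
        ei = _expected_improvement(mu, sigma, float(y.max()), xi=xi)
    except Exception as exc:  # surrogate failure: fall back to random draw
        warnings.warn(f"surrogate fit failed ({exc!r}); proposing a random gradient")
        return as_params(rng.random(4))

    order = np.argsort(ei)[::-1]
    for idx in order:
        dists = np.linalg.norm(x - cand[idx], axis=1)
        if dists.min() > duplicate_tol:
            return as_params(cand[idx])
    return as_params(rng.random(4))  # all candidates duplicated (pathological)


@dataclass
class BOMDIRecord:
    """One BO iteration: the gradient run and every score it obtained."""

    index: int
    params: BOGradientParams
    program: GradientProgram
    n_peaks: int
    n_connected_components: int
    prod_rs: float
    objective: float


def run_bo_loop(
    instrument_iface,
    rng: np.random.Generator,
    n_mdi: int = 10,
    objective_kind: str = "connected_components",
    n_init: int = 3,
    phi_init: float = 0.05,
    phi_final: float = 1.0,
    t_final: float = 20.0,
    min_snr: float = 10.0,
    min_points: int = 5,
) -> list[BOMDIRecord]:
    """Sequential BO: space-filling initialization, then propose-run-score.

    All three scores are recorded every MDI regardless of which one drives
    the acquisition.  ``instrument_iface`` must provide
    ``run(program, run_id) -> ChromatogramMS``; instrument errors propagate
    with the MDI index attached.
    """
    if objective_kind not in OBJECTIVE_KINDS:
        raise ValueError(f"objective_kind must be one of {OBJECTIVE_KINDS}")
    if n_mdi < 1:
        raise ValueError("n_mdi must be >= 1")
    state = BOState(
        phi_init=phi_init, phi_final=phi_final, t_init=T_INIT_MIN, t_final=t_final
    )
    sampler = qmc.LatinHypercube(d=4, seed=int(rng.integers(2**31 - 1)))
    init_points = sampler.random(n=min(n_init, n_mdi))

    history: list[BOMDIRecord] = []
    for mdi in range(1, n_mdi + 1):
        if mdi <= len(init_points):
            params = BOGradientParams.from_unit(
                init_points[mdi - 1], phi_init, phi_final, T_INIT_MIN, t_final
            )
        else:
            params = propose_next(state, rng)
        program = to_program(params).relabel(f"bo-mdi-{mdi:02d}")
        try:
            chrom = instrument_iface.run(program, run_id=f"bo-mdi-{mdi:02d}")
        except Exception as exc:
            raise RuntimeError(f"instrument failed at MDI {mdi}") from exc
        peaks = detect_peaks_tic(chrom, min_snr=min_snr, min_points=min_points)
        t_r = [p.t_R for p in peaks]
        widths = [p.base_width for p in peaks]
        n_cc = connected_components(t_r, widths) if peaks else 0
        prod = product_resolution(t_r, widths) if peaks else 0.0
        scores = {
            "connected_components": float(n_cc),
            "n_peaks": float(len(peaks)),
            "product_rs": prod,
        }
        value = scores[objective_kind]
        state.add(params, value)
        history.append(
            BOMDIRecord(
                index=mdi,
                params=params,
                program=program,
                n_peaks=len(peaks),
                n_connected_components=n_cc,
                prod_rs=prod,
                objective=value,
            )
        )
    return history


def best_mdi(history: Sequence[BOMDIRecord]) -> BOMDIRecord:
    """The best iteration: highest objective, ties broken by peak count."""
    if not history:
        raise ValueError("empty history")
    return max(history, key=lambda r: (r.objective, r.n_peaks))


def history_to_frame(history: Sequence[BOMDIRecord]) -> pd.DataFrame:
    """Per-MDI trace of parameters and scores (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "mdi": r.index,
                "phi_A": r.params.phi_A,
                "phi_B": r.params.phi_B,
                "t_A": r.params.t_A,
                "t_B": r.params.t_B,
                "n_peaks": r.n_peaks,
                "connected_components": r.n_connected_components,
                "product_rs": r.prod_rs,
                "objective": r.objective,
            }
            for r in history
        ]
    )
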