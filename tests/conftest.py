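"""Shared fixtures: instruments, budgets, and small synthetic chromatograms."""

from __future__ import annotations

import math

import numpy as np
import pytest

from autolc.chromsignal import ChromatogramMS
from autolc.gradient import GradientProgram, InstrumentConfig, TimeBudget


@pytest.fixture
def instrument() -> InstrumentConfig:
    return InstrumentConfig(t0=1.0, tD=0.5, sampling_rate=600.0)


@pytest.fixture
def no_dwell_instrument() -> InstrumentConfig:
    return InstrumentConfig(t0=1.0, tD=0.0, sampling_rate=600.0)


@pytest.fixture
def budget() -> TimeBudget:
    return TimeBudget(t_max=40.0)


def linear_program(ramp: float, phi_start: float = 0.0, phi_end: float = 1.0) -> GradientProgram:
    """Single linear gradient phi_start -> phi_end over ``ramp`` minutes."""
    return GradientProgram(
        phis=(phi_start, phi_end, phi_end, phi_end, phi_end, phi_end),
        holds=(0.0,) * 5,
        ramps=(ramp, 0.0, 0.0, 0.0, 0.0),
    )


def isocratic_program(phi: float, hold: float = 200.0) -> GradientProgram:
    """Long isocratic hold at ``phi`` (budget-free construction for math tests)."""
    return GradientProgram(phis=(phi,) * 6, holds=(hold, 0.0, 0.0, 0.0, 0.0), ramps=(0.0,) * 5)


def gaussian_trace(
    time_axis: np.ndarray, peaks: list[tuple[float, float, float]]
) -> np.ndarray:
    """Sum of Gaussians given (apex_time, base_width_4sigma, area) triples."""
    y = np.zeros_like(time_axis)
    for t_r, w, area in peaks:
        sigma = w / 4.0
        y += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((time_axis - t_r) / sigma) ** 2
        )
    return y


def make_chromatogram(
    peaks: list[tuple[float, float, float, float]],
    t_end: float = 10.0,
    dt: float = 1.0 / 600.0,
    mz_axis: np.ndarray | None = None,
    run_id: str = "test",
) -> ChromatogramMS:
    """Chromatogram from (t_R, base_width, area, mz) tuples, noiseless."""
    time_axis = np.arange(0.0, t_end, dt)
    if mz_axis is None:
        mz_axis = np.arange(100.0, 151.0, 1.0)
    intensity = np.zeros((time_axis.size, mz_axis.size))
    for t_r, w, area, mz in peaks:
        j = int(np.argmin(np.abs(mz_axis - mz)))
        intensity[:, j] += gaussian_trace(time_axis, [(t_r, w, area)])
    return ChromatogramMS(
        time_axis=time_axis, mz_axis=mz_axis, intensity=intensity, run_id=run_id
    )
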