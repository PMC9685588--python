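"""Multisegment gradient programs for reversed-phase LC.

A gradient program is the pump table of one method-development iteration
(MDI): five segments, each an isocratic hold of length ``t_n`` at organic
modifier fraction ``phi_n`` followed by a linear ramp of length ``tG_n``
up to ``phi_{n+1}``, closed by a purge segment that steps immediately to
``phi_7 = 1`` and holds it.  Six compositions, five holds and five ramps
give the 16 free parameters of a candidate method; the purge composition
and its hold are presets.

Feasibility rules: compositions are non-decreasing (positive gradient
slopes only), all in [0, 1]; all times are non-negative; the programmed
time ``sum(t_n) + sum(tG_n)`` may not exceed the analysis budget
``t_max``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "N_SEGMENTS",
    "N_FREE_PARAMETERS",
    "GradientProgram",
    "InstrumentConfig",
    "TimeBudget",
    "validate_program",
    "composition_at_time",
    "random_candidate",
]

N_SEGMENTS = 5
#: free parameters of a candidate method: 6 compositions + 5 holds + 5 ramps
N_FREE_PARAMETERS = 16

DEFAULT_PURGE_PHI = 1.0
DEFAULT_PURGE_HOLD = 2.0


@dataclass(frozen=True)
class TimeBudget:
    """Analysis-time budget: holds plus ramps may not exceed ``t_max`` minutes."""

    t_max: float = 40.0

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")


@dataclass(frozen=True)
class InstrumentConfig:
    """Column/system constants.

    Parameters
    ----------
    t0
        Column dead time in minutes (elution time of an unretained tracer).
    tD
        Dwell time in minutes: delay between the pump mixing point and the
        column inlet.  The programmed profile reaches the column shifted by
        this amount.
    sampling_rate
        Detector sampling rate in points per minute.
    flow_label
        Free-text metadata (flow rate, column id); not used numerically.
    """

    t0: float = 1.0
    tD: float = 0.5
    sampling_rate: float = 600.0
    flow_label: str = ""

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise ValueError(f"dead time t0 must be > 0, got {self.t0}")
        if self.tD < 0:
            raise ValueError(f"dwell time tD must be >= 0, got {self.tD}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")


@dataclass(frozen=True)
class GradientProgram:
    """One 16-parameter, 5-segment gradient method plus the purge preset.

    ``phis`` holds phi_1..phi_6, ``holds`` t_1..t_5, ``ramps`` tG_1..tG_5.
    Construction does not enforce feasibility; use :func:`validate_program`
    (violations are data, not exceptions).
    """

    phis: tuple[float, ...]
    holds: tuple[float, ...]
    ramps: tuple[float, ...]
    purge_phi: float = DEFAULT_PURGE_PHI
    purge_hold: float = DEFAULT_PURGE_HOLD
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "phis", tuple(float(v) for v in self.phis))
        object.__setattr__(self, "holds", tuple(float(v) for v in self.holds))
        object.__setattr__(self, "ramps", tuple(float(v) for v in self.ramps))
        if len(self.phis) != N_SEGMENTS + 1:
            raise ValueError(f"expected {N_SEGMENTS + 1} compositions, got {len(self.phis)}")
        if len(self.holds) != N_SEGMENTS or len(self.ramps) != N_SEGMENTS:
            raise ValueError(f"expected {N_SEGMENTS} holds and {N_SEGMENTS} ramps")

    # -- time structure -------------------------------------------------

    @property
    def programmed_time(self) -> float:
        """Total programmed time before the purge, sum(t_n) + sum(tG_n), minutes."""
        return float(sum(self.holds) + sum(self.ramps))

    def free_parameters(self) -> np.ndarray:
        """The 16 free parameters as one vector (phi_1..6, t_1..5, tG_1..5)."""
        return np.concatenate([self.phis, self.holds, self.ramps])

    @classmethod
    def from_free_parameters(
        cls,
        vec: np.ndarray,
        purge_phi: float = DEFAULT_PURGE_PHI,
        purge_hold: float = DEFAULT_PURGE_HOLD,
        label: str = "",
    ) -> "GradientProgram":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_FREE_PARAMETERS,):
            raise ValueError(f"expected {N_FREE_PARAMETERS} parameters, got {vec.shape}")
        return cls(
            phis=tuple(vec[:6]),
            holds=tuple(vec[6:11]),
            ramps=tuple(vec[11:16]),
            purge_phi=purge_phi,
            purge_hold=purge_hold,
            label=label,
        )

    def pieces(self, tD: float = 0.0) -> list[tuple[float, float, float, float]]:
        """Piecewise-linear profile as seen at the column inlet.

        Returns ``(t_start, duration, phi_start, slope)`` tuples covering
        [0, inf): the pre-dwell hold at phi_1, each programmed hold and ramp
        delayed by ``tD``, then the purge step to ``purge_phi`` held
        indefinitely (the purge never ends from the column's point of view,
        guaranteeing elution of every analyte with finite retention).
        """
        out: list[tuple[float, float, float, float]] = []
        t = 0.0
        if tD > 0:
            out.append((0.0, tD, self.phis[0], 0.0))
            t = tD
        for n in range(N_SEGMENTS):
            if self.holds[n] > 0:
                out.append((t, self.holds[n], self.phis[n], 0.0))
                t += self.holds[n]
            if self.ramps[n] > 0:
                slope = (self.phis[n + 1] - self.phis[n]) / self.ramps[n]
                out.append((t, self.ramps[n], self.phis[n], slope))
                t += self.ramps[n]
        out.append((t, math.inf, self.purge_phi, 0.0))
        return out

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "phi": list(self.phis),
            "hold": list(self.holds),
            "ramp": list(self.ramps),
            "purge": {"phi": self.purge_phi, "hold": self.purge_hold},
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GradientProgram":
        purge = d.get("purge", {})
        return cls(
            phis=tuple(d["phi"]),
            holds=tuple(d["hold"]),
            ramps=tuple(d["ramp"]),
            purge_phi=float(purge.get("phi", DEFAULT_PURGE_PHI)),
            purge_hold=float(purge.get("hold", DEFAULT_PURGE_HOLD)),
            label=d.get("label", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GradientProgram":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "GradientProgram":
        return cls.from_dict(yaml.safe_load(s))

    def relabel(self, label: str) -> "GradientProgram":
        return replace(self, label=label)


def validate_program(program: GradientProgram, budget: TimeBudget) -> list[str]:
    """Check every feasibility rule; return one message per violation.

    An empty list means the program is a valid candidate under ``budget``.
    The time budget is inclusive: programmed time exactly equal to ``t_max``
    is allowed.
    """
    v: list[str] = []
    phis = program.phis
    for i, phi in enumerate(phis, start=1):
        if not (0.0 <= phi <= 1.0):
            v.append(f"phi{i}={phi:g}: composition outside [0, 1]")
    for i in range(len(phis) - 1):
        if phis[i] > phis[i + 1]:
            v.append(
                f"phi{i + 1}={phis[i]:g} > phi{i + 2}={phis[i + 1]:g}: "
                "compositions must be non-decreasing (positive gradient slope)"
            )
    if phis[-1] > program.purge_phi:
        v.append(
            f"phi6={phis[-1]:g} > purge phi={program.purge_phi:g}: "
            "compositions must be non-decreasing into the purge"
        )
    for i, t in enumerate(program.holds, start=1):
        if t < 0:
            v.append(f"hold t{i}={t:g}: negative time")
    for i, t in enumerate(program.ramps, start=1):
        if t < 0:
            v.append(f"ramp tG{i}={t:g}: negative time")
    total = program.programmed_time
    if total > budget.t_max:
        v.append(
            f"sum of holds and ramps {total:g} min exceeds budget t_max={budget.t_max:g} min"
        )
    return v


def composition_at_time(
    program: GradientProgram, instrument: InstrumentConfig, t: float
) -> float:
    """Modifier fraction phi at the column inlet at time ``t`` (minutes).

    The programmed profile is delayed by the dwell time; before it arrives
    the column sees phi_1, after the last programmed segment it sees the
    purge composition.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    for t_start, dur, phi0, slope in program.pieces(instrument.tD):
        if t < t_start + dur:
            return phi0 + slope * (t - t_start)
    return program.purge_phi  # unreachable: last piece is infinite


def random_candidate(
    rng: np.random.Generator,
    budget: TimeBudget,
    purge_phi: float = DEFAULT_PURGE_PHI,
    purge_hold: float = DEFAULT_PURGE_HOLD,
    label: str = "",
) -> GradientProgram:
    """Draw one feasible candidate gradient, valid by construction.

    Compositions: six Uniform(0, 1) draws, sorted non-decreasing.
    Times: ten exponential variates normalized to a Uniform(0, 1) fraction
    of ``t_max`` — a Dirichlet split of a random total — so the budget holds
    by construction and short and long candidates are equally likely.
    """
    phis = np.sort(rng.uniform(0.0, 1.0, size=N_SEGMENTS + 1))
    raw = rng.exponential(1.0, size=2 * N_SEGMENTS)
    total = rng.uniform(0.0, 1.0) * budget.t_max
    times = raw / raw.sum() * total
    return GradientProgram(
        phis=tuple(phis),
        holds=tuple(times[:N_SEGMENTS]),
        ramps=tuple(times[N_SEGMENTS:]),
        purge_phi=purge_phi,
        purge_hold=purge_hold,
        label=label,
    )
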