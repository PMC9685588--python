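"""Virtual LC-MS instrument: the closed-loop stand-in for real hardware.

A :class:`VirtualSample` is a hidden ground-truth analyte library — per
analyte a true LSS retention model, a true plate number, an abundance and
an m/z signature.  Given any gradient program the instrument solves the
true migration integral, renders Gaussian peaks onto the analyte's m/z
channels (area proportional to abundance), adds baseline drift, additive
detector noise and small retention/width jitter, and returns the
chromatogram together with the hidden true peak table.  Truth widths are
never floored: the 0.3 min prediction floor is a property of the
optimizer, and keeping truth unfloored makes its safety margin observable
as a predicted-vs-achieved bias.

Default analyte statistics mimic small-molecule/peptide reversed-phase
behaviour: log10 k0 uniform on [0.5, 4] and S uniform on [5, 40] with
correlation 0.7 (stronger-retained compounds respond more steeply to the
modifier), plate numbers 5e3-5e4, abundances spread over two decades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

from .gradient import GradientProgram, InstrumentConfig, TimeBudget
from .retention import RetentionModel, compression_factor, predict_elution

__all__ = [
    "Analyte",
    "VirtualSample",
    "NoiseSpec",
    "VirtualInstrument",
    "generate_sample",
    "render_chromatogram",
    "scouting_programs",
]

DEFAULT_MZ_MIN = 100.0
DEFAULT_MZ_MAX = 1500.0
DEFAULT_MZ_BIN = 1.0


@dataclass(frozen=True)
class Analyte:
    """Ground truth for one compound."""

    model: RetentionModel
    N: float  # true plate number
    abundance: float  # total rendered area, arbitrary units
    mz_signature: tuple[tuple[float, float], ...]  # (m/z, relative intensity)

    def __post_init__(self) -> None:
        if not self.N > 0 or not self.abundance > 0:
            raise ValueError("N and abundance must be > 0")
        if not self.mz_signature:
            raise ValueError("analyte needs at least one m/z channel")


@dataclass(frozen=True)
class VirtualSample:
    """Hidden analyte library driving the simulator."""

    analytes: tuple[Analyte, ...]
    name: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.analytes)

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "seed": self.seed,
            "analytes": [
                {
                    "k0": a.model.k0,
                    "S": a.model.S,
                    "S2": a.model.S2,
                    "model_kind": a.model.model_kind,
                    "N": a.N,
                    "abundance": a.abundance,
                    "mz": [list(ch) for ch in a.mz_signature],
                }
                for a in self.analytes
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "VirtualSample":
        d = yaml.safe_load(text)
        analytes = tuple(
            Analyte(
                model=RetentionModel(
                    k0=a["k0"],
                    S=a["S"],
                    S2=a.get("S2", 0.0),
                    model_kind=a.get("model_kind", "lss"),
                ),
                N=a["N"],
                abundance=a["abundance"],
                mz_signature=tuple((float(m), float(w)) for m, w in a["mz"]),
            )
            for a in d["analytes"]
        )
        return cls(analytes=analytes, name=d.get("name", ""), seed=d.get("seed"))


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement imperfections added on top of the ideal chromatogram.

    ``drift_amplitude`` and ``noise_sd`` are fractions of the maximum
    rendered signal; ``rt_jitter_sd`` is in minutes; ``width_jitter`` is a
    fractional standard deviation on the true base width.
    """

    drift_amplitude: float = 0.02
    drift_shape: str = "sine"  # "sine" or "linear"
    noise_sd: float = 1e-4
    rt_jitter_sd: float = 0.01
    width_jitter: float = 0.02

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "noise_sd", "rt_jitter_sd", "width_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_shape not in ("sine", "linear"):
            raise ValueError("drift_shape must be 'sine' or 'linear'")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(drift_amplitude=0.0, noise_sd=0.0, rt_jitter_sd=0.0, width_jitter=0.0)


def generate_sample(
    n_analytes: int,
    rng: np.random.Generator,
    difficulty: str = "default",
    n_mz_channels: int = 1,
    mz_min: float = DEFAULT_MZ_MIN,
    mz_max: float = DEFAULT_MZ_MAX,
    name: str = "",
) -> VirtualSample:
    """Draw a ground-truth analyte library.

    ``difficulty`` is either ``"default"`` (unique m/z per analyte) or
    ``"overlapF"`` with a fraction F (e.g. ``"overlap0.3"``): that fraction
    of analytes reuses another analyte's m/z channel, stressing the
    order-prior branch of peak tracking.  ``n_mz_channels`` > 1 adds minor
    signature channels per analyte.
    """
    if n_analytes < 1:
        raise ValueError("n_analytes must be >= 1")
    overlap = 0.0
    if difficulty.startswith("overlap"):
        overlap = float(difficulty[len("overlap"):])
        if not 0.0 <= overlap <= 1.0:
            raise ValueError(f"overlap fraction must be in [0, 1], got {overlap}")
    elif difficulty != "default":
        raise ValueError(f"unknown difficulty preset {difficulty!r}")

    # Gaussian copula: log10 k0 and S uniform marginals, correlation 0.7
    cov = np.array([[1.0, 0.7], [0.7, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_analytes)
    u = ndtr(z)
    log10_k0 = 0.5 + 3.5 * u[:, 0]
    s_vals = 5.0 + 35.0 * u[:, 1]
    n_plates = rng.uniform(5e3, 5e4, size=n_analytes)
    abundance = 10.0 ** rng.uniform(0.0, 2.0, size=n_analytes)

    channels = np.arange(math.ceil(mz_min), math.floor(mz_max) + 1, dtype=float)
    n_channels_needed = n_analytes * max(1, n_mz_channels)
    if n_channels_needed > channels.size:
        raise ValueError("m/z grid too narrow for the requested sample")
    picks = rng.choice(channels, size=n_channels_needed, replace=False)
    primary = picks[:n_analytes].copy()
    n_shared = int(round(overlap * n_analytes))
    if n_shared and n_analytes > 1:
        sharers = rng.choice(n_analytes, size=n_shared, replace=False)
        for idx in sharers:
            donor = int(rng.integers(n_analytes))
            while donor == idx:
                donor = int(rng.integers(n_analytes))
            primary[idx] = primary[donor]

    analytes = []
    extra = picks[n_analytes:]
    for i in range(n_analytes):
        signature = [(float(primary[i]), 1.0)]
        for c in range(1, n_mz_channels):
            signature.append(
                (float(extra[i * (n_mz_channels - 1) + (c - 1)]), float(rng.uniform(0.2, 0.8)))
            )
        analytes.append(
            Analyte(
                model=RetentionModel(k0=float(10.0 ** log10_k0[i]), S=float(s_vals[i])),
                N=float(n_plates[i]),
                abundance=float(abundance[i]),
                mz_signature=tuple(signature),
            )
        )
    return VirtualSample(analytes=tuple(analytes), name=name)


def render_chromatogram(
    sample: VirtualSample,
    program: GradientProgram,
    instrument: InstrumentConfig,
    noise: NoiseSpec,
    rng: np.random.Generator,
    run_id: str = "",
    mz_min: float = DEFAULT_MZ_MIN,
    mz_max: float = DEFAULT_MZ_MAX,
    mz_bin: float = DEFAULT_MZ_BIN,
    compression: bool = False,
) -> tuple:
    """Simulate one run: true elution, Gaussian rendering, drift and noise.

    Acquisition covers the programmed gradient, the dwell delay, the purge
    hold and one extra dead time; analytes whose apex falls beyond that
    window do not appear (they have not eluted when acquisition stops).

    Returns ``(ChromatogramMS, truth)`` where ``truth`` is the hidden peak
    table (analyte index, as-rendered t_R and unfloored base width, primary
    m/z, abundance).
    """
    from .chromsignal import ChromatogramMS  # local import to avoid a cycle

    # acquisition covers the program, the purge, and — because the purge is
    # designed to elute everything — any stragglers still migrating at phi = 1
    states = [predict_elution(a.model, program, instrument) for a in sample.analytes]
    t_end = program.programmed_time + instrument.tD + program.purge_hold + instrument.t0
    if states:
        t_end = max(t_end, max(s.t_R for s in states) + instrument.t0)
    dt = 1.0 / instrument.sampling_rate
    time_axis = np.arange(0.0, t_end + dt / 2, dt)
    mz_axis = np.arange(mz_min, mz_max + mz_bin / 2, mz_bin)
    intensity = np.zeros((time_axis.size, mz_axis.size))

    truth_rows = []
    for i, analyte in enumerate(sample.analytes):
        state = states[i]
        t_r = state.t_R + (rng.normal(0.0, noise.rt_jitter_sd) if noise.rt_jitter_sd else 0.0)
        g = (
            compression_factor(analyte.model.S, state.slope_e, instrument.t0, state.k_e)
            if compression
            else 1.0
        )
        width = 4.0 * instrument.t0 / math.sqrt(analyte.N) * (1.0 + state.k_e) * g
        if noise.width_jitter:
            width *= max(1.0 + rng.normal(0.0, noise.width_jitter), 0.05)
        if not 0.0 <= t_r <= time_axis[-1]:
            continue
        sigma = width / 4.0
        lo = np.searchsorted(time_axis, t_r - 6.0 * sigma)
        hi = np.searchsorted(time_axis, t_r + 6.0 * sigma)
        window = time_axis[lo:hi]
        shape = np.exp(-0.5 * ((window - t_r) / sigma) ** 2)
        for mz, rel in analyte.mz_signature:
            j = int(round((mz - mz_min) / mz_bin))
            if not 0 <= j < mz_axis.size:
                continue
            area = analyte.abundance * rel
            intensity[lo:hi, j] += area / (sigma * math.sqrt(2.0 * math.pi)) * shape
        truth_rows.append(
            {
                "analyte": i,
                "t_R_min": t_r,
                "width_base_min": width,
                "mz": analyte.mz_signature[0][0],
                "abundance": analyte.abundance,
            }
        )

    max_signal = float(intensity.max()) if intensity.size else 0.0
    if max_signal > 0 and noise.drift_amplitude > 0:
        if noise.drift_shape == "sine":
            drift = 0.5 * (1.0 + np.sin(2.0 * math.pi * time_axis / time_axis[-1] - math.pi / 2))
        else:
            drift = time_axis / time_axis[-1]
        intensity += (noise.drift_amplitude * max_signal / mz_axis.size) * drift[:, None]
    if max_signal > 0 and noise.noise_sd > 0:
        intensity += rng.normal(0.0, noise.noise_sd * max_signal, size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)

    chrom = ChromatogramMS(
        time_axis=time_axis,
        mz_axis=mz_axis,
        intensity=intensity,
        run_id=run_id,
        program_used=program,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["analyte", "t_R_min", "width_base_min", "mz", "abundance"]
    )
    return chrom, truth


def scouting_programs(
    instrument: InstrumentConfig,
    budget: TimeBudget,
    slope_multiples: tuple[float, ...] = (10.0, 30.0, 90.0),
) -> list[GradientProgram]:
    """Three linear scouting gradients phi 0 -> 1 with distinct slopes.

    Ramp times default to 10, 30 and 90 dead times, clipped into the
    budget while keeping the slopes strictly ordered.
    """
    ramps = []
    for m in slope_multiples:
        ramps.append(min(m * instrument.t0, budget.t_max))
    if len(set(ramps)) != len(ramps):  # budget clipped two ramps together
        ramps = sorted({min(r, budget.t_max * (i + 1) / len(ramps)) for i, r in enumerate(ramps)})
    programs = []
    for i, ramp in enumerate(ramps, start=1):
        programs.append(
            GradientProgram(
                phis=(0.0, 1.0, 1.0, 1.0, 1.0, 1.0),
                holds=(0.0,) * 5,
                ramps=(ramp, 0.0, 0.0, 0.0, 0.0),
                label=f"scout-{i}",
            )
        )
    return programs


class VirtualInstrument:
    """Stateful run-on-demand interface used by the closed loops.

    ``run(program)`` returns the chromatogram only — the loop never sees
    ground truth — while ``truths`` accumulates the hidden tables for
    post-hoc evaluation.
    """

    def __init__(
        self,
        sample: VirtualSample,
        instrument: InstrumentConfig,
        noise: NoiseSpec | None = None,
        rng: np.random.Generator | None = None,
        mz_min: float = DEFAULT_MZ_MIN,
        mz_max: float = DEFAULT_MZ_MAX,
        mz_bin: float = DEFAULT_MZ_BIN,
    ) -> None:
        self.sample = sample
        self.instrument = instrument
        self.noise = noise if noise is not None else NoiseSpec()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.grid = (mz_min, mz_max, mz_bin)
        self.truths: dict[str, pd.DataFrame] = {}
        self._counter = 0

    def run(self, program: GradientProgram, run_id: str = ""):
        self._counter += 1
        run_id = run_id or f"run-{self._counter:03d}"
        chrom, truth = render_chromatogram(
            self.sample,
            program,
            self.instrument,
            self.noise,
            self.rng,
            run_id=run_id,
            mz_min=self.grid[0],
            mz_max=self.grid[1],
            mz_bin=self.grid[2],
        )
        self.truths[run_id] = truth
        return chrom
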