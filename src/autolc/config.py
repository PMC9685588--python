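"""Configuration schema and deterministic seed fan-out.

One YAML file configures a whole closed-loop run.  Validation is strict:
unknown keys are rejected and every violation is reported at once.  A
single master seed is fanned out into independent per-role child seeds
(candidate generation, GA, BO, instrument noise, model fitting) so any
stochastic stage can be re-seeded in isolation and a run is exactly
reproducible from (config, master seed).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .gradient import InstrumentConfig, TimeBudget
from .instrument import NoiseSpec
from .optimize_rm import RMLoopConfig
from .scores import ScoreWeights

__all__ = [
    "AutoLCConfig",
    "load_config",
    "dump_config",
    "child_seed",
    "child_rng",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class InstrumentSection(_Strict):
    t0: float = Field(1.0, gt=0, description="dead time, min")
    tD: float = Field(0.5, ge=0, description="dwell time, min")
    sampling_rate: float = Field(600.0, gt=0, description="points per minute")
    flow_label: str = ""
    mz_min: float = Field(100.0, gt=0)
    mz_max: float = Field(1500.0, gt=0)
    mz_bin: float = Field(1.0, gt=0)

    def build(self) -> InstrumentConfig:
        return InstrumentConfig(
            t0=self.t0, tD=self.tD, sampling_rate=self.sampling_rate, flow_label=self.flow_label
        )


class WeightsSection(_Strict):
    w_rs: float = Field(1.00, gt=0)
    w_t: float = Field(0.05, gt=0)
    rs_cap: float = Field(2.0, gt=0)
    cc_threshold: float = Field(1.5, gt=0)

    def build(self) -> ScoreWeights:
        return ScoreWeights(
            w_rs=self.w_rs, w_t=self.w_t, rs_cap=self.rs_cap, cc_threshold=self.cc_threshold
        )


class NoiseSection(_Strict):
    drift_amplitude: float = Field(0.02, ge=0)
    drift_shape: str = "sine"
    noise_sd: float = Field(1e-4, ge=0)
    rt_jitter_sd: float = Field(0.01, ge=0)
    width_jitter: float = Field(0.02, ge=0)

    def build(self) -> NoiseSpec:
        return NoiseSpec(
            drift_amplitude=self.drift_amplitude,
            drift_shape=self.drift_shape,
            noise_sd=self.noise_sd,
            rt_jitter_sd=self.rt_jitter_sd,
            width_jitter=self.width_jitter,
        )


class RMSection(_Strict):
    pool_size: int = Field(2000, gt=0)
    top_k: int = Field(200, gt=0)
    generations: int = Field(1500, gt=0)
    stage_one_maxfev: int = Field(500, gt=0)
    mdi_cap: int = Field(13, ge=4)
    stop_tol: float = Field(0.01, gt=0)
    stop_patience: int = Field(2, gt=0)
    model_kind: str = "lss"
    width_floor: float = Field(0.3, ge=0)
    compression: bool = False
    min_snr: float = Field(10.0, gt=0)
    min_points: int = Field(5, gt=0)
    area_fraction: float = Field(0.80, gt=0, le=1)
    mz_tolerance: float = Field(0.5, gt=0)


class BOSection(_Strict):
    n_mdi: int = Field(10, gt=0)
    objective: str = "connected_components"
    n_init: int = Field(3, gt=0)
    phi_init: float = Field(0.05, ge=0, le=1)
    phi_final: float = Field(1.0, ge=0, le=1)
    t_final: float = Field(20.0, gt=0)


class AutoLCConfig(_Strict):
    """Effective configuration of a run; every default is materialized."""

    seed: int = 0
    t_max: float = Field(40.0, gt=0, description="analysis-time budget, min")
    instrument: InstrumentSection = InstrumentSection()
    weights: WeightsSection = WeightsSection()
    noise: NoiseSection = NoiseSection()
    rm: RMSection = RMSection()
    bo: BOSection = BOSection()

    def budget(self) -> TimeBudget:
        return TimeBudget(t_max=self.t_max)

    def rm_loop_config(self) -> RMLoopConfig:
        r = self.rm
        return RMLoopConfig(
            budget=self.budget(),
            weights=self.weights.build(),
            pool_size=r.pool_size,
            top_k=r.top_k,
            generations=r.generations,
            stage_one_maxfev=r.stage_one_maxfev,
            mdi_cap=r.mdi_cap,
            stop_tol=r.stop_tol,
            stop_patience=r.stop_patience,
            model_kind=r.model_kind,
            width_floor=r.width_floor,
            compression=r.compression,
            min_snr=r.min_snr,
            min_points=r.min_points,
            area_fraction=r.area_fraction,
            mz_tolerance=r.mz_tolerance,
        )


def load_config(path: str | Path | None = None) -> AutoLCConfig:
    """Load and validate a YAML config; an empty/missing body yields defaults.

    Schema violations (unknown keys, out-of-range values) are raised
    together in one ValidationError.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    return AutoLCConfig(**data)


def dump_config(config: AutoLCConfig) -> str:
    """Serialize the effective config (round-trips through load_config)."""
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


def child_seed(master_seed: int, role: str) -> int:
    """Stable per-role child seed derived from the master seed (< 2**31)."""
    digest = hashlib.blake2s(f"{master_seed}:{role}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def child_rng(master_seed: int, role: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, role))
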