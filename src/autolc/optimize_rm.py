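"""Retention-modeling optimization strategy (two-stage, closed loop).

Each method-development iteration (MDI) of this strategy:

1. fits per-analyte retention models to the tracked peak tables,
2. builds a pool of exactly 2000 candidate gradients — the programs of
   all previous MDIs plus ``2000 - x`` fresh random candidates,
3. locally refines every candidate against the resolution score alone
   (stage one, bounded simplex with feasibility repair),
4. hands the 200 best candidates to a genetic algorithm that fine-tunes
   them against the weighted performance score, which also discourages
   needlessly long gradients (stage two),
5. programs the best gradient found as the next MDI.

Three linear scouting gradients of different slope seed the loop; a full
re-detection/re-tracking over all stored runs ("retrack") happens at MDI
4, 9, 14, ...; the loop stops when the achieved performance score has
improved by less than a tolerance for two consecutive MDIs, or at the
MDI cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _fast
from .chromsignal import (
    ChromatogramMS,
    PeakRecord,
    TrackTable,
    detect_peaks_mz,
    peaks_to_frame,
    retrack,
    retrack_due,
    track_peaks,
)
from .gradient import (
    GradientProgram,
    InstrumentConfig,
    TimeBudget,
    random_candidate,
    validate_program,
)
from .instrument import scouting_programs
from .retention import (
    WIDTH_FLOOR_MIN,
    PlateEstimate,
    RetentionModel,
    estimate_plate_number,
    fit_retention_model,
    predict_elution,
    predict_peak_width,
)
from .scores import ScoreReport, ScoreWeights, score_peaks

__all__ = [
    "POOL_SIZE",
    "TOP_K",
    "GA_GENERATIONS",
    "ScoredCandidate",
    "GAResult",
    "MDIRecord",
    "RMLoopConfig",
    "InstrumentInterface",
    "simulate_chromatogram",
    "build_pool",
    "stage_one_refine",
    "select_top",
    "ga_optimize",
    "fit_models_from_tracktable",
    "run_rm_loop",
]

POOL_SIZE = 2000
TOP_K = 200
GA_GENERATIONS = 1500
STAGE_ONE_MAXFEV = 500


class InstrumentInterface(Protocol):
    """What the loop needs from an instrument: run a program, get raw data."""

    def run(self, program: GradientProgram, run_id: str = "") -> ChromatogramMS: ...


# ---------------------------------------------------------------------------
# simulation of candidate methods from fitted models
# ---------------------------------------------------------------------------


def simulate_chromatogram(
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]],
    program: GradientProgram,
    instrument: InstrumentConfig,
    floor: float = WIDTH_FLOOR_MIN,
    compression: bool = False,
) -> pd.DataFrame:
    """Predict the peak set one program would produce.

    Returns a DataFrame (analyte_id, t_R_min, width_base_min, ok) sorted by
    retention time; an analyte whose prediction fails is kept as a flagged
    row with NaNs rather than aborting the simulation.
    """
    rows = []
    for analyte_id, (model, plate) in models.items():
        try:
            state = predict_elution(model, program, instrument)
            width = predict_peak_width(
                model, plate, program, instrument, floor=floor, compression=compression
            )
            rows.append(
                {"analyte_id": analyte_id, "t_R_min": state.t_R, "width_base_min": width, "ok": True}
            )
        except (ValueError, RuntimeError):
            rows.append(
                {"analyte_id": analyte_id, "t_R_min": np.nan, "width_base_min": np.nan, "ok": False}
            )
    df = pd.DataFrame(rows, columns=["analyte_id", "t_R_min", "width_base_min", "ok"])
    return df.sort_values("t_R_min", na_position="last").reset_index(drop=True)


def _model_arrays(
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k0s = np.array([m.k0 for m, _ in models.values()])
    ss = np.array([m.S for m, _ in models.values()])
    ns = np.array([p.N for _, p in models.values()])
    return k0s, ss, ns


def make_objective(
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]],
    instrument: InstrumentConfig,
    budget: TimeBudget,
    weights: ScoreWeights = ScoreWeights(),
    floor: float = WIDTH_FLOOR_MIN,
    compression: bool = False,
    include_time: bool = False,
    purge_phi: float = 1.0,
) -> Callable[[np.ndarray], float]:
    """Objective over raw 16-vectors (repair included): o_rs or o_perf.

    Uses the compiled LSS kernel; falls back to the scalar route when any
    model is quadratic.
    """
    if all(m.model_kind == "lss" for m, _ in models.values()):
        k0s, ss, ns = _model_arrays(models)
        t0, tD = instrument.t0, instrument.tD

        def objective(vec: np.ndarray) -> float:
            return _fast.rm_objective(
                np.ascontiguousarray(vec, dtype=np.float64),
                k0s,
                ss,
                ns,
                t0,
                tD,
                purge_phi,
                budget.t_max,
                floor,
                weights.rs_cap,
                weights.w_rs,
                weights.w_t,
                include_time,
                compression,
            )

        return objective

    def objective_slow(vec: np.ndarray) -> float:
        rep = _fast.repair16(np.ascontiguousarray(vec, dtype=np.float64), budget.t_max)
        program = GradientProgram.from_free_parameters(rep, purge_phi=purge_phi)
        df = simulate_chromatogram(models, program, instrument, floor=floor, compression=compression)
        good = df[df["ok"]]
        report = score_peaks(
            good["t_R_min"].to_numpy(), good["width_base_min"].to_numpy(), budget.t_max, weights
        )
        return report.o_perf if include_time else report.o_rs

    return objective_slow


# ---------------------------------------------------------------------------
# candidate pool and two-stage optimization
# ---------------------------------------------------------------------------


@dataclass
class ScoredCandidate:
    program: GradientProgram
    o_rs: float
    t_last: float
    refined: bool = True  # False when local refinement failed


def build_pool(
    prior_programs: Sequence[GradientProgram],
    rng: np.random.Generator,
    budget: TimeBudget,
    pool_size: int = POOL_SIZE,
) -> list[GradientProgram]:
    """Pool of exactly ``pool_size`` candidates: priors plus fresh randoms."""
    if not prior_programs:
        raise ValueError("at least the scouting programs must be supplied")
    if len(prior_programs) >= pool_size:
        raise ValueError(f"{len(prior_programs)} prior programs exceed the pool size {pool_size}")
    pool = list(prior_programs)
    for i in range(pool_size - len(prior_programs)):
        pool.append(random_candidate(rng, budget, label=f"cand-{i + 1}"))
    return pool


def _t_last(objective_vec: np.ndarray, models, instrument, budget, floor, compression) -> float:
    k0s, ss, ns = _model_arrays(models)
    rep = _fast.repair16(np.ascontiguousarray(objective_vec, dtype=np.float64), budget.t_max)
    t_r, _ = _fast.predict_peaks16(
        rep, k0s, ss, ns, instrument.t0, instrument.tD, 1.0, floor, compression
    )
    return float(t_r.max()) if t_r.size else 0.0


def stage_one_refine(
    pool: Sequence[GradientProgram],
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]],
    instrument: InstrumentConfig,
    budget: TimeBudget,
    weights: ScoreWeights = ScoreWeights(),
    maxfev: int = STAGE_ONE_MAXFEV,
    floor: float = WIDTH_FLOOR_MIN,
    compression: bool = False,
) -> list[ScoredCandidate]:
    """Locally refine every candidate against the resolution score alone.

    Nelder-Mead over the raw 16-vector with feasibility repair inside the
    objective, capped at ``maxfev`` evaluations per candidate.  Refinement
    can only help: if the local search ends worse than it started (or
    fails), the candidate keeps its unrefined parameters and score, marked
    unrefined.  The result is sorted ascending by score.
    """
    objective = make_objective(
        models, instrument, budget, weights, floor, compression, include_time=False
    )
    scored: list[ScoredCandidate] = []
    for program in pool:
        x0 = program.free_parameters()
        f0 = objective(x0)
        refined = True
        try:
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-6},
            )
            if res.fun <= f0:
                best_vec, best_f = res.x, float(res.fun)
            else:
                best_vec, best_f, refined = x0, f0, False
        except Exception:
            best_vec, best_f, refined = x0, f0, False
        rep = _fast.repair16(np.ascontiguousarray(best_vec, dtype=np.float64), budget.t_max)
        refined_program = GradientProgram.from_free_parameters(
            rep, purge_phi=program.purge_phi, purge_hold=program.purge_hold, label=program.label
        )
        t_last = _t_last(rep, models, instrument, budget, floor, compression)
        scored.append(
            ScoredCandidate(program=refined_program, o_rs=best_f, t_last=t_last, refined=refined)
        )
    order = sorted(range(len(scored)), key=lambda i: (scored[i].o_rs, scored[i].t_last, i))
    return [scored[i] for i in order]


def select_top(scored: Sequence[ScoredCandidate], k: int = TOP_K) -> list[ScoredCandidate]:
    """The k lowest-o_rs candidates (ties: shorter analysis, then pool order)."""
    if len(scored) < k:
        raise ValueError(f"pool of {len(scored)} is smaller than k={k}")
    order = sorted(range(len(scored)), key=lambda i: (scored[i].o_rs, scored[i].t_last, i))
    return [scored[i] for i in order[:k]]


@dataclass
class GAResult:
    best_program: GradientProgram
    best_o_perf: float
    trace: pd.DataFrame  # generation, mean_fitness, best_so_far


def ga_optimize(
    population: Sequence[GradientProgram],
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]],
    instrument: InstrumentConfig,
    budget: TimeBudget,
    rng: np.random.Generator,
    weights: ScoreWeights = ScoreWeights(),
    generations: int = GA_GENERATIONS,
    tournament: int = 3,
    p_crossover: float = 0.7,
    p_mutation: float = 0.1,
    mutation_sigma_frac: float = 0.05,
    n_elite: int = 2,
    floor: float = WIDTH_FLOOR_MIN,
    compression: bool = False,
) -> GAResult:
    """Genetic fine-tuning of the top candidates against the performance score.

    Tournament selection, uniform crossover, per-gene Gaussian mutation
    with sigma at 5 % of each gene's range, elitism, and feasibility repair
    after every variation, so no generation ever holds an invalid program.
    """
    objective = make_objective(
        models, instrument, budget, weights, floor, compression, include_time=True
    )
    n_pop = len(population)
    genes = np.stack(
        [
            _fast.repair16(np.ascontiguousarray(p.free_parameters()), budget.t_max)
            for p in population
        ]
    )
    sigma = np.empty(16)
    sigma[:6] = mutation_sigma_frac * 1.0
    sigma[6:] = mutation_sigma_frac * budget.t_max
    fitness = np.array([objective(genes[i]) for i in range(n_pop)])

    best_idx = int(np.argmin(fitness))
    best_vec = genes[best_idx].copy()
    best_fit = float(fitness[best_idx])
    gen_col, mean_col, best_col = [0], [float(fitness.mean())], [best_fit]

    for gen in range(1, generations + 1):
        elite_order = np.argsort(fitness, kind="stable")[:n_elite]
        children = [genes[i].copy() for i in elite_order]
        while len(children) < n_pop:
            picks = rng.integers(n_pop, size=(2, tournament))
            pa = picks[0][np.argmin(fitness[picks[0]])]
            pb = picks[1][np.argmin(fitness[picks[1]])]
            c1, c2 = genes[pa].copy(), genes[pb].copy()
            if rng.random() < p_crossover:
                mask = rng.random(16) < 0.5
                c1[mask], c2[mask] = c2[mask], c1[mask].copy()
            for child in (c1, c2):
                mut = rng.random(16) < p_mutation
                if mut.any():
                    child[mut] += rng.normal(0.0, sigma[mut])
                children.append(_fast.repair16(np.ascontiguousarray(child), budget.t_max))
                if len(children) == n_pop:
                    break
        genes = np.stack(children)
        fitness = np.array([objective(genes[i]) for i in range(n_pop)])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = float(fitness[gen_best])
            best_vec = genes[gen_best].copy()
        gen_col.append(gen)
        mean_col.append(float(fitness.mean()))
        best_col.append(best_fit)

    best_program = GradientProgram.from_free_parameters(best_vec, label="ga-best")
    trace = pd.DataFrame(
        {"generation": gen_col, "mean_fitness": mean_col, "best_so_far": best_col}
    )
    return GAResult(best_program=best_program, best_o_perf=best_fit, trace=trace)


# ---------------------------------------------------------------------------
# model fitting from tracked tables
# ---------------------------------------------------------------------------


def fit_models_from_tracktable(
    table: TrackTable,
    programs_by_run: Mapping[str, GradientProgram],
    instrument: InstrumentConfig,
    rng: np.random.Generator,
    model_kind: str = "lss",
    n_starts: int = 20,
    max_evals: int = 3000,
    compression: bool = False,
) -> dict[str, tuple[RetentionModel, PlateEstimate]]:
    """Fit retention model and plate number per tracked analyte.

    Analytes observed in fewer runs than the model has parameters are
    skipped (they cannot constrain a fit); an analyte absent from a run
    simply contributes no observation for that run.
    """
    n_par = 2 if model_kind == "lss" else 3
    out: dict[str, tuple[RetentionModel, PlateEstimate]] = {}
    for analyte_id in table.analyte_ids:
        obs = table.observations(analyte_id)
        if len(obs) < n_par:
            continue
        rt_obs = [(programs_by_run[run_id], t_r) for run_id, t_r, _ in obs]
        model = fit_retention_model(
            rt_obs,
            instrument,
            model_kind=model_kind,
            rng=rng,
            n_starts=n_starts,
            max_evals=max_evals,
        )
        width_obs = [(programs_by_run[run_id], w) for run_id, _, w in obs]
        plate = estimate_plate_number(
            width_obs, model, instrument, analyte_id=analyte_id, compression=compression
        )
        out[analyte_id] = (model, plate)
    return out


def models_to_frame(
    models: Mapping[str, tuple[RetentionModel, PlateEstimate]]
) -> pd.DataFrame:
    """Fitted models as a long table (analyte_id, model_kind, k0, S, S2, N, sse)."""
    rows = [
        {
            "analyte_id": analyte_id,
            "model_kind": m.model_kind,
            "k0": m.k0,
            "S": m.S,
            "S2": m.S2,
            "N": p.N,
            "sse": m.sse,
        }
        for analyte_id, (m, p) in models.items()
    ]
    return pd.DataFrame(rows, columns=["analyte_id", "model_kind", "k0", "S", "S2", "N", "sse"])


def track_incremental(
    table: TrackTable,
    new_peaks: Sequence[PeakRecord],
    run_id: str,
    mz_tolerance: float = 0.5,
) -> TrackTable:
    """Attach one new run to an existing table, matching known analytes only.

    Mirrors the incremental mode of the tracking workflow: between
    retracks the algorithm searches the new chromatogram exclusively for
    the analytes it already knows; unmatched new peaks are left for the
    next retrack to discover.  Implemented by re-tracking the stored peak
    records together with the new list and then dropping analytes that
    were not in the existing table's m/z groups.
    """
    peak_lists: dict[str, list[PeakRecord]] = {}
    for (analyte, run), rec in table.records.items():
        peak_lists.setdefault(run, []).append(rec)
    known_mz = np.sort(table.mz.dropna().to_numpy())
    kept = [
        p
        for p in new_peaks
        if known_mz.size
        and np.min(np.abs(known_mz - (p.mz if p.mz is not None else np.inf))) <= mz_tolerance
    ]
    peak_lists[run_id] = kept
    return track_peaks(peak_lists, mz_tolerance=mz_tolerance)


# ---------------------------------------------------------------------------
# the closed loop
# ---------------------------------------------------------------------------


@dataclass
class RMLoopConfig:
    """All tunables of the retention-modeling loop (defaults = study conditions)."""

    budget: TimeBudget = field(default_factory=TimeBudget)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    pool_size: int = POOL_SIZE
    top_k: int = TOP_K
    generations: int = GA_GENERATIONS
    stage_one_maxfev: int = STAGE_ONE_MAXFEV
    mdi_cap: int = 13
    stop_tol: float = 0.01
    stop_patience: int = 2
    model_kind: str = "lss"
    fit_starts: int = 20
    fit_max_evals: int = 3000
    width_floor: float = WIDTH_FLOOR_MIN
    compression: bool = False
    min_snr: float = 10.0
    min_points: int = 5
    area_fraction: float = 0.80
    mz_tolerance: float = 0.5
    scouting_slope_multiples: tuple[float, ...] = (10.0, 30.0, 90.0)


@dataclass
class MDIRecord:
    """One iteration of the loop: what ran and how it scored."""

    index: int
    kind: str  # "scouting" or "optimized"
    program: GradientProgram
    achieved: ScoreReport
    predicted: ScoreReport | None = None
    n_tracked: int = 0
    n_modeled: int = 0
    retracked: bool = False
    ga_trace: pd.DataFrame | None = None
    peak_table: pd.DataFrame | None = None  # detected peaks of this run
    track_table: pd.DataFrame | None = None  # long-format linkage after this MDI
    model_table: pd.DataFrame | None = None  # fitted models used for this MDI


def run_rm_loop(
    instrument_iface: InstrumentInterface,
    instrument: InstrumentConfig,
    rng: np.random.Generator,
    config: RMLoopConfig | None = None,
) -> list[MDIRecord]:
    """Run the full closed loop against any instrument interface.

    Returns the MDI history (scouting runs included).  Aborts with a
    diagnostic if tracking cannot link peaks across at least two runs,
    since no retention model can be fitted from a single observation.
    """
    cfg = config if config is not None else RMLoopConfig()
    history: list[MDIRecord] = []
    chroms: list[ChromatogramMS] = []
    peak_lists: dict[str, list[PeakRecord]] = {}
    programs_by_run: dict[str, GradientProgram] = {}

    def run_and_detect(program: GradientProgram, mdi: int) -> tuple[ChromatogramMS, list[PeakRecord]]:
        run_id = f"mdi-{mdi:02d}"
        chrom = instrument_iface.run(program, run_id=run_id)
        peaks, _ = detect_peaks_mz(
            chrom,
            area_fraction=cfg.area_fraction,
            min_snr=cfg.min_snr,
            min_points=cfg.min_points,
        )
        chroms.append(chrom)
        peak_lists[run_id] = peaks
        programs_by_run[run_id] = program
        return chrom, peaks

    def achieved_report(peaks: Sequence[PeakRecord]) -> ScoreReport:
        return score_peaks(
            [p.t_R for p in peaks], [p.base_width for p in peaks], cfg.budget.t_max, cfg.weights
        )

    # phase I: three scouting gradients
    scouts = scouting_programs(instrument, cfg.budget, cfg.scouting_slope_multiples)
    for mdi, program in enumerate(scouts, start=1):
        _, peaks = run_and_detect(program, mdi)
        history.append(
            MDIRecord(
                index=mdi,
                kind="scouting",
                program=program,
                achieved=achieved_report(peaks),
                peak_table=peaks_to_frame(peaks),
            )
        )
    table = track_peaks(peak_lists, mz_tolerance=cfg.mz_tolerance)
    for rec in history:
        rec.n_tracked = len(table.analyte_ids)

    usable = sum(1 for a in table.analyte_ids if len(table.observations(a)) >= 2)
    if usable == 0:
        raise RuntimeError(
            "tracking linked no analyte across >= 2 runs; "
            f"{len(table.analyte_ids)} analytes seen, all in single runs — "
            "cannot fit any retention model"
        )

    best_scout = min(history, key=lambda r: r.achieved.o_perf)
    if best_scout.achieved.o_perf == 0.0:
        return history  # scouting already ideal; nothing to optimize

    stall = 0
    prev_perf = best_scout.achieved.o_perf
    mdi = len(scouts)
    while mdi < cfg.mdi_cap:
        mdi += 1
        models = fit_models_from_tracktable(
            table,
            programs_by_run,
            instrument,
            rng,
            model_kind=cfg.model_kind,
            n_starts=cfg.fit_starts,
            max_evals=cfg.fit_max_evals,
            compression=cfg.compression,
        )
        if not models:
            raise RuntimeError("no analyte has enough tracked observations to fit a model")
        pool = build_pool(
            [programs_by_run[r] for r in sorted(programs_by_run)], rng, cfg.budget, cfg.pool_size
        )
        scored = stage_one_refine(
            pool,
            models,
            instrument,
            cfg.budget,
            cfg.weights,
            maxfev=cfg.stage_one_maxfev,
            floor=cfg.width_floor,
            compression=cfg.compression,
        )
        top = select_top(scored, cfg.top_k)
        ga = ga_optimize(
            [c.program for c in top],
            models,
            instrument,
            cfg.budget,
            rng,
            cfg.weights,
            generations=cfg.generations,
            floor=cfg.width_floor,
            compression=cfg.compression,
        )
        next_program = ga.best_program.relabel(f"mdi-{mdi:02d}")
        assert not validate_program(next_program, cfg.budget)

        predicted_df = simulate_chromatogram(
            models, next_program, instrument, floor=cfg.width_floor, compression=cfg.compression
        )
        good = predicted_df[predicted_df["ok"]]
        predicted = score_peaks(
            good["t_R_min"].to_numpy(),
            good["width_base_min"].to_numpy(),
            cfg.budget.t_max,
            cfg.weights,
        )

        _, peaks = run_and_detect(next_program, mdi)
        if retrack_due(mdi):
            table = retrack(
                chroms,
                area_fraction=cfg.area_fraction,
                min_snr=cfg.min_snr,
                min_points=cfg.min_points,
                mz_tolerance=cfg.mz_tolerance,
            )
            retracked = True
        else:
            table = track_incremental(
                table, peaks, f"mdi-{mdi:02d}", mz_tolerance=cfg.mz_tolerance
            )
            retracked = False

        achieved = achieved_report(peaks)
        history.append(
            MDIRecord(
                index=mdi,
                kind="optimized",
                program=next_program,
                achieved=achieved,
                predicted=predicted,
                n_tracked=len(table.analyte_ids),
                n_modeled=len(models),
                retracked=retracked,
                ga_trace=ga.trace,
                peak_table=peaks_to_frame(peaks),
                track_table=table.to_frame(),
                model_table=models_to_frame(models),
            )
        )

        improvement = (prev_perf - achieved.o_perf) / max(prev_perf, 1e-12)
        stall = stall + 1 if improvement < cfg.stop_tol else 0
        prev_perf = min(prev_perf, achieved.o_perf)
        if stall >= cfg.stop_patience:
            break
    return history
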