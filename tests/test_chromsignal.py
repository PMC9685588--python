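"""Baseline correction, two-stage peak detection, tracking, retracking."""

import numpy as np
import pytest

from autolc.chromsignal import (
    ChromatogramMS,
    PeakRecord,
    correct_baseline,
    detect_peaks_mz,
    detect_peaks_tic,
    is_chromatographic_peak,
    retrack,
    retrack_due,
    track_peaks,
)
from autolc.gradient import InstrumentConfig, TimeBudget
from autolc.instrument import NoiseSpec, generate_sample, render_chromatogram, scouting_programs
from conftest import gaussian_trace, make_chromatogram


class TestBaseline:
    def test_flat_trace_is_fully_removed(self):
        y = np.full(500, 37.0)
        corrected, baseline = correct_baseline(y)
        assert np.allclose(baseline, 37.0, atol=1e-6 * 37.0)
        assert np.allclose(corrected, 0.0, atol=1e-6 * 37.0)

    def test_all_zero_trace(self):
        corrected, baseline = correct_baseline(np.zeros(100))
        assert not corrected.any() and not baseline.any()

    def test_planted_peak_areas_survive_drift_removal(self):
        """Gaussians on a linear drift: areas recovered within 2 %."""
        t = np.arange(0.0, 10.0, 1 / 600)
        planted = [(2.0, 0.4, 30.0), (5.0, 0.3, 12.0), (8.0, 0.5, 50.0)]
        drift = 5.0 + 3.0 * t / t[-1]
        y = gaussian_trace(t, planted) + drift
        corrected, _ = correct_baseline(y, dt=1 / 600)
        dt = t[1] - t[0]
        for t_r, w, area in planted:
            sel = np.abs(t - t_r) < 1.5 * w
            recovered = corrected[sel].sum() * dt
            assert recovered == pytest.approx(area, rel=0.02)

    def test_too_short_trace_is_an_error(self):
        with pytest.raises(ValueError):
            correct_baseline(np.ones(5))


class TestTicDetection:
    def test_well_separated_peaks_all_found_with_accurate_apexes(self):
        dt = 1 / 600
        planted = [(1.5, 0.3, 10.0), (3.0, 0.25, 5.0), (4.5, 0.4, 20.0), (6.0, 0.3, 8.0), (8.0, 0.35, 15.0)]
        chrom = make_chromatogram([(t, w, a, 100.0 + 10 * i) for i, (t, w, a) in enumerate(planted)])
        peaks = detect_peaks_tic(chrom, baseline=False)
        assert len(peaks) == 5
        for rec, (t_r, w, a) in zip(peaks, planted):
            assert abs(rec.t_R - t_r) <= dt / 2
            assert rec.base_width == pytest.approx(w, rel=0.05)
            assert rec.area == pytest.approx(a, rel=0.05)

    def test_pure_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 10.0, 1 / 600)
        intensity = np.abs(rng.normal(0, 1.0, (t.size, 3)))
        chrom = ChromatogramMS(time_axis=t, mz_axis=np.array([100.0, 101, 102]), intensity=intensity)
        assert detect_peaks_tic(chrom, baseline=False) == []

    def test_badly_merged_pair_counts_as_one(self):
        """Rs = 0.3 is far below what the summed trace can resolve."""
        w = 0.5
        delta = 0.3 * w  # Rs = 2*dt/(2w) = dt/w
        chrom = make_chromatogram([(5.0, w, 10.0, 100.0), (5.0 + delta, w, 10.0, 101.0)])
        assert len(detect_peaks_tic(chrom, baseline=False)) == 1


class TestXicDecision:
    def test_clear_gaussian_is_a_peak(self):
        t = np.arange(0.0, 10.0, 1 / 600)
        rng = np.random.default_rng(1)
        noise_sd = 1.0
        xic = gaussian_trace(t, [(5.0, 0.3, 50 * noise_sd * 0.3 / 4 * np.sqrt(2 * np.pi))])
        xic += np.clip(rng.normal(0, noise_sd, t.size), 0, None)
        ok, peaks = is_chromatographic_peak(t, xic, min_snr=10)
        assert ok and len(peaks) == 1

    def test_white_noise_is_not_a_peak(self):
        t = np.arange(0.0, 10.0, 1 / 600)
        xic = np.clip(np.random.default_rng(2).normal(0, 1.0, t.size), 0, None)
        ok, _ = is_chromatographic_peak(t, xic)
        assert not ok

    def test_one_channel_may_carry_two_peaks(self):
        t = np.arange(0.0, 10.0, 1 / 600)
        xic = gaussian_trace(t, [(3.0, 0.3, 20.0), (7.0, 0.3, 20.0)])
        ok, peaks = is_chromatographic_peak(t, xic)
        assert ok and len(peaks) == 2


class TestMzDetection:
    def test_disjoint_channels_all_found_and_area_rule_satisfied(self):
        peaks_in = [(1.5 + i, 0.3, 10.0, 100.0 + 7 * i) for i in range(5)]
        chrom = make_chromatogram(peaks_in)
        found, frac = detect_peaks_mz(chrom)
        assert len(found) == 5
        assert frac >= 0.80
        assert sorted(p.mz for p in found) == sorted(mz for *_, mz in peaks_in)

    def test_coeluting_pair_separated_by_mass(self):
        """The summed trace shows one peak; the m/z stage resolves two."""
        chrom = make_chromatogram([(5.0, 0.4, 10.0, 100.0), (5.05, 0.4, 10.0, 120.0)])
        assert len(detect_peaks_tic(chrom, baseline=False)) == 1
        found, _ = detect_peaks_mz(chrom)
        assert len(found) == 2

    def test_empty_chromatogram_terminates_immediately(self):
        t = np.arange(0.0, 5.0, 1 / 600)
        chrom = ChromatogramMS(
            time_axis=t, mz_axis=np.arange(100.0, 110.0), intensity=np.zeros((t.size, 10))
        )
        found, frac = detect_peaks_mz(chrom)
        assert found == []


def _simulate_runs(n_analytes, seeds, noise=None, difficulty="default"):
    rng = np.random.default_rng(seeds[0])
    sample = generate_sample(n_analytes, rng, difficulty=difficulty, mz_min=100, mz_max=500)
    inst = InstrumentConfig(t0=1.0, tD=0.5)
    noise = noise or NoiseSpec.none()
    run_rng = np.random.default_rng(seeds[1])
    out = {}
    truths = {}
    for i, prog in enumerate(scouting_programs(inst, TimeBudget(40.0))):
        chrom, truth = render_chromatogram(
            sample, prog, inst, noise, run_rng, run_id=f"run-{i}", mz_min=100, mz_max=500
        )
        peaks, _ = detect_peaks_mz(chrom)
        out[f"run-{i}"] = (chrom, peaks)
        truths[f"run-{i}"] = truth
    return sample, out, truths


class TestTracking:
    def test_unique_mass_analytes_track_perfectly(self):
        """20 analytes, unique m/z, 3 scouting runs, low noise: every analyte
        appears once per run and retention matches truth."""
        sample, runs, truths = _simulate_runs(20, (5, 6), noise=NoiseSpec())
        table = track_peaks({rid: peaks for rid, (_, peaks) in runs.items()})
        assert len(table.analyte_ids) == 20
        assert table.retention.notna().all().all()
        dt = 1 / 600
        n_checked = 0
        for rid in table.run_ids:
            truth = truths[rid].set_index("mz")["t_R_min"]
            for aid in table.analyte_ids:
                t_obs = table.retention.at[aid, rid]
                t_true = truth[table.mz[aid]]
                if abs(t_obs - t_true) <= dt:
                    n_checked += 1
        assert n_checked >= 0.95 * 20 * 3

    def test_shared_mass_linked_by_elution_order(self):
        """Two analytes on one m/z never swap order across runs; the order
        prior links them correctly."""
        r1 = [
            PeakRecord("a", 2.0, 0.3, 1, 1, ((100.0, 1.0),)),
            PeakRecord("a", 6.0, 0.3, 1, 1, ((100.0, 1.0),)),
        ]
        r2 = [
            PeakRecord("b", 2.5, 0.3, 1, 1, ((100.0, 1.0),)),
            PeakRecord("b", 5.0, 0.3, 1, 1, ((100.0, 1.0),)),
        ]
        table = track_peaks({"a": r1, "b": r2})
        assert len(table.analyte_ids) == 2
        first, second = table.analyte_ids
        assert table.retention.loc[first].tolist() == [2.0, 2.5]
        assert table.retention.loc[second].tolist() == [6.0, 5.0]

    def test_single_run_tracks_each_peak_as_its_own_analyte(self):
        peaks = [
            PeakRecord("only", 1.0 + i, 0.3, 1, 1, ((100.0 + i, 1.0),)) for i in range(4)
        ]
        table = track_peaks({"only": peaks})
        assert len(table.analyte_ids) == 4
        assert table.run_ids == ["only"]

    def test_partition_independent_of_run_order(self):
        sample, runs, _ = _simulate_runs(12, (8, 9))
        lists = {rid: peaks for rid, (_, peaks) in runs.items()}
        t_a = track_peaks(lists)
        reordered = {rid: lists[rid] for rid in reversed(list(lists))}
        t_b = track_peaks(reordered)
        assert t_a.retention.sort_index(axis=1).equals(t_b.retention.sort_index(axis=1))


class TestRetrack:
    @pytest.mark.parametrize("mdi,due", [(1, False), (4, True), (5, False), (9, True), (13, False), (14, True)])
    def test_schedule_every_fifth_minus_one(self, mdi, due):
        assert retrack_due(mdi) is due

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            retrack_due(0)

    def test_idempotent_on_unchanged_inputs(self):
        _, runs, _ = _simulate_runs(8, (12, 13))
        chroms = [chrom for chrom, _ in runs.values()]
        t_a = retrack(chroms)
        t_b = retrack(chroms)
        assert t_a.retention.equals(t_b.retention)

    def test_single_run_retrack_equals_direct_detection(self):
        _, runs, _ = _simulate_runs(6, (14, 15))
        chrom, peaks = runs["run-0"]
        table = retrack([chrom])
        assert len(table.analyte_ids) == len(peaks)
        assert sorted(table.retention["run-0"]) == pytest.approx(
            sorted(p.t_R for p in peaks)
        )

    def test_retrack_discovers_newly_separated_analytes(self):
        """A pair co-eluting (same m/z channel is not needed — same apex) in
        early runs hides one analyte; once a later run separates the pair, a
        full retrack tracks more analytes than the incremental table, which
        only searches for known analytes."""
        from autolc.optimize_rm import track_incremental

        # two analytes share an m/z and co-elute exactly in runs 1 and 2
        def run_peaks(rid, times):
            return [
                PeakRecord(rid, t, 0.3, 1, 1, ((150.0, 1.0),)) for t in times
            ]

        early = {
            "r1": run_peaks("r1", [3.0]),  # pair fused: one peak
            "r2": run_peaks("r2", [3.2]),
        }
        table = track_peaks(early)
        assert len(table.analyte_ids) == 1
        # new run separates them into two peaks
        new_peaks = run_peaks("r3", [2.8, 4.1])
        incremental = track_incremental(table, new_peaks, "r3")
        full = track_peaks({**early, "r3": new_peaks})
        assert len(full.analyte_ids) > len(table.analyte_ids)
        assert len(full.analyte_ids) >= len(incremental.analyte_ids)


class TestContainerIO:
    def test_npz_round_trip(self, tmp_path):
        chrom = make_chromatogram([(2.0, 0.3, 5.0, 100.0)])
        path = tmp_path / "run.npz"
        chrom.save(path)
        again = ChromatogramMS.load(path)
        assert np.array_equal(again.intensity, chrom.intensity)
        assert np.array_equal(again.time_axis, chrom.time_axis)
        assert again.run_id == chrom.run_id


class TestExternalPeakTables:
    def test_round_trip_through_long_format(self):
        from autolc.chromsignal import track_table_from_frame

        _, runs, _ = _simulate_runs(6, (30, 31))
        table = track_peaks({rid: peaks for rid, (_, peaks) in runs.items()})
        again = track_table_from_frame(table.to_frame())
        assert again.retention.equals(table.retention)
        assert again.width.equals(table.width)

    def test_missing_columns_rejected(self):
        import pandas as pd

        from autolc.chromsignal import track_table_from_frame

        with pytest.raises(ValueError, match="misses columns"):
            track_table_from_frame(pd.DataFrame({"analyte_id": ["a"]}))

    def test_duplicate_cell_rejected(self):
        import pandas as pd

        from autolc.chromsignal import track_table_from_frame

        df = pd.DataFrame(
            {
                "analyte_id": ["a", "a"],
                "run_id": ["r1", "r1"],
                "t_R_min": [1.0, 2.0],
                "width_base_min": [0.3, 0.3],
            }
        )
        with pytest.raises(ValueError, match="twice"):
            track_table_from_frame(df)
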