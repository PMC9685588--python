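"""Retention laws, multistep retention-time integration, widths, fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from autolc.gradient import GradientProgram, InstrumentConfig, TimeBudget, random_candidate
from autolc.retention import (
    PlateEstimate,
    RetentionModel,
    estimate_plate_number,
    fit_retention_model,
    k_of_phi,
    predict_elution,
    predict_peak_width,
    predict_retention_time,
)
from conftest import isocratic_program, linear_program


def quadrature_retention_time(
    model: RetentionModel, program: GradientProgram, instrument: InstrumentConfig
) -> float:
    """Independent oracle: piecewise adaptive quadrature + root finding.

    Integrates 1/k over each linear piece of the delayed profile with
    ``scipy.integrate.quad`` and locates the migration-complete time by
    bisection inside the terminal piece.
    """

    pieces = program.pieces(instrument.tD)

    def piece_integral(phi0, slope, d):
        val, _ = quad(lambda t: 1.0 / k_of_phi(model, min(max(phi0 + slope * t, 0.0), 1.0)), 0.0, d, limit=200)
        return val

    acc = 0.0
    for t_start, dur, phi0, slope in pieces:
        if math.isfinite(dur):
            contrib = piece_integral(phi0, slope, dur)
        else:
            contrib = math.inf
        if acc + contrib >= instrument.t0:
            rem = instrument.t0 - acc
            if slope == 0.0:
                d = rem * k_of_phi(model, min(max(phi0, 0.0), 1.0))
            else:
                hi = dur
                d = brentq(lambda x: piece_integral(phi0, slope, x) - rem, 0.0, hi, xtol=1e-12)
            return t_start + d + instrument.t0
        acc += contrib
    raise AssertionError("no elution")


class TestRetentionLaw:
    def test_zero_modifier_returns_k0(self):
        assert k_of_phi(RetentionModel(k0=100, S=10), 0.0) == pytest.approx(100.0)

    def test_nonpositive_slope_rejected_at_construction(self):
        with pytest.raises(ValueError):
            RetentionModel(k0=100, S=0.0)
        with pytest.raises(ValueError):
            RetentionModel(k0=-1, S=10)

    @pytest.mark.parametrize(
        "k0,S,S2,phi",
        [(100.0, 10.0, 0.0, 0.2), (5.0, 25.0, 0.0, 0.73), (50.0, 12.0, 4.0, 0.4)],
    )
    def test_matches_direct_arithmetic(self, k0, S, S2, phi):
        kind = "quadratic" if S2 else "lss"
        model = RetentionModel(k0=k0, S=S, S2=S2, model_kind=kind)
        expected = k0 * math.exp(-S * phi + S2 * phi * phi)
        assert k_of_phi(model, phi) == pytest.approx(expected, abs=1e-12)


class TestRetentionTime:
    def test_isocratic_closed_form(self, no_dwell_instrument):
        """Isocratic elution follows tR = t0 * (1 + k)."""
        model = RetentionModel(k0=10, S=5)
        t_r = predict_retention_time(model, isocratic_program(0.2), no_dwell_instrument)
        assert t_r == pytest.approx(1.0 * (1 + 10 * math.exp(-1.0)), abs=1e-9)

    def test_unretained_limit_never_below_dead_time(self, instrument):
        model = RetentionModel(k0=1e-6, S=5)
        t_r = predict_retention_time(model, linear_program(20.0), instrument)
        assert t_r >= instrument.t0
        assert t_r == pytest.approx(instrument.t0, rel=1e-4)

    def test_agrees_with_quadrature_oracle(self, budget):
        rng = np.random.default_rng(99)
        for _ in range(100):
            prog = random_candidate(rng, budget)
            model = RetentionModel(k0=10 ** rng.uniform(0.5, 4), S=rng.uniform(5, 40))
            inst = InstrumentConfig(t0=rng.uniform(0.3, 2.0), tD=rng.uniform(0.0, 1.0))
            closed = predict_retention_time(model, prog, inst)
            oracle = quadrature_retention_time(model, prog, inst)
            assert abs(closed - oracle) < 1e-6

    def test_quadratic_law_agrees_with_quadrature(self, budget):
        rng = np.random.default_rng(5)
        for _ in range(25):
            prog = random_candidate(rng, budget)
            model = RetentionModel(
                k0=10 ** rng.uniform(1, 3),
                S=rng.uniform(8, 30),
                S2=rng.uniform(-5, 5),
                model_kind="quadratic",
            )
            inst = InstrumentConfig(t0=1.0, tD=0.5)
            closed = predict_retention_time(model, prog, inst)
            oracle = quadrature_retention_time(model, prog, inst)
            assert abs(closed - oracle) < 1e-6

    def test_stronger_eluent_elutes_no_later(self, budget):
        """Raising every composition by a common delta can only speed elution."""
        rng = np.random.default_rng(17)
        inst = InstrumentConfig(t0=1.0, tD=0.5)
        for _ in range(50):
            prog = random_candidate(rng, budget)
            headroom = 1.0 - prog.phis[-1]
            delta = rng.uniform(0.0, headroom) if headroom > 0 else 0.0
            shifted = GradientProgram(
                phis=tuple(min(p + delta, 1.0) for p in prog.phis),
                holds=prog.holds,
                ramps=prog.ramps,
            )
            model = RetentionModel(k0=10 ** rng.uniform(1, 3.5), S=rng.uniform(5, 40))
            assert (
                predict_retention_time(model, shifted, inst)
                <= predict_retention_time(model, prog, inst) + 1e-9
            )


class TestPeakWidth:
    def test_floor_applies_when_plates_are_huge(self, instrument):
        model = RetentionModel(k0=50, S=10)
        w = predict_peak_width(model, PlateEstimate(N=1e9), linear_program(20.0), instrument)
        assert w == 0.3

    def test_arithmetic_below_floor_is_floored(self, no_dwell_instrument):
        """w_model = 4*t0/sqrt(N)*(1+k_e): 4*1/100*5 = 0.2, floored to 0.3."""
        # isocratic at phi with k = 4 exactly: pick phi so k0*exp(-S*phi) = 4
        model = RetentionModel(k0=10, S=5)
        phi = math.log(10 / 4) / 5
        prog = isocratic_program(phi)
        w_unfloored = predict_peak_width(
            model, PlateEstimate(N=10_000), prog, no_dwell_instrument, floor=0.0
        )
        assert w_unfloored == pytest.approx(0.2, abs=1e-9)
        w = predict_peak_width(model, PlateEstimate(N=10_000), prog, no_dwell_instrument)
        assert w == 0.3

    def test_width_non_increasing_in_plate_number(self, instrument):
        model = RetentionModel(k0=200, S=15)
        prog = linear_program(30.0)
        widths = [
            predict_peak_width(model, PlateEstimate(N=n), prog, instrument, floor=0.0)
            for n in (1e3, 1e4, 1e5, 1e6)
        ]
        assert all(a >= b for a, b in zip(widths, widths[1:]))


class TestPlateEstimation:
    def make_width_observations(self, model, inst, n_true, programs):
        return [
            (p, predict_peak_width(model, PlateEstimate(N=n_true), p, inst, floor=0.0))
            for p in programs
        ]

    def test_recovers_known_plate_number(self, instrument):
        model = RetentionModel(k0=300, S=18)
        programs = [linear_program(r) for r in (10.0, 30.0, 90.0)]
        obs = self.make_width_observations(model, instrument, 20_000, programs)
        est = estimate_plate_number(obs, model, instrument)
        assert est.N == pytest.approx(20_000, rel=0.01)
        assert not est.at_bound

    def test_single_observation_solves_exactly(self, instrument):
        model = RetentionModel(k0=300, S=18)
        obs = self.make_width_observations(model, instrument, 7_500, [linear_program(30.0)])
        est = estimate_plate_number(obs, model, instrument)
        assert est.N == pytest.approx(7_500, rel=1e-9)

    def test_all_widths_at_floor_returns_flagged_upper_bound(self, instrument):
        model = RetentionModel(k0=300, S=18)
        obs = [(linear_program(r), 0.3) for r in (10.0, 30.0, 90.0)]
        est = estimate_plate_number(obs, model, instrument, floor=0.3)
        assert est.at_bound
        assert est.N == 1e7

    def test_no_observations_is_an_error(self, instrument):
        with pytest.raises(ValueError):
            estimate_plate_number([], RetentionModel(k0=10, S=5), instrument)


class TestModelFitting:
    SCOUTS = [linear_program(r) for r in (10.0, 30.0, 90.0)]

    def observations(self, model, inst, noise_sd=0.0, rng=None):
        obs = []
        for prog in self.SCOUTS:
            t_r = predict_retention_time(model, prog, inst)
            if noise_sd:
                t_r += rng.normal(0.0, noise_sd)
            obs.append((prog, t_r))
        return obs

    def test_noiseless_recovery(self, instrument):
        truth = RetentionModel(k0=50, S=8)
        fit = fit_retention_model(
            self.observations(truth, instrument), instrument, rng=np.random.default_rng(0)
        )
        assert fit.k0 == pytest.approx(50, rel=1e-3)
        assert fit.S == pytest.approx(8, rel=1e-3)
        assert fit.sse < 1e-8
        assert not fit.ill_conditioned

    def test_noisy_recovery_median_within_five_percent(self, instrument):
        """sigma = 0.02 min of retention noise leaves S recoverable."""
        truth = RetentionModel(k0=200, S=15)
        rng = np.random.default_rng(1234)
        rel_errors = []
        for _ in range(100):
            fit = fit_retention_model(
                self.observations(truth, instrument, noise_sd=0.02, rng=rng),
                instrument,
                rng=rng,
                n_starts=5,
            )
            rel_errors.append(abs(fit.S - truth.S) / truth.S)
        assert np.median(rel_errors) < 0.05

    def test_duplicate_observations_flagged_ill_conditioned(self, instrument):
        truth = RetentionModel(k0=50, S=8)
        prog = self.SCOUTS[0]
        t_r = predict_retention_time(truth, prog, instrument)
        fit = fit_retention_model(
            [(prog, t_r), (prog, t_r)], instrument, rng=np.random.default_rng(0)
        )
        assert fit.ill_conditioned

    def test_too_few_observations_is_an_error(self, instrument):
        with pytest.raises(ValueError):
            fit_retention_model(
                [(self.SCOUTS[0], 5.0)], instrument, rng=np.random.default_rng(0)
            )

    def test_fit_invariant_to_observation_order_and_reproducible(self, instrument):
        truth = RetentionModel(k0=120, S=22)
        obs = self.observations(truth, instrument)
        fit_a = fit_retention_model(obs, instrument, rng=np.random.default_rng(77))
        fit_b = fit_retention_model(obs[::-1], instrument, rng=np.random.default_rng(77))
        fit_c = fit_retention_model(obs, instrument, rng=np.random.default_rng(77))
        assert fit_a.sse == fit_c.sse and fit_a.k0 == fit_c.k0
        assert fit_a.k0 == pytest.approx(fit_b.k0, rel=1e-6)


class TestFastKernelEquivalence:
    def test_batch_kernel_matches_scalar_route(self, budget):
        """The compiled optimizer kernel and the public scalar API are the
        same computation."""
        from autolc import _fast

        rng = np.random.default_rng(31)
        inst = InstrumentConfig(t0=1.0, tD=0.5)
        k0s = 10 ** rng.uniform(0.5, 4, size=8)
        ss = rng.uniform(5, 40, size=8)
        ns = rng.uniform(5e3, 5e4, size=8)
        for _ in range(25):
            prog = random_candidate(rng, budget)
            vec = _fast.repair16(prog.free_parameters(), budget.t_max)
            t_r, widths = _fast.predict_peaks16(vec, k0s, ss, ns, 1.0, 0.5, 1.0, 0.3, False)
            for i in range(8):
                model = RetentionModel(k0=float(k0s[i]), S=float(ss[i]))
                assert predict_retention_time(model, prog, inst) == pytest.approx(
                    t_r[i], abs=1e-9
                )
                assert predict_peak_width(
                    model, PlateEstimate(N=float(ns[i])), prog, inst
                ) == pytest.approx(widths[i], abs=1e-9)
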