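"""Single-cycle SPR model, global fitting and SAR arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from compskit import spr


class TestEquilibriumResponse:
    def test_half_saturation_at_kd(self):
        p = spr.KineticParameters(1e6, 1e-3, 100.0)
        assert spr.equilibrium_response(p.kd_equilibrium, p) == pytest.approx(50.0)

    def test_zero_concentration(self):
        p = spr.KineticParameters(1e6, 1e-3, 100.0)
        assert spr.equilibrium_response(0.0, p) == 0.0

    def test_closed_form_value(self):
        # 9 nM analyte at K_D = 1 nM occupies 90% of a 100 RU surface
        p = spr.KineticParameters(1e6, 1e-3, 100.0)
        assert spr.equilibrium_response(9e-9, p) == pytest.approx(90.0)

    def test_rejects_non_finite(self):
        p = spr.KineticParameters(1e6, 1e-3, 100.0)
        with pytest.raises(ValueError):
            spr.equilibrium_response(float("nan"), p)
        with pytest.raises(ValueError):
            spr.equilibrium_response(-1e-9, p)

    @given(
        kd_scale=st.floats(0.1, 100.0),
        c_nm=st.floats(0.01, 1000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_increasing_kd_lowers_occupancy(self, kd_scale, c_nm):
        p_lo = spr.KineticParameters(1e6, 1e-3 * kd_scale, 100.0)
        p_hi = spr.KineticParameters(1e6, 1e-3 * kd_scale * 2.0, 100.0)
        c = c_nm * 1e-9
        assert spr.equilibrium_response(c, p_hi) < spr.equilibrium_response(c, p_lo)


class TestSimulatePhase:
    def test_dissociation_half_life(self, cp40_params):
        p = spr.KineticParameters(1e6, 1e-3, 100.0)
        half_life = math.log(2) / p.k_d
        _, r = spr.simulate_phase(100.0, 0.0, p, duration=half_life, dt=half_life / 4)
        assert r[-1] == pytest.approx(50.0, rel=1e-9)

    def test_equilibrium_is_fixed_point(self, cp40_params):
        r_eq = spr.equilibrium_response(10e-9, cp40_params)
        _, r = spr.simulate_phase(r_eq, 10e-9, cp40_params, 300.0, 1.0)
        assert np.allclose(r, r_eq)

    @pytest.mark.parametrize("c,r0", [(10e-9, 0.0), (0.0, 40.0), (2.5e-9, 12.0)])
    def test_matches_numerical_ode_integration(self, cp40_params, c, r0):
        """Analytic solution agrees with a generic ODE integrator to <1e-6 RU."""
        p = cp40_params
        t, analytic = spr.simulate_phase(r0, c, p, 120.0, 1.0)
        sol = solve_ivp(
            lambda _t, y: p.k_a * c * (p.r_max - y) - p.k_d * y,
            (0, 120.0),
            [r0],
            t_eval=t,
            rtol=1e-11,
            atol=1e-12,
        )
        assert np.max(np.abs(sol.y[0] - analytic)) < 1e-6


class TestSimulateSingleCycle:
    def test_noiseless_single_segment_equals_phase(self, cp40_params):
        sched = spr.InjectionSchedule(((10e-9, 120.0, 60.0),), 600.0, dt=1.0)
        gram = spr.simulate_single_cycle(sched, cp40_params)
        _, phase = spr.simulate_phase(0.0, 10e-9, cp40_params, 120.0, 1.0)
        assert np.allclose(gram.response[:121], phase)

    def test_stepwise_rise_and_decay(self, schedule, cp40_params):
        """Response rises during every contact and decays between contacts,
        matching the sign of dR/dt from the closed form."""
        gram = spr.simulate_single_cycle(schedule, cp40_params)
        t0 = 0.0
        for conc, duration in schedule.phases():
            sl = (gram.time > t0) & (gram.time <= t0 + duration)
            seg = gram.response[sl]
            if seg.size >= 2:
                diffs = np.diff(seg)
                if conc > 0:
                    assert np.all(diffs > 0)
                else:
                    assert np.all(diffs < 0)
            t0 += duration

    def test_seed_determinism(self, schedule, cp40_params):
        g1 = spr.simulate_single_cycle(schedule, cp40_params, noise_sd=0.5, seed=11)
        g2 = spr.simulate_single_cycle(schedule, cp40_params, noise_sd=0.5, seed=11)
        assert np.array_equal(g1.response, g2.response)
        g3 = spr.simulate_single_cycle(schedule, cp40_params, noise_sd=0.5, seed=12)
        assert not np.array_equal(g1.response, g3.response)

    def test_noise_requires_seed(self, schedule, cp40_params):
        with pytest.raises(ValueError):
            spr.simulate_single_cycle(schedule, cp40_params, noise_sd=0.5)


class TestScheduleValidation:
    def test_concentrations_must_increase(self):
        with pytest.raises(ValueError):
            spr.InjectionSchedule(((10e-9, 120, 60), (5e-9, 120, 60)))

    def test_positive_durations(self):
        with pytest.raises(ValueError):
            spr.InjectionSchedule(((10e-9, 0.0, 60),))


class TestFitSingleCycle:
    @pytest.mark.parametrize("kd_nm", [0.1, 0.7, 5.0, 100.0])
    def test_noiseless_round_trip(self, schedule, kd_nm):
        """Parameter recovery to <0.1% across the 0.1-100 nM affinity range."""
        truth = spr.KineticParameters(1.0e6, kd_nm * 1e-9 * 1.0e6, 50.0)
        gram = spr.simulate_single_cycle(schedule, truth)
        fit = spr.fit_single_cycle(gram, schedule)
        assert fit.converged
        assert fit.parameters.k_a == pytest.approx(truth.k_a, rel=1e-3)
        assert fit.parameters.k_d == pytest.approx(truth.k_d, rel=1e-3)
        assert fit.parameters.r_max == pytest.approx(truth.r_max, rel=1e-3)
        assert fit.k_D == fit.parameters.k_d / fit.parameters.k_a

    def test_flat_trace_raises_no_binding(self, schedule):
        t = np.arange(0.0, schedule.total_duration, schedule.dt)
        gram = spr.Sensorgram(t, np.zeros_like(t))
        with pytest.raises(spr.NoBindingSignalError):
            spr.fit_single_cycle(gram, schedule)

    def test_pure_noise_raises_no_binding(self, schedule):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, schedule.total_duration, schedule.dt)
        gram = spr.Sensorgram(t, rng.normal(0, 0.5, t.size))
        with pytest.raises(spr.NoBindingSignalError):
            spr.fit_single_cycle(gram, schedule)

    def test_monte_carlo_kd_bias(self, cp40_params):
        """Median relative bias of the dissociation rate stays below 5%
        under 0.5 RU Gaussian noise."""
        sched = spr.InjectionSchedule.single_cycle(dt=5.0)
        rel_errors = []
        for seed in range(50):
            gram = spr.simulate_single_cycle(
                sched, cp40_params, noise_sd=0.5, seed=seed
            )
            fit = spr.fit_single_cycle(gram, sched)
            rel_errors.append(
                (fit.parameters.k_d - cp40_params.k_d) / cp40_params.k_d
            )
        assert abs(float(np.median(rel_errors))) < 0.05


class TestDeriveKd:
    @pytest.mark.parametrize(
        "ka,kd,expected_nm",
        [
            (2.8e6, 1.4e-3, 0.5),  # reported lead-compound profile
            (1e6, 1e-3, 1.0),
            (1.0e6, 0.7e-3, 0.7),  # replicate means; printed K_D 0.8 +/- 0.2
        ],
    )
    def test_ratio(self, ka, kd, expected_nm):
        assert spr.derive_kd(ka, kd) * 1e9 == pytest.approx(expected_nm)

    def test_guards_nonpositive_ka(self):
        with pytest.raises(ValueError):
            spr.derive_kd(0.0, 1e-3)


class TestFoldChange:
    @pytest.mark.parametrize(
        "variant,ref,expected",
        [(19.2, 0.8, 24), (5.6, 0.8, 7), (6.2, 0.8, 8), (9.9, 0.8, 12)],
    )
    def test_integer_rounding(self, variant, ref, expected):
        assert spr.fold_change(variant, ref, "integer") == expected

    def test_identity(self):
        assert spr.fold_change(3.3, 3.3) == 1.0

    def test_half_up(self):
        assert spr.fold_change(2.5, 1.0, "integer") == 3  # 2.5 rounds up
        assert spr.fold_change(1.25, 1.0, "one_decimal") == 1.3


class TestSummarizeReplicates:
    def _fit(self, ka, kd):
        return spr.FitResult(
            parameters=spr.KineticParameters(ka, kd, 50.0),
            residual_norm=0.0,
            stderr={},
            converged=True,
            n_points=100,
        )

    def test_mean_and_sd(self):
        # K_D values 0.6, 0.8, 1.0 nM at fixed k_a
        fits = [self._fit(1e6, kd_nm * 1e-9 * 1e6) for kd_nm in (0.6, 0.8, 1.0)]
        rec = spr.summarize_replicates(fits, "X")
        assert rec.kd_nm_mean == pytest.approx(0.8)
        assert rec.kd_nm_sd == pytest.approx(0.2)
        assert rec.n_replicates == 3

    def test_identical_fits_zero_sd(self):
        fits = [self._fit(1e6, 7e-4)] * 3
        rec = spr.summarize_replicates(fits, "X")
        assert rec.kd_nm_sd == 0.0 and rec.ka_sd == 0.0

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning):
            rec = spr.summarize_replicates([self._fit(1e6, 7e-4)], "X")
        assert rec.single_replicate and rec.kd_nm_sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spr.summarize_replicates([], "X")


class TestIsoaffinity:
    def _record(self, name, ka_1e6, kdiss_1e3):
        return spr.SARRecord(
            compound=name, position="", n_replicates=3,
            kd_nm_mean=kdiss_1e3 * 1e-3 / (ka_1e6 * 1e6) * 1e9, kd_nm_sd=0.0,
            ka_mean=ka_1e6, ka_sd=0.0, kdiss_mean=kdiss_1e3, kdiss_sd=0.0,
            kd_nm_ratio_of_means=0.0,
        )

    def test_lead_compound_coordinates(self):
        pts = spr.isoaffinity_points([self._record("Cp40", 1.0, 0.7)])
        assert pts.loc[0, "log10_ka"] == pytest.approx(6.0)
        assert pts.loc[0, "log10_kd"] == pytest.approx(math.log10(0.7e-3))

    def test_equal_kd_records_on_one_diagonal(self):
        pts = spr.isoaffinity_points(
            [self._record("a", 1.0, 0.7), self._record("b", 2.0, 1.4)]
        )
        offsets = pts["log10_kd"] - pts["log10_ka"]
        assert offsets.nunique() == 1 or np.allclose(offsets, offsets.iloc[0])

    def test_empty_input(self):
        assert spr.isoaffinity_points([]).empty

    def test_diagonals(self):
        lines = spr.isoaffinity_diagonals([1.0], (5.0, 7.0))
        # on a log-log plot the iso-K_D line has unit slope
        y = lines["log10_kd"].to_numpy()
        x = lines["log10_ka"].to_numpy()
        assert (y[1] - y[0]) / (x[1] - x[0]) == pytest.approx(1.0)


class TestCsvRoundTrip:
    def test_sensorgram_csv(self, tmp_path, schedule, cp40_params):
        gram = spr.simulate_single_cycle(schedule, cp40_params, 0.5, seed=5)
        path = tmp_path / "gram.csv"
        gram.to_csv(path)
        back = spr.Sensorgram.from_csv(path)
        assert np.allclose(back.time, gram.time)
        assert np.allclose(back.response, gram.response)
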