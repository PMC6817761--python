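"""Arrhenius mapping, recovery-curve fitting, grid search, tau_1 estimation."""

import numpy as np
import pytest

from methylrelax import (
    ArrheniusParams,
    BracketError,
    InvalidParameterError,
    MethylGeometry,
    MotionState,
    RecoverySolution,
    arrhenius_regression,
    fit_multiexponential,
    fit_tau1_fixed_bath,
    fit_tau1_series,
    generate_recovery_curve,
    generate_temperature_series,
    grid_search,
    predict_alpha_curve,
    recovery_solution,
    tau_from_temperature,
)
from methylrelax.constants import R_GAS_KCAL
from methylrelax.synthetic import default_sampling_times


class TestArrheniusLaw:
    def test_known_value(self, arrhenius_full):
        assert tau_from_temperature(arrhenius_full, 268.0) == pytest.approx(1.787e-10, rel=1e-3)

    def test_high_temperature_limit_is_prefactor(self):
        p = ArrheniusParams(ea=3.5, tau0=2.5e-13)
        assert p.tau(1e9) == pytest.approx(2.5e-13, rel=1e-6)

    def test_temperature_ratio_closed_form(self, arrhenius_full):
        ratio = arrhenius_full.tau(149.0) / arrhenius_full.tau(268.0)
        expected = np.exp((3.5 / R_GAS_KCAL) * (1 / 149.0 - 1 / 268.0))
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_temperature(self, arrhenius_full):
        temps = np.linspace(100, 400, 50)
        assert np.all(np.diff(arrhenius_full.tau(temps)) < 0)

    def test_rejects_nonpositive_temperature(self, arrhenius_full):
        with pytest.raises(InvalidParameterError):
            arrhenius_full.tau(0.0)


class TestMultiExponentialFit:
    def test_noiseless_biexponential_round_trip(self):
        # rates of the 268 K methyl recovery
        truth = RecoverySolution(rates=np.array([6.3, 0.45]),
                                 amplitudes=np.array([0.6, 0.4]))
        ds = generate_recovery_curve(truth, np.geomspace(1e-3, 12.0, 16))
        fit = fit_multiexponential(ds, 2)
        assert fit.rss < 1e-10
        assert fit.m0 == pytest.approx(1.0, abs=1e-6)
        assert fit.rates == pytest.approx([6.3, 0.45], rel=1e-5)
        assert fit.alpha == pytest.approx(0.6, abs=1e-5)

    def test_noiseless_triexponential_round_trip(self):
        truth = RecoverySolution(rates=np.array([7.5, 1.2, 0.81]),
                                 amplitudes=np.array([0.61, -0.002, 0.392]))
        ds = generate_recovery_curve(truth, np.geomspace(1e-3, 20.0, 24))
        fit = fit_multiexponential(ds, 3)
        assert fit.rss < 1e-8

    def test_single_exponential_data_flagged_degenerate_with_two_components(self):
        truth = RecoverySolution(rates=np.array([2.0]), amplitudes=np.array([1.0]))
        ds = generate_recovery_curve(truth, np.geomspace(1e-3, 5.0, 16))
        fit = fit_multiexponential(ds, 2)
        assert fit.degenerate
        assert min(fit.alpha, 1 - fit.alpha) < 0.05 or \
            abs(fit.rates[0] - fit.rates[1]) / fit.rates[0] < 0.05

    def test_insufficient_points_rejected(self):
        truth = RecoverySolution(rates=np.array([2.0]), amplitudes=np.array([1.0]))
        ds = generate_recovery_curve(truth, np.geomspace(1e-2, 3.0, 6))
        with pytest.raises(InvalidParameterError):
            fit_multiexponential(ds, 2)

    def test_monte_carlo_alpha_unbiased(self):
        # 1% noise: the mean recovered alpha should sit within 2 SE of truth
        truth = RecoverySolution(rates=np.array([6.3, 0.45]),
                                 amplitudes=np.array([0.6, 0.4]))
        times = np.geomspace(1e-3, 12.0, 16)
        alphas = []
        for seed in range(200):
            ds = generate_recovery_curve(truth, times, noise_sigma=0.01, seed=seed)
            alphas.append(fit_multiexponential(ds, 2).alpha)
        alphas = np.array(alphas)
        se = alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert abs(alphas.mean() - 0.6) < 2 * se + 1e-4


class TestGridSearch:
    def test_recovers_generating_parameters(self, geom, field800):
        truth = {"n_b": 1.7, "sigma": 1.3, "s2": 0.94, "tau1": 5e-9}
        sol = recovery_solution(geom.with_s2(truth["s2"]), field800,
                                MotionState(truth["tau1"]),
                                n_b=truth["n_b"], sigma=truth["sigma"])
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        res = grid_search(ds, geom, field800)
        assert res.n_b == pytest.approx(truth["n_b"], rel=0.02)
        assert res.sigma == pytest.approx(truth["sigma"], rel=0.02)
        assert res.s2 == pytest.approx(truth["s2"], abs=0.005)
        assert res.tau1 == pytest.approx(truth["tau1"], rel=0.02)
        # definitional invariant: returned objective is the grid minimum
        assert res.objective <= res.ledger["objective"].min() + 1e-30

    def test_sigma_zero_selected_for_isolated_methyl(self, geom, field800):
        # data generated without any spin-diffusion sink: a sigma grid that
        # contains 0 must select it (exact-zero residual), and the boundary
        # location is reported
        sol = recovery_solution(geom.with_s2(0.93), field800, MotionState(4e-10),
                                n_b=1.6, sigma=0.0)
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        with pytest.warns(UserWarning, match="boundary"):
            res = grid_search(ds, geom, field800,
                              grids={"n_b": np.array([1.6]),
                                     "sigma": np.linspace(0.0, 2.0, 5),
                                     "s2": np.array([0.93]),
                                     "tau1": np.array([1e-10, 4e-10, 1.6e-9])},
                              polish=False, n_starts=1, n_refine=0)
        assert res.sigma == 0.0
        assert res.tau1 == 4e-10
        assert res.objective < 1e-25

    def test_empty_grid_rejected(self, geom, field800):
        sol = recovery_solution(geom, field800, MotionState(1e-9), n_b=1.6, sigma=0.9)
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        with pytest.raises(InvalidParameterError):
            grid_search(ds, geom, field800, grids={"n_b": np.array([])})


class TestTau1Estimation:
    def test_round_trip_with_side_flag(self, geom93, field800):
        sol = recovery_solution(geom93, field800, MotionState(1e-9), n_b=1.6, sigma=0.9)
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        est = fit_tau1_fixed_bath(ds, geom93, field800)
        assert est.tau1 == pytest.approx(1e-9, rel=0.02)
        assert est.side == "fast"  # 1 ns lies below the rate-maximizing tau

    def test_slow_side_round_trip(self, geom93, field800):
        sol = recovery_solution(geom93, field800, MotionState(2e-8), n_b=1.6, sigma=0.9)
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        est = fit_tau1_fixed_bath(ds, geom93, field800)
        assert est.tau1 == pytest.approx(2e-8, rel=0.02)
        assert est.side == "slow"

    def test_bracket_failure_reported(self, geom93, field800):
        sol = recovery_solution(geom93, field800, MotionState(1e-9), n_b=1.6, sigma=0.9)
        ds = generate_recovery_curve(sol, default_sampling_times(sol))
        with pytest.raises(BracketError):
            fit_tau1_fixed_bath(ds, geom93, field800, tau_bounds=(1e-12, 1e-11))

    def test_series_resolution_enforces_monotonicity(self, geom93, field800,
                                                     arrhenius_full):
        dss = generate_temperature_series(geom93, field800, arrhenius_full, seed=11)
        ests = fit_tau1_series(dss, geom93, field800)
        by_temp = sorted(zip([d.temperature for d in dss], [e.tau1 for e in ests]),
                         reverse=True)
        taus = [t for _, t in by_temp]
        assert np.all(np.diff(taus) > 0)


class TestArrheniusRegression:
    def test_exact_recovery_on_noiseless_points(self):
        p = ArrheniusParams(ea=3.05, tau0=1.3e-12)
        temps = np.array([268.0, 233.0, 198.0, 178.0, 149.0])
        fit = arrhenius_regression(temps, p.tau(temps))
        assert fit.ea == pytest.approx(3.05, rel=1e-10)
        assert fit.tau0 == pytest.approx(1.3e-12, rel=1e-10)
        assert fit.ea_stderr == pytest.approx(0.0, abs=1e-8)

    def test_requires_three_distinct_points(self):
        with pytest.raises(InvalidParameterError):
            arrhenius_regression([268.0, 233.0], [1e-10, 5e-10])
        with pytest.raises(InvalidParameterError):
            arrhenius_regression([268.0, 268.0, 233.0], [1e-10, 1e-10, 5e-10])

    def test_lognormal_noise_bias_below_two_percent(self):
        p = ArrheniusParams(ea=3.5, tau0=2.5e-13)
        temps = np.array([268.0, 233.0, 198.0, 178.0, 149.0])
        tau_true = p.tau(temps)
        rng = np.random.default_rng(4242)
        eas = [arrhenius_regression(temps, tau_true * rng.lognormal(0, 0.1, 5)).ea
               for _ in range(500)]
        assert abs(np.mean(eas) / 3.5 - 1) < 0.02


class TestPredictAlphaCurve:
    def test_spin_diffusion_model_amplitudes(self, geom93, field800, arrhenius_full):
        table = predict_alpha_curve(geom93, field800, arrhenius_full,
                                    n_b=1.6, sigma=0.9,
                                    temperatures=[268.0, 149.0])
        assert table["alpha"].iloc[0] == pytest.approx(0.58, abs=0.05)
        assert table["alpha"].iloc[1] == pytest.approx(0.23, abs=0.05)

    def test_isolated_model_amplitude_at_268(self, geom, field800, arrhenius_simple):
        table = predict_alpha_curve(geom, field800, arrhenius_simple,
                                    n_b=1.6, sigma=0.0, temperatures=[268.0])
        assert table["alpha"].iloc[0] == pytest.approx(0.85, abs=0.03)

    def test_alpha_in_unit_interval_and_rates_ordered(self, geom93, field800,
                                                      arrhenius_full):
        table = predict_alpha_curve(geom93, field800, arrhenius_full,
                                    temperatures=np.linspace(140, 280, 15))
        assert ((table["alpha"] > 0) & (table["alpha"] < 1)).all()
        assert (table["lambda_fast"] > table["lambda_slow"]).all()

    def test_fast_rate_peaks_near_inverse_carbon_frequency(self, geom93, field800,
                                                           arrhenius_full):
        temps = np.linspace(150, 270, 61)
        table = predict_alpha_curve(geom93, field800, arrhenius_full, temperatures=temps)
        t_peak = table.loc[table["lambda_fast"].idxmax()]
        # at the T1 minimum, tau_1 ~ 1/omega_C (ns timescale)
        assert t_peak["tau1_s"] == pytest.approx(1.0 / field800.omega_s, rel=0.6)


class TestPipelineRoundTrip:
    def test_noiseless_pipeline_recovers_arrhenius_parameters(
            self, geom93, field800, arrhenius_full):
        dss = generate_temperature_series(geom93, field800, arrhenius_full)
        ests = fit_tau1_series(dss, geom93, field800)
        fit = arrhenius_regression([d.temperature for d in dss],
                                   [e.tau1 for e in ests])
        assert fit.ea == pytest.approx(3.5, rel=0.01)
        assert fit.tau0 == pytest.approx(2.5e-13, rel=0.01)
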