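"""Monod/Haldane regression and time-course parameter estimation."""

import math

import numpy as np
import pytest

from clostkin.bayes_mcmc import McmcConfig
from clostkin.ferm_kinetics import FermentationState, KineticParams, specific_growth_rate
from clostkin.model_fitting import (
    GrowthRatePoint,
    MonodFit,
    TimeCourseFitSpec,
    fit_diagnostics,
    fit_haldane,
    fit_monod,
    fit_timecourse,
    ssq_timecourse,
)
from clostkin.synthetic_data import NoiseModel, generate_timecourse


def monod(theta1, theta2, s):
    return theta1 * s / (theta2 + s)


def make_points(svals, yvals):
    return [GrowthRatePoint(S=s, mu_obs=y) for s, y in zip(svals, yvals)]


class TestFitMonod:
    def test_zero_noise_recovery_to_4_decimals(self):
        theta = (0.48, 25.0)
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 120.0, 160.0])
        data = make_points(s, monod(*theta, s))
        fit = fit_monod(data)
        assert fit.theta1 == pytest.approx(theta[0], abs=1e-4)
        assert fit.theta2 == pytest.approx(theta[1], abs=1e-4)
        assert fit.ssq < 1e-10

    def test_matches_two_point_closed_form(self):
        # exact double-reciprocal solve from two distinct substrate levels:
        # 1/y = 1/t1 + (t2/t1)/s is a line in 1/s
        s = np.array([5.0, 50.0, 50.0])
        y = monod(0.6, 12.0, s)
        inv_slope, inv_icept = np.polyfit(1 / s[:2], 1 / y[:2], 1)
        t1_closed = 1 / inv_icept
        t2_closed = inv_slope * t1_closed
        fit = fit_monod(make_points(s, y))
        assert fit.theta1 == pytest.approx(t1_closed, rel=1e-5)
        assert fit.theta2 == pytest.approx(t2_closed, rel=1e-5)

    def test_descent_from_start(self):
        rng = np.random.default_rng(0)
        s = np.array([3.0, 6.0, 12.0, 25.0, 50.0])
        y = monod(0.5, 8.0, s) * (1 + 0.05 * rng.standard_normal(5))
        start = (0.9, 30.0)
        fit = fit_monod(make_points(s, y), start=start)
        ssq_start = float(np.sum((y - monod(*start, s)) ** 2))
        assert fit.ssq <= ssq_start

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(5)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            s = np.array([2.0, 4.0, 8.0, 16.0, 32.0, 64.0])
            y = monod(0.45, 10.0, s) * (1 + 0.03 * rng.standard_normal(6))
            fit = fit_monod(make_points(s, y))
            g1 = np.linspace(0.1, 1.0, 400)
            g2 = np.linspace(1.0, 40.0, 400)
            pred = g1[:, None, None] * s / (g2[None, :, None] + s)
            ssq = ((y - pred) ** 2).sum(axis=2)
            i, j = np.unravel_index(np.argmin(ssq), ssq.shape)
            cell1 = g1[1] - g1[0]
            cell2 = g2[1] - g2[0]
            assert abs(fit.theta1 - g1[i]) <= cell1
            assert abs(fit.theta2 - g2[j]) <= cell2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_monod(make_points([1.0, 2.0], [0.1, 0.2]))  # too few points
        with pytest.raises(ValueError):
            fit_monod(make_points([5.0, 5.0, 5.0], [0.1, 0.1, 0.1]))  # one level
        with pytest.raises(ValueError):
            fit_monod(make_points([1.0, 2.0, 4.0], [0.0, 0.0, 0.0]))  # all zero


class TestFitHaldane:
    def test_zero_noise_recovery(self, table4_params):
        p = table4_params
        s = np.array([1, 2, 3, 5, 8, 12, 20, 30, 50, 75, 100, 150.0])
        y = np.array([specific_growth_rate(p, si, 0.0) for si in s])
        fit = fit_haldane(make_points(s, y))
        assert fit.theta1 == pytest.approx(p.mu_m, rel=1e-3)
        assert fit.theta2 == pytest.approx(p.K_S, rel=1e-3)
        assert fit.theta3 == pytest.approx(p.K_I, rel=1e-2)

    def test_predict_uses_inhibition_term(self):
        fit = MonodFit(theta1=0.5, theta2=2.0, ssq=0.0, n_points=5, theta3=200.0)
        s = np.array([100.0])
        expected = 0.5 * 100 / (100 + 2 + 100**2 / 200)
        assert fit.predict(s)[0] == pytest.approx(expected)


class TestSsqTimecourse:
    def test_zero_at_generating_parameters(self, table4_params, reference_initial):
        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 120, 13),
            NoiseModel(sigma=0.0),
        )
        assert ssq_timecourse(table4_params, obs) == pytest.approx(0.0, abs=1e-10)

    def test_linear_in_weights(self, table4_params, reference_initial):
        obs = generate_timecourse(
            table4_params.replace(mu_m=0.4), reference_initial,
            np.linspace(0, 60, 7), NoiseModel(sigma=0.0),
        )
        w1 = {"X": 1.0, "S": 0.1, "P_Ba": 0.5, "P_Aa": 2.0}
        w2 = {k: 2 * v for k, v in w1.items()}
        s1 = ssq_timecourse(table4_params, obs, weights=w1)
        assert ssq_timecourse(table4_params, obs, weights=w2) == pytest.approx(2 * s1)

    def test_perturbing_mu_m_increases_objective(self, table4_params, reference_initial):
        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 120, 13),
            NoiseModel(sigma=0.0),
        )
        base = ssq_timecourse(table4_params, obs)
        bumped = ssq_timecourse(table4_params.replace(mu_m=0.48 * 1.1), obs)
        assert bumped > base

    def test_equals_order_free_per_point_sum(self, table4_params, reference_initial):
        # the objective is a plain sum over (variable, time) cells, so it must
        # equal an independently accumulated per-cell total in any order
        from clostkin.ferm_kinetics import simulate_batch

        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 60, 7),
            NoiseModel(sigma=0.05, seed=8),
        )
        w = {"X": 1.0, "S": 2.0, "P_Ba": 3.0, "P_Aa": 4.0}
        total = ssq_timecourse(table4_params, obs, weights=w)
        sim = simulate_batch(table4_params, obs.initial, 60.0, obs.times,
                             rtol=1e-7, atol=1e-9)
        cells = []
        for i in range(len(obs.states)):
            for j, var in enumerate(["X", "S", "P_Ba", "P_Aa"]):
                r = obs.as_array()[i, j] - sim.as_array()[i, j]
                cells.append(w[var] * r * r)
        rng = np.random.default_rng(0)
        rng.shuffle(cells)
        assert total == pytest.approx(math.fsum(cells), rel=1e-9)

    def test_simulation_failure_returns_inf(self, reference_initial):
        bad = KineticParams().replace(mu_m=1e-7)
        obs = generate_timecourse(
            KineticParams(), reference_initial, np.linspace(0, 10, 3),
            NoiseModel(sigma=0.0),
        )
        # unsimulable horizon via empty observed table instead
        with pytest.raises(ValueError):
            ssq_timecourse(bad, obs.__class__(states=[], params_used=bad,
                                              initial=reference_initial))


class TestFitTimecourse:
    def test_all_fixed_returns_inputs_unchanged(self, table4_params, reference_initial):
        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 60, 7),
            NoiseModel(sigma=0.0),
        )
        spec = TimeCourseFitSpec(free_params=[], initial_state=reference_initial,
                                 fixed=table4_params)
        fit = fit_timecourse(obs, spec)
        assert fit.params == table4_params
        assert fit.estimates == {}
        assert fit.ssq == pytest.approx(0.0, abs=1e-10)

    def test_mu_m_recovery_from_noisy_data(self, table4_params, reference_initial):
        errs = []
        for seed in range(3):
            obs = generate_timecourse(
                table4_params, reference_initial, np.linspace(0, 120, 13),
                NoiseModel(sigma=0.02, seed=100 + seed),
            )
            spec = TimeCourseFitSpec(
                free_params=["mu_m"], initial_state=obs.initial,
                fixed=table4_params.replace(mu_m=0.3),
            )
            fit = fit_timecourse(obs, spec, method="simplex")
            errs.append(abs(fit.estimates["mu_m"] - table4_params.mu_m) / table4_params.mu_m)
        assert np.median(errs) <= 0.10

    def test_mcmc_agrees_with_simplex_on_identifiable_problem(
        self, table4_params, reference_initial
    ):
        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 72, 7),
            NoiseModel(sigma=0.02, seed=31),
        )
        spec = TimeCourseFitSpec(
            free_params=["mu_m", "P_d"], initial_state=obs.initial,
            fixed=table4_params,
            bounds={"mu_m": (0.1, 1.0), "P_d": (20.0, 100.0)},
        )
        simplex = fit_timecourse(obs, spec, method="simplex")
        cfg = McmcConfig(n_steps=1500, n_params=2, adapt_start=200,
                         adapt_interval=100, seed=13,
                         init_cov=np.diag([1e-4, 1.0]))
        mcmc = fit_timecourse(obs, spec, method="mcmc", mcmc_config=cfg)
        for name in ("mu_m", "P_d"):
            sd = mcmc.diagnostics["params"][name]["sd"]
            assert abs(mcmc.estimates[name] - simplex.estimates[name]) < 2 * max(sd, 1e-6)

    def test_bound_hit_reported(self, table4_params, reference_initial):
        obs = generate_timecourse(
            table4_params, reference_initial, np.linspace(0, 60, 7),
            NoiseModel(sigma=0.0),
        )
        # bounds exclude the generating value, so the optimum sits on a bound
        spec = TimeCourseFitSpec(
            free_params=["mu_m"], initial_state=obs.initial,
            fixed=table4_params.replace(mu_m=0.2),
            bounds={"mu_m": (0.1, 0.3)},
        )
        fit = fit_timecourse(obs, spec, method="simplex")
        assert "mu_m" in fit.at_bounds

    def test_unknown_free_parameter_rejected(self, table4_params, reference_initial):
        with pytest.raises(ValueError):
            TimeCourseFitSpec(free_params=["mu_max"], initial_state=reference_initial,
                              fixed=table4_params)


class TestFitDiagnostics:
    def test_residual_mean_square_arithmetic(self):
        # S_R = 0.0003 with n = 5 points and p = 2 parameters -> S_R/(n-p) = 0.0001
        fit = MonodFit(theta1=0.48, theta2=10.0, ssq=0.0003, n_points=5)
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
        data = make_points(s, monod(0.48, 10.0, s))
        rep = fit_diagnostics(fit, data)
        assert rep["residual_mean_square"] == pytest.approx(0.0001)
        assert rep["n"] == 5 and rep["p"] == 2

    def test_zero_residuals_degenerate_intervals(self):
        s = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
        y = monod(0.5, 8.0, s)
        fit = fit_monod(make_points(s, y))
        rep = fit_diagnostics(fit, make_points(s, y))
        for lo, hi in rep["ci95"].values():
            assert lo == pytest.approx(hi)

    def test_intervals_shrink_with_sample_size(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (10, 80):
            s = np.linspace(1, 60, n)
            y = monod(0.5, 8.0, s) + rng.normal(0, 0.01, n)
            fit = fit_monod(make_points(s, np.clip(y, 1e-6, None)))
            rep = fit_diagnostics(fit, make_points(s, np.clip(y, 1e-6, None)))
            lo, hi = rep["ci95"]["theta1"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_underdetermined_fit_rejected(self):
        fit = MonodFit(theta1=0.5, theta2=8.0, ssq=0.01, n_points=2)
        with pytest.raises(ValueError):
            fit_diagnostics(fit, make_points([1.0, 2.0], [0.1, 0.2]))
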