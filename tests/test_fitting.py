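"""Nonlinear least squares: dataset assembly, Gauss-Newton, correlations."""

import logging

import numpy as np
import pandas as pd
import pytest

from aphidrgr.fitting import (
    RegressionDataset,
    SingularJacobianWarning,
    build_dataset,
    fit_rgr_model,
    param_correlations,
    weekly_mean_temperature,
)
from aphidrgr.pipeline import estimate_all, simulate_region
from aphidrgr.surface import RGRParams, rgr_surface
from aphidrgr.synthetic import (
    NoiseParams,
    SeasonalParams,
    SimulationConfig,
    gen_temperature,
    recovery_design,
)

TRUE = RGRParams(s_m=45.0, a=0.012, b=1.2, k=0.35)
TRUE_VEC = np.array([45.0, 0.012, 1.2, 0.35])
NAMES = ["s_m", "a", "b", "k"]


def _dataset(theta, s, y, n_fields=16):
    n = len(y)
    per = int(np.ceil(n / n_fields))
    return RegressionDataset(
        rgr_obs=np.asarray(y, float),
        theta_weekly=np.asarray(theta, float),
        s_weekly=np.asarray(s, float),
        field_id=np.repeat([f"F{i:02d}" for i in range(n_fields)], per)[:n],
        date=pd.date_range("2000-05-01", periods=n, freq="D"),
    )


@pytest.fixture(scope="module")
def design():
    theta, s = recovery_design(160)
    return theta, s, rgr_surface(theta, s, TRUE)


class TestWeeklyMeanTemperature:
    def test_constant_week(self):
        temps = gen_temperature(
            "2001-05-01", 7,
            SeasonalParams(mean_level=12, amplitude=0, clip_max=None),
            NoiseParams(sd=0, year_sd=0),
        )
        out = weekly_mean_temperature(temps, [temps.dates[-1]])
        assert out[0] == pytest.approx(12.0)

    def test_hand_mean(self):
        temps = gen_temperature(
            "2001-05-01", 7,
            SeasonalParams(mean_level=0, amplitude=0, clip_max=None),
            NoiseParams(sd=0, year_sd=0),
        )
        temps.t_mean[:] = [10, 11, 12, 13, 14, 15, 16]
        temps.t_min[:] = temps.t_mean - 1
        temps.t_max[:] = temps.t_mean + 1
        assert weekly_mean_temperature(temps, [temps.dates[-1]])[0] == pytest.approx(13.0)

    def test_partial_window_warns_and_averages(self, caplog):
        temps = gen_temperature(
            "2001-05-04", 4,
            SeasonalParams(mean_level=8, amplitude=0, clip_max=None),
            NoiseParams(sd=0, year_sd=0),
        )
        with caplog.at_level(logging.WARNING):
            out = weekly_mean_temperature(temps, [temps.dates[-1]])
        assert out[0] == pytest.approx(8.0)
        assert any("4/7" in r.getMessage() for r in caplog.records)

    def test_empty_window_rejected(self):
        temps = gen_temperature("2001-05-01", 7, seed=0)
        with pytest.raises(ValueError, match="no temperature records"):
            weekly_mean_temperature(temps, [pd.Timestamp("2001-08-01")])


class TestBuildDataset:
    @pytest.fixture(scope="class")
    def two_fields(self):
        surveys, temps = simulate_region(SimulationConfig(seed=2), 2)
        rgr = estimate_all(surveys)
        return surveys, rgr, temps

    def test_record_count_full_coverage(self, two_fields):
        surveys, rgr, temps = two_fields
        data = build_dataset(surveys, rgr, temps)
        assert len(data) == sum(s.n_dates for s in surveys)

    def test_missing_weather_drops_record(self, two_fields, caplog):
        surveys, rgr, temps = two_fields
        from aphidrgr.synthetic import TemperatureSeries

        # truncate one weather series so the first sampling date lacks coverage
        t0 = temps[0]
        trimmed = TemperatureSeries(
            dates=t0.dates[7:], t_min=t0.t_min[7:], t_mean=t0.t_mean[7:], t_max=t0.t_max[7:]
        )
        with caplog.at_level(logging.WARNING):
            data = build_dataset(surveys, rgr, [trimmed, temps[1]])
        assert len(data) == sum(s.n_dates for s in surveys) - 1
        assert any("dropped 1" in r.getMessage() for r in caplog.records)

    def test_order_stable_under_field_permutation(self, two_fields):
        surveys, rgr, temps = two_fields
        a = build_dataset(surveys, rgr, temps)
        b = build_dataset(surveys[::-1], rgr[::-1], temps[::-1])
        assert np.array_equal(a.rgr_obs, b.rgr_obs)
        assert np.array_equal(a.field_id, b.field_id)

    def test_misaligned_inputs_rejected(self, two_fields):
        surveys, rgr, temps = two_fields
        with pytest.raises(ValueError, match="aligned"):
            build_dataset(surveys, rgr[:1], temps)


class TestFitRecovery:
    def test_zero_noise_truth_init_exact(self, design):
        theta, s, f_true = design
        fit = fit_rgr_model(_dataset(theta, s, f_true), init=TRUE)
        est = fit.params.free_values()
        assert np.all(np.abs(est / TRUE_VEC - 1) < 1e-6)
        assert fit.objective < 1e-20
        assert fit.converged

    def test_zero_noise_perturbed_init(self, design):
        """±20% perturbed start still lands on the truth (1e-4 relative);
        cross-checked against an independent derivative-free minimizer."""
        theta, s, f_true = design
        data = _dataset(theta, s, f_true)
        pert = TRUE.replace_free(TRUE_VEC * np.array([1.2, 0.8, 1.2, 0.8]))
        fit = fit_rgr_model(data, init=pert)
        assert np.all(np.abs(fit.params.free_values() / TRUE_VEC - 1) < 1e-4)

        from scipy.optimize import minimize

        def sse(x):
            try:
                p = TRUE.replace_free(x)
            except ValueError:
                return 1e6
            return float(np.sum((f_true - rgr_surface(theta, s, p)) ** 2))

        oracle = minimize(sse, pert.free_values(), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        assert fit.objective <= oracle.fun + 1e-12

    def test_objective_never_worse_than_start(self, design):
        theta, s, f_true = design
        rng = np.random.default_rng(0)
        y = f_true + rng.normal(0, 0.03, f_true.size)
        data = _dataset(theta, s, y)
        for fac in ([1.3, 0.7, 1.3, 0.7], [0.8, 1.4, 0.9, 1.5]):
            init = TRUE.replace_free(TRUE_VEC * np.array(fac))
            start_sse = float(np.sum((y - rgr_surface(theta, s, init)) ** 2))
            fit = fit_rgr_model(data, init=init)
            assert fit.objective <= start_sse

    def test_fit_invariant_to_record_order(self, design):
        theta, s, f_true = design
        rng = np.random.default_rng(1)
        y = f_true + rng.normal(0, 0.03, f_true.size)
        data = _dataset(theta, s, y)
        perm = rng.permutation(160)
        data_p = RegressionDataset(
            rgr_obs=y[perm], theta_weekly=theta[perm], s_weekly=s[perm],
            field_id=data.field_id[perm], date=data.date[perm],
        )
        a = fit_rgr_model(data).params.free_values()
        b = fit_rgr_model(data_p).params.free_values()
        assert np.allclose(a, b, rtol=1e-8)

    def test_lm_fallback_agrees(self, design):
        theta, s, f_true = design
        rng = np.random.default_rng(2)
        y = f_true + rng.normal(0, 0.03, f_true.size)
        data = _dataset(theta, s, y)
        gn = fit_rgr_model(data)
        lm = fit_rgr_model(data, method="lm")
        assert lm.objective <= gn.objective * (1 + 1e-6)
        assert np.allclose(gn.params.free_values(), lm.params.free_values(), rtol=1e-3)

    def test_n_not_greater_than_p_rejected(self):
        data = _dataset([10, 12, 14, 16], [40, 50, 60, 70], [0.1, 0.1, 0.1, 0.1], 1)
        with pytest.raises(ValueError, match="free parameters"):
            fit_rgr_model(data)

    def test_se_coverage_of_truth(self, design):
        """±2 asymptotic standard errors cover the truth in at least 80% of
        100 noisy replicates (the asymptotics are approximate)."""
        theta, s, f_true = design
        hits = np.zeros(4)
        n_sim = 100
        for i in range(n_sim):
            y = f_true + np.random.default_rng(3000 + i).normal(0, 0.03, 160)
            fit = fit_rgr_model(_dataset(theta, s, y))
            est = fit.params.free_values()
            se = fit.std_errors[NAMES].to_numpy()
            hits += np.abs(est - TRUE_VEC) <= 2 * se
        assert np.all(hits / n_sim >= 0.80)


class TestEnemyModel:
    def test_enemy_coefficients_recovered_zero_noise(self, design):
        theta, s, _ = design
        rng = np.random.default_rng(4)
        E = rng.integers(0, 80, 160)
        M = rng.integers(0, 30, 160)
        truth = RGRParams(**{**TRUE.to_dict(), "c_E": -8e-4, "c_M": -5e-4})
        from aphidrgr.surface import rgr_with_enemies

        y = rgr_with_enemies(theta, s, E, M, truth)
        data = RegressionDataset(
            rgr_obs=y, theta_weekly=theta, s_weekly=s,
            field_id=np.repeat([f"F{i}" for i in range(16)], 10),
            date=pd.date_range("2000-05-01", periods=160, freq="D"),
            E=E.astype(float), M=M.astype(float),
        )
        fit = fit_rgr_model(data, init=truth, with_enemies=True)
        assert fit.params.c_E == pytest.approx(-8e-4, rel=1e-4)
        assert fit.params.c_M == pytest.approx(-5e-4, rel=1e-4)

    def test_missing_enemy_columns_rejected(self, design):
        theta, s, f_true = design
        with pytest.raises(ValueError, match="enemy"):
            fit_rgr_model(_dataset(theta, s, f_true), with_enemies=True)


class TestCorrelations:
    def test_unit_diagonal_and_symmetry(self, design):
        theta, s, f_true = design
        y = f_true + np.random.default_rng(5).normal(0, 0.03, 160)
        fit = fit_rgr_model(_dataset(theta, s, y))
        corr = param_correlations(fit)
        assert list(corr.index) == ["s_m", "b", "k", "a"]
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.all(np.abs(corr.to_numpy()) <= 1.0)

    def test_duplicated_parameter_is_singular(self):
        """A model where two parameters multiply identically has |corr| -> 1
        and triggers the singularity warning."""
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 2, 60)
        y = 0.5 * x + rng.normal(0, 0.01, 60)

        from aphidrgr.fitting import _asymptotic_correlations

        J = np.column_stack([x, x])  # d/da (a·b·x) at a=b=1, twice
        with pytest.warns(SingularJacobianWarning):
            corr, se, singular = _asymptotic_correlations(J, 0.01, 60, 2, ["a", "b"])
        assert singular
        assert abs(corr.to_numpy()[0, 1]) > 0.999
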