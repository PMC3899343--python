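"""Synthetic survey generator: seasonal climate, phenology, counts."""

import numpy as np
import pandas as pd
import pytest

from aphidrgr.surface import RGRParams
from aphidrgr.synthetic import (
    FieldSurvey,
    NoiseParams,
    SeasonalParams,
    SimulationConfig,
    gen_phenology,
    gen_population,
    gen_survey,
    gen_temperature,
    simulate_field_year,
)


class TestTemperature:
    def test_zero_noise_equals_seasonal_curve(self):
        sp = SeasonalParams()
        temps = gen_temperature("2001-05-01", 30, sp, NoiseParams(sd=0, year_sd=0), seed=0)
        assert np.allclose(temps.t_mean, sp.curve(temps.dates))

    @pytest.mark.parametrize("seed", [0, 1, 7, 123, 9999])
    def test_spring_summer_means_capped_at_22(self, seed):
        """With the default seasonal parameters no May-July daily mean
        exceeds 22 °C, matching the empirical ceiling of the regions."""
        temps = gen_temperature("2001-05-01", 76, seed=seed)
        assert temps.t_mean.max() <= 22.0

    def test_fixed_seed_bit_identical(self):
        a = gen_temperature("2001-05-01", 76, seed=42)
        b = gen_temperature("2001-05-01", 76, seed=42)
        assert np.array_equal(a.t_mean, b.t_mean)
        assert np.array_equal(a.t_min, b.t_min)
        assert a.dates.equals(b.dates)

    def test_ordering_invariant(self):
        temps = gen_temperature("2001-05-01", 76, seed=3)
        assert np.all(temps.t_min <= temps.t_mean)
        assert np.all(temps.t_mean <= temps.t_max)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="n_days"):
            gen_temperature("2001-05-01", 0)
        with pytest.raises(ValueError, match="autocorrelation"):
            NoiseParams(rho=1.0)


class TestPhenology:
    def test_cold_days_freeze_stage(self):
        temps = gen_temperature(
            "2001-05-01", 20,
            SeasonalParams(mean_level=-5, amplitude=0, clip_max=None),
            NoiseParams(sd=0, year_sd=0),
        )
        phen = gen_phenology(temps, base_temp=0.0, start_stage=30.0)
        assert np.all(phen.stage == 30.0)

    def test_closed_form_degree_day_accumulation(self):
        """Constant t_mean = base + d for k days raises the stage by
        k·d / degree_days_per_stage (hand summation)."""
        base, d, k_days, ddps = 4.0, 3.5, 14, 20.0
        temps = gen_temperature(
            "2001-05-01", k_days,
            SeasonalParams(mean_level=base + d, amplitude=0, clip_max=None),
            NoiseParams(sd=0, year_sd=0),
        )
        phen = gen_phenology(temps, base_temp=base, degree_days_per_stage=ddps,
                             start_stage=31.0)
        assert phen.stage[-1] - 31.0 == pytest.approx(k_days * d / ddps, rel=1e-12)

    def test_default_season_ends_at_grain_ripening(self):
        """The noise-free default season (1 May - 15 July) ends in Zadoks
        [90, 92], i.e. at grain ripening; stochastic seasons scatter around
        it within the survey window."""
        temps = gen_temperature("2001-05-01", 76, noise_params=NoiseParams(sd=0, year_sd=0))
        phen = gen_phenology(temps)
        assert 90.0 <= phen.stage[-1] <= 92.0
        for seed in range(5):
            t = gen_temperature("2001-05-01", 76, seed=seed)
            p = gen_phenology(t)
            assert 80.0 <= p.stage[-1] <= 99.0

    def test_monotone_and_capped(self):
        temps = gen_temperature("2001-05-01", 200, seed=0)
        phen = gen_phenology(temps, degree_days_per_stage=5.0)
        assert np.all(np.diff(phen.stage) >= 0)
        assert phen.stage.max() <= 99.0

    def test_invalid_start_stage_rejected(self):
        temps = gen_temperature("2001-05-01", 5, seed=0)
        with pytest.raises(ValueError, match="start_stage"):
            gen_phenology(temps, start_stage=99.0)


class TestPopulation:
    def test_zero_growth_constant_density(self, quiet_season):
        temps, phen = quiet_season
        params = RGRParams(s_m=45, a=0.0, b=1.2, k=0.35)  # f == 0
        latent = gen_population(params, temps, phen, n0=0.4)
        assert np.allclose(latent.to_numpy(), 0.4)

    def test_constant_rate_euler_closed_form(self, quiet_season, true_params):
        """f == r constant: daily Euler gives n0 (1+r)^k after k days."""
        temps, phen = quiet_season
        r = 0.07
        latent = gen_population(true_params, temps, phen, n0=0.3,
                                rate_fn=lambda th, s: np.full(th.shape, r))
        k = len(latent) - 1
        assert latent.iloc[-1] == pytest.approx(0.3 * (1 + r) ** k, rel=1e-12)

    def test_ten_days_at_ten_percent(self, true_params):
        temps = gen_temperature("2001-05-01", 11, noise_params=NoiseParams(sd=0, year_sd=0))
        phen = gen_phenology(temps)
        latent = gen_population(true_params, temps, phen, n0=1.0,
                                rate_fn=lambda th, s: np.full(th.shape, 0.1))
        assert latent.iloc[-1] == pytest.approx(2.5937424601, rel=1e-9)

    def test_date_mismatch_rejected(self, quiet_season, true_params):
        temps, phen = quiet_season
        short = gen_temperature("2001-05-01", 10, seed=0)
        with pytest.raises(ValueError, match="different dates"):
            gen_population(true_params, short, phen, n0=1.0)

    def test_positive_throughout(self, quiet_season, true_params):
        temps, phen = quiet_season
        latent = gen_population(true_params, temps, phen, n0=1e-3)
        assert np.all(latent.to_numpy() > 0)


class TestSurvey:
    def test_poisson_limit_zero_mean_gives_zero_counts(self, quiet_season, true_params):
        temps, phen = quiet_season
        latent = pd.Series(np.zeros(len(temps)) , index=temps.dates) + 0.0
        sv = gen_survey(latent, temps, phen, 100, np.inf, None,
                        temps.dates[::7], seed=0)
        assert np.all(sv.aphids == 0)

    def test_negative_binomial_mean_monte_carlo(self):
        """10,000 replicate draws at mean 50: sample mean within 3 standard
        errors of 50 (var = mu + mu^2/k)."""
        from aphidrgr.synthetic import _nb_draw

        rng = np.random.default_rng(77)
        mu, k = 50.0, 3.0
        draws = _nb_draw(rng, np.full(10_000, mu), k)
        se = np.sqrt((mu + mu**2 / k) / 10_000)
        assert abs(draws.mean() - mu) < 3 * se

    def test_zero_enemy_rates_give_zero_counts(self, quiet_season, true_params):
        temps, phen = quiet_season
        latent = gen_population(true_params, temps, phen, n0=0.5)
        sv = gen_survey(latent, temps, phen, 200, 3.0, (0.0, 0.0),
                        temps.dates[::7], seed=1)
        assert sv.has_enemies
        assert np.all(sv.e_kills == 0) and np.all(sv.mummies == 0)

    def test_weekly_date_outside_range_rejected(self, quiet_season, true_params):
        temps, phen = quiet_season
        latent = gen_population(true_params, temps, phen, n0=0.5)
        bad = pd.DatetimeIndex(["2001-04-01"])
        with pytest.raises(ValueError, match="outside"):
            gen_survey(latent, temps, phen, 100, 3.0, None, bad, seed=0)

    def test_tiller_bounds_enforced(self, quiet_season, true_params):
        temps, phen = quiet_season
        latent = gen_population(true_params, temps, phen, n0=0.5)
        with pytest.raises(ValueError, match="tillers"):
            gen_survey(latent, temps, phen, 20, 3.0, None, temps.dates[::7], seed=0)


class TestFieldYearAndInvariants:
    def test_fixed_seed_bit_identical(self):
        a, _ = simulate_field_year(SimulationConfig(seed=5))
        b, _ = simulate_field_year(SimulationConfig(seed=5))
        assert np.array_equal(a.aphids, b.aphids)
        assert np.array_equal(a.stage, b.stage)
        assert a.dates.equals(b.dates)

    @pytest.mark.parametrize("seed", range(10))
    def test_generated_surveys_satisfy_invariants(self, seed):
        """Random configurations always produce a valid FieldSurvey: the
        constructor enforces every invariant, so construction succeeding
        plus spot checks is the property."""
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(
            n0=float(rng.uniform(0.01, 0.2)),
            overdispersion=float(rng.uniform(0.5, 10)),
            tillers=int(rng.integers(50, 1001)),
            seed=seed,
        )
        sv, temps = simulate_field_year(cfg, with_enemies=bool(seed % 2))
        assert np.all(np.diff(sv.dates.to_numpy()).astype("timedelta64[D]").astype(int) == 7)
        assert np.all((sv.tillers >= 50) & (sv.tillers <= 1000))
        assert np.all(np.diff(sv.stage) >= 0)
        assert np.all(sv.aphids >= 0)
        assert (sv.e_kills is None) == (sv.mummies is None)

    def test_invalid_survey_rejected(self):
        dates = pd.date_range("2001-05-01", periods=4, freq="7D")
        with pytest.raises(ValueError, match="tillers"):
            FieldSurvey("F", "r", dates, [20, 100, 100, 100], [0, 1, 2, 3],
                        [30, 31, 32, 33])
        with pytest.raises(ValueError, match="stage decreases"):
            FieldSurvey("F", "r", dates, [100] * 4, [0, 1, 2, 3],
                        [30, 35, 33, 36])
        with pytest.raises(ValueError, match="both"):
            FieldSurvey("F", "r", dates, [100] * 4, [0, 1, 2, 3],
                        [30, 31, 32, 33], e_kills=[0, 0, 0, 0])
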