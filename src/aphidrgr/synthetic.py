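"""Synthetic field surveys of cereal-aphid populations on winter wheat.

Real survey campaigns count living aphids on 50-1000 randomly chosen tillers
once a week from early May (stem extension, Zadoks ~30) to mid-July (grain
ripening, Zadoks ~92), record the wheat growth stage, and log daily
min/mean/max temperature at a nearby weather station.  This module generates
data with that structure from a known ground truth so every downstream stage
— spline RGR estimation, nonlinear surface fitting, validation — can be
exercised and checked against the truth.

The generative chain is:

* daily mean temperature = sinusoidal seasonal curve + AR(1) noise, clipped
  so spring/summer means stay at or below 22 °C (oceanic/continental French
  springs rarely exceed it);
* wheat phenology = degree-day accumulation above a base temperature, which
  deliberately reproduces the field confounding of temperature and stage;
* latent per-tiller aphid density = daily Euler integration of
  dN/dt = f(θ(t), s(t)) · N with the true RGR surface;
* observed counts = negative-binomial draws around latent density × tillers
  (sampling noise is strongly overdispersed in real counts), with optional
  fungus-kill and mummy counts proportional to the aphid mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Callable

import numpy as np
import pandas as pd

from .surface import RGRParams, rgr_surface

__all__ = [
    "SeasonalParams",
    "NoiseParams",
    "TemperatureSeries",
    "PhenologyTrack",
    "FieldSurvey",
    "SimulationConfig",
    "gen_temperature",
    "gen_phenology",
    "gen_population",
    "gen_survey",
    "simulate_field_year",
    "default_true_params",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonalParams:
    """Sinusoidal annual mean-temperature curve for a French cereal region.

    mean_level + amplitude · cos(2π (doy − peak_doy)/365.25), with the mean
    clipped at clip_max so no spring/summer daily mean exceeds 22 °C under
    the defaults.  t_min/t_max sit symmetrically ±diurnal_offset around the
    mean.
    """

    mean_level: float = 12.0
    amplitude: float = 6.0
    peak_doy: float = 200.0
    clip_max: Optional[float] = 22.0
    diurnal_offset: float = 4.0

    def curve(self, dates: pd.DatetimeIndex) -> np.ndarray:
        doy = dates.dayofyear.to_numpy(dtype=float)
        return self.mean_level + self.amplitude * np.cos(
            2.0 * np.pi * (doy - self.peak_doy) / 365.25
        )


@dataclass(frozen=True)
class NoiseParams:
    """Temperature noise: AR(1) daily fluctuations plus a year effect.

    ``sd``/``rho`` parameterize first-order autocorrelated daily noise
    (stationary standard deviation ``sd``); ``year_sd`` is the standard
    deviation of a constant per-season climatic offset, reproducing the
    cold-versus-warm springs that make weekly mean temperatures range over
    roughly 6-22 °C across survey years.
    """

    sd: float = 1.5
    rho: float = 0.5
    year_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.sd < 0 or self.year_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"autocorrelation must be in [0, 1), got {self.rho}")


@dataclass
class TemperatureSeries:
    """Daily min/mean/max temperatures over a contiguous date range."""

    dates: pd.DatetimeIndex
    t_min: np.ndarray
    t_mean: np.ndarray
    t_max: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.t_mean = np.asarray(self.t_mean, dtype=float)
        self.t_max = np.asarray(self.t_max, dtype=float)
        n = len(self.dates)
        if not (len(self.t_min) == len(self.t_mean) == len(self.t_max) == n):
            raise ValueError("temperature arrays must match the date index")
        if n == 0:
            raise ValueError("empty temperature series")
        step = np.diff(self.dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if n > 1 and not np.all(step == 1):
            raise ValueError("dates must be consecutive days with no gaps")
        bad = np.flatnonzero((self.t_min > self.t_mean) | (self.t_mean > self.t_max))
        if bad.size:
            raise ValueError(f"t_min <= t_mean <= t_max violated at rows {bad[:5].tolist()}")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "t_min": self.t_min, "t_mean": self.t_mean, "t_max": self.t_max}
        )


@dataclass
class PhenologyTrack:
    """Daily Zadoks growth-stage trajectory of the wheat crop."""

    dates: pd.DatetimeIndex
    stage: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.stage = np.asarray(self.stage, dtype=float)
        if len(self.stage) != len(self.dates):
            raise ValueError("stage array must match the date index")
        if np.any((self.stage < 0) | (self.stage > 99)):
            raise ValueError("Zadoks stage outside [0, 99]")
        if np.any(np.diff(self.stage) < -1e-12):
            raise ValueError("stage must be non-decreasing")

    def at(self, dates) -> np.ndarray:
        s = pd.Series(self.stage, index=self.dates)
        return s.loc[pd.DatetimeIndex(dates)].to_numpy()


@dataclass
class FieldSurvey:
    """One field-year of weekly aphid counts with phenology and effort.

    ``aphids`` are totals over the sampled tillers (the raw tally sheet);
    per-tiller density is ``density()``.  ``e_kills`` (fungus-killed aphids)
    and ``mummies`` (parasitoid mummies) are either both present or both
    absent.
    """

    field_id: str
    region: str
    dates: pd.DatetimeIndex
    tillers: np.ndarray
    aphids: np.ndarray
    stage: np.ndarray
    e_kills: Optional[np.ndarray] = None
    mummies: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tillers = np.asarray(self.tillers, dtype=int)
        self.aphids = np.asarray(self.aphids, dtype=int)
        self.stage = np.asarray(self.stage, dtype=float)
        n = len(self.dates)
        for name in ("tillers", "aphids", "stage"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one value per sampling date")
        if n == 0:
            raise ValueError("survey has no sampling dates")
        step = np.diff(self.dates.to_numpy()).astype("timedelta64[D]").astype(int)
        if np.any(step <= 0):
            raise ValueError("sampling dates must be strictly increasing")
        off = np.flatnonzero((step < 6) | (step > 8))
        if off.size:
            raise ValueError(
                f"sampling interval not ~weekly (6-8 days) after rows {off[:5].tolist()}"
            )
        bad = np.flatnonzero((self.tillers < 50) | (self.tillers > 1000))
        if bad.size:
            raise ValueError(f"tillers outside [50, 1000] at rows {bad[:5].tolist()}")
        if np.any(self.aphids < 0):
            raise ValueError("aphid counts must be nonnegative")
        dec = np.flatnonzero(np.diff(self.stage) < -1e-9)
        if dec.size:
            raise ValueError(f"growth stage decreases after rows {dec[:5].tolist()}")
        if np.any((self.stage < 0) | (self.stage > 99)):
            raise ValueError("Zadoks stage outside [0, 99]")
        if (self.e_kills is None) != (self.mummies is None):
            raise ValueError("e_kills and mummies must be both present or both absent")
        if self.e_kills is not None:
            self.e_kills = np.asarray(self.e_kills, dtype=int)
            self.mummies = np.asarray(self.mummies, dtype=int)
            if len(self.e_kills) != n or len(self.mummies) != n:
                raise ValueError("enemy counts must have one value per sampling date")
            if np.any(self.e_kills < 0) or np.any(self.mummies < 0):
                raise ValueError("enemy counts must be nonnegative")

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    @property
    def has_enemies(self) -> bool:
        return self.e_kills is not None

    def times_days(self) -> np.ndarray:
        """Days since the first sampling date (internal time axis)."""
        delta = self.dates.to_numpy() - self.dates[0].to_numpy()
        return delta.astype("timedelta64[D]").astype(float)

    def density(self) -> np.ndarray:
        """Living aphids per tiller."""
        return self.aphids / self.tillers

    def to_frame(self) -> pd.DataFrame:
        d = {
            "field_id": self.field_id,
            "region": self.region,
            "date": self.dates,
            "tillers": self.tillers,
            "aphids": self.aphids,
            "stage": self.stage,
        }
        if self.has_enemies:
            d["e_kills"] = self.e_kills
            d["mummies"] = self.mummies
        return pd.DataFrame(d)


def default_true_params() -> RGRParams:
    """Ground-truth surface parameters used by the default simulations.

    Chosen so the surface peaks near 0.15/day inside the observable window
    (θ ≤ 22 °C, s in [30, 92]) — the magnitude of the plateau seen in field
    estimates of cereal-aphid RGR — with the phenology inflexion mid-way
    through stem extension-to-heading.  Under the default season this yields
    peak densities of a few tens of aphids per tiller.
    """
    return RGRParams(s_m=45.0, a=0.012, b=1.2, k=0.35)


@dataclass
class SimulationConfig:
    """Everything needed to simulate one region's survey campaign."""

    true_params: RGRParams = field(default_factory=default_true_params)
    n0: float = 0.05  # initial aphids per tiller
    overdispersion: float = 3.0  # negative-binomial size parameter
    enemy_rates: tuple[float, float] = (0.0, 0.0)  # E and M means per aphid mean
    base_temp: float = 0.0  # °C, degree-day base
    degree_days_per_stage: float = 20.0  # °C·day per Zadoks unit
    seed: int = 0
    start_date: str = "2001-05-01"
    n_days: int = 76  # 1 May to 15 July inclusive
    start_stage: float = 30.0
    tillers: int = 200
    seasonal: SeasonalParams = field(default_factory=SeasonalParams)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("initial density n0 must be > 0")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion parameter must be > 0")
        if any(r < 0 for r in self.enemy_rates):
            raise ValueError("enemy rates must be >= 0")
        if self.degree_days_per_stage <= 0:
            raise ValueError("degree_days_per_stage must be > 0")


def recovery_design(
    n: int = 160,
    theta_range: tuple[float, float] = (6.0, 26.0),
    s_range: tuple[float, float] = (35.0, 80.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic space-filling (θ, s) design for parameter-recovery studies.

    Unscrambled Halton points over the region where the surface carries
    signal: temperatures around the thermal-response band seen in the field
    and stages from the sigmoid flank to the pre-ripening decline.  Used to
    benchmark the fitter at a fixed design, free of sampling clumps.
    """
    from scipy.stats import qmc

    pts = qmc.Halton(2, scramble=False).random(n)
    theta = theta_range[0] + (theta_range[1] - theta_range[0]) * pts[:, 0]
    s = s_range[0] + (s_range[1] - s_range[0]) * pts[:, 1]
    return theta, s


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_temperature(
    start_date,
    n_days: int,
    seasonal_params: SeasonalParams | None = None,
    noise_params: NoiseParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> TemperatureSeries:
    """Daily temperature series: seasonal sinusoid plus AR(1) noise.

    With the default seasonal parameters the generated daily means are
    clipped at 22 °C, matching the empirical ceiling of spring/summer daily
    means in the wheat-growing regions being emulated.
    """
    if n_days < 1:
        raise ValueError(f"n_days must be >= 1, got {n_days}")
    sp = seasonal_params or SeasonalParams()
    npar = noise_params or NoiseParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    dates = pd.date_range(start=start_date, periods=n_days, freq="D")
    mean_curve = sp.curve(dates)
    if npar.year_sd > 0:
        mean_curve = mean_curve + rng.normal(0.0, npar.year_sd)
    eps = np.zeros(n_days)
    if npar.sd > 0:
        innov_sd = npar.sd * np.sqrt(1.0 - npar.rho**2)
        z = rng.normal(0.0, 1.0, size=n_days)
        eps[0] = npar.sd * z[0]
        for i in range(1, n_days):
            eps[i] = npar.rho * eps[i - 1] + innov_sd * z[i]
    t_mean = mean_curve + eps
    if sp.clip_max is not None:
        t_mean = np.minimum(t_mean, sp.clip_max)
    return TemperatureSeries(
        dates=dates,
        t_min=t_mean - sp.diurnal_offset,
        t_mean=t_mean,
        t_max=t_mean + sp.diurnal_offset,
    )


def gen_phenology(
    temps: TemperatureSeries,
    base_temp: float = 0.0,
    degree_days_per_stage: float = 20.0,
    start_stage: float = 30.0,
    seed=None,
) -> PhenologyTrack:
    """Degree-day driven Zadoks phenology (deterministic given temperature).

    stage(t) = start_stage + cumulative max(0, t_mean - base_temp)
               / degree_days_per_stage, capped at 99.  ``seed`` is accepted
    for interface uniformity; the track is deterministic.
    """
    if len(temps) == 0:
        raise ValueError("empty temperature series")
    if not (0.0 <= start_stage < 99.0):
        raise ValueError(f"start_stage must be in [0, 99), got {start_stage}")
    if degree_days_per_stage <= 0:
        raise ValueError("degree_days_per_stage must be > 0")
    dd = np.cumsum(np.maximum(0.0, temps.t_mean - base_temp))
    stage = np.minimum(start_stage + dd / degree_days_per_stage, 99.0)
    return PhenologyTrack(dates=temps.dates, stage=stage)


def gen_population(
    true_params: RGRParams,
    temps: TemperatureSeries,
    phen: PhenologyTrack,
    n0: float,
    rate_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> pd.Series:
    """Latent per-tiller aphid density by daily Euler integration.

    N_{t+1} = N_t · (1 + f(θ_t, s_t) · 1 day).  ``rate_fn(theta, stage)``
    overrides the surface when a bespoke growth law is wanted (tests,
    what-if runs).  Returns a daily pandas Series indexed by date.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if not temps.dates.equals(phen.dates):
        raise ValueError("temperature and phenology cover different dates")
    f = rate_fn or (lambda th, s: rgr_surface(th, s, true_params))
    rates = np.asarray(f(temps.t_mean, phen.stage), dtype=float)
    growth = 1.0 + rates
    if np.any(growth <= 0):
        raise ValueError("daily growth factor fell to zero or below; shrink the step or rates")
    n = np.empty(len(temps))
    n[0] = n0
    # daily Euler recursion; (1 + f)^k closed form when f is constant
    np.cumprod(growth[:-1], out=growth[:-1])
    n[1:] = n0 * growth[:-1]
    return pd.Series(n, index=temps.dates, name="density")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and size ``dispersion``.

    Var = mean + mean²/dispersion; dispersion → ∞ recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.isinf(dispersion):
        out[pos] = rng.poisson(mean[pos])
    else:
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def gen_survey(
    latent: pd.Series,
    temps: TemperatureSeries,
    phen: PhenologyTrack,
    tillers_per_date,
    overdispersion: float,
    enemy_rates: tuple[float, float] | None,
    weekly_dates,
    seed=None,
    field_id: str = "F1",
    region: str = "synthetic",
    deterministic: bool = False,
) -> FieldSurvey:
    """Observe the latent trajectory: weekly overdispersed counts on tillers.

    ``deterministic=True`` replaces every count draw by its rounded mean —
    the noise-free observation mode used to verify that the estimation
    chain recovers the generating growth-rate surface.
    """
    weekly = pd.DatetimeIndex(weekly_dates)
    missing = weekly.difference(latent.index)
    if len(missing):
        raise ValueError(f"weekly dates outside the simulated range: {missing[0].date()}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    tillers = np.broadcast_to(np.asarray(tillers_per_date, dtype=int), (len(weekly),)).copy()
    if np.any((tillers < 50) | (tillers > 1000)):
        raise ValueError("tillers per date must lie in [50, 1000]")

    mu = latent.loc[weekly].to_numpy() * tillers
    if deterministic:
        draw = lambda m: np.round(m).astype(np.int64)
    else:
        draw = lambda m: _nb_draw(rng, m, overdispersion)
    aphids = draw(mu)
    e_kills = mummies = None
    if enemy_rates is not None:
        e_kills = draw(enemy_rates[0] * mu)
        mummies = draw(enemy_rates[1] * mu)
    return FieldSurvey(
        field_id=field_id,
        region=region,
        dates=weekly,
        tillers=tillers,
        aphids=aphids,
        stage=phen.at(weekly),
        e_kills=e_kills,
        mummies=mummies,
    )


def simulate_field_year(
    config: SimulationConfig,
    field_id: str = "F1",
    region: str = "synthetic",
    seed: int | None = None,
    with_enemies: bool = False,
) -> tuple[FieldSurvey, TemperatureSeries]:
    """Run the full generative chain for one field-year.

    ``seed`` overrides ``config.seed``.  With ``with_enemies`` the survey
    carries fungus-kill and mummy counts at the configured rates (defaults
    emulate a region where those tallies were collected at roughly 5% and 2%
    of the aphid mean when the config rates are zero).
    """
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    rng_temp, rng_obs = [np.random.default_rng(s) for s in ss.spawn(2)]

    temps = gen_temperature(
        config.start_date, config.n_days, config.seasonal, config.noise, seed=rng_temp
    )
    phen = gen_phenology(
        temps, config.base_temp, config.degree_days_per_stage, config.start_stage
    )
    latent = gen_population(config.true_params, temps, phen, config.n0)
    weekly = temps.dates[::7]
    enemy_rates: tuple[float, float] | None = None
    if with_enemies:
        enemy_rates = config.enemy_rates if any(config.enemy_rates) else (0.05, 0.02)
    survey = gen_survey(
        latent,
        temps,
        phen,
        config.tillers,
        config.overdispersion,
        enemy_rates,
        weekly,
        seed=rng_obs,
        field_id=field_id,
        region=region,
    )
    return survey, temps
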