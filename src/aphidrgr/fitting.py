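"""Nonlinear least-squares estimation of the RGR surface parameters.

Weekly observations from all field-years of a region are pooled into one
regression dataset: the response is the spline-estimated RGR at each
sampling date, the regressors are the weekly mean of mean daily temperatures
(trailing 7-day window ending at the sampling date) and the recorded Zadoks
stage.  The free parameters (s_m, a, b, k, optionally the linear enemy
coefficients c_E, c_M) minimize the sum of squared residuals by
Gauss-Newton iteration with step halving; bounds are enforced by projection.

The records are treated as independent in the objective even though
residuals within a field are serially correlated; the Durbin-Watson
diagnostic quantifies that violation rather than correcting it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .smoothing import RGRSeries
from .surface import RGRParams, rgr_surface, rgr_with_enemies
from .synthetic import FieldSurvey, TemperatureSeries

__all__ = [
    "RegressionDataset",
    "FitResult",
    "SingularJacobianWarning",
    "weekly_mean_temperature",
    "build_dataset",
    "fit_rgr_model",
    "param_correlations",
]

logger = logging.getLogger(__name__)

#: Reporting order of the free parameters in correlation tables.
CORRELATION_ORDER = ["s_m", "b", "k", "a"]


class SingularJacobianWarning(UserWarning):
    """The Jacobian cross-product was (near-)singular at the solution."""


def weekly_mean_temperature(temps: TemperatureSeries, week_anchors) -> np.ndarray:
    """Mean of mean daily temperatures over the 7 days ending at each anchor.

    The window is [anchor − 6 days, anchor], inclusive.  A partially covered
    window is averaged over the available days with a warning; an empty
    window is an error.
    """
    anchors = pd.DatetimeIndex(week_anchors)
    series = pd.Series(temps.t_mean, index=temps.dates)
    out = np.empty(len(anchors))
    for i, anchor in enumerate(anchors):
        window = series.loc[anchor - pd.Timedelta(days=6): anchor]
        if window.empty:
            raise ValueError(f"no temperature records in the week ending {anchor.date()}")
        if len(window) < 7:
            logger.warning(
                "week ending %s has only %d/7 temperature days; using their mean",
                anchor.date(),
                len(window),
            )
        out[i] = float(window.mean())
    return out


@dataclass
class RegressionDataset:
    """Pooled (RGR, weekly temperature, weekly stage) records across fields."""

    rgr_obs: np.ndarray
    theta_weekly: np.ndarray
    s_weekly: np.ndarray
    field_id: np.ndarray
    date: pd.DatetimeIndex
    E: Optional[np.ndarray] = None
    M: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.rgr_obs)
        for name in ("theta_weekly", "s_weekly", "field_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if len(self.date) != n:
            raise ValueError("date length mismatch")
        if not np.all(np.isfinite(self.rgr_obs)):
            raise ValueError("missing or non-finite response values")
        if (self.E is None) != (self.M is None):
            raise ValueError("E and M must be both present or both absent")

    def __len__(self) -> int:
        return len(self.rgr_obs)

    @property
    def has_enemies(self) -> bool:
        return self.E is not None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "field_id": self.field_id,
            "date": self.date,
            "rgr_obs": self.rgr_obs,
            "theta_weekly": self.theta_weekly,
            "s_weekly": self.s_weekly,
        }
        if self.has_enemies:
            d["E"] = self.E
            d["M"] = self.M
        return pd.DataFrame(d)


def build_dataset(
    surveys: Sequence[FieldSurvey],
    rgr: Sequence[RGRSeries],
    temps: Sequence[TemperatureSeries],
) -> RegressionDataset:
    """Pool per-field RGR series into one regression dataset.

    One record per (field, sampling date), sorted by field then date.  Dates
    whose trailing temperature week is entirely missing are dropped with a
    logged count.
    """
    if not (len(surveys) == len(rgr) == len(temps)):
        raise ValueError("surveys, rgr and temps must be aligned lists of equal length")
    rows = []
    n_dropped = 0
    for survey, series, temp in zip(surveys, rgr, temps):
        if len(series.dates) != survey.n_dates:
            raise ValueError(f"RGR series does not match survey {survey.field_id}")
        daily = pd.Series(temp.t_mean, index=temp.dates)
        for j, date in enumerate(pd.DatetimeIndex(series.dates)):
            window = daily.loc[date - pd.Timedelta(days=6): date]
            if window.empty:
                n_dropped += 1
                continue
            row = {
                "field_id": survey.field_id,
                "date": date,
                "rgr_obs": series.rgr[j],
                "theta_weekly": float(window.mean()),
                "s_weekly": survey.stage[j],
            }
            if survey.has_enemies:
                row["E"] = survey.e_kills[j]
                row["M"] = survey.mummies[j]
            rows.append(row)
    if n_dropped:
        logger.warning("dropped %d records lacking temperature coverage", n_dropped)
    df = pd.DataFrame(rows).sort_values(["field_id", "date"], kind="stable")
    with_enemies = "E" in df.columns and df["E"].notna().all()
    return RegressionDataset(
        rgr_obs=df["rgr_obs"].to_numpy(float),
        theta_weekly=df["theta_weekly"].to_numpy(float),
        s_weekly=df["s_weekly"].to_numpy(float),
        field_id=df["field_id"].to_numpy(),
        date=pd.DatetimeIndex(df["date"]),
        E=df["E"].to_numpy(float) if with_enemies else None,
        M=df["M"].to_numpy(float) if with_enemies else None,
    )


@dataclass
class FitResult:
    """Outcome of the nonlinear least-squares fit."""

    params: RGRParams
    free_names: list[str]
    residuals: np.ndarray
    fitted: np.ndarray
    correlations: pd.DataFrame
    std_errors: pd.Series
    iterations: int
    objective: float
    converged: bool
    n: int
    p: int
    singular: bool = False

    def summary(self) -> str:
        lines = [
            f"Nonlinear least squares: n={self.n}, p={self.p}, "
            f"SSE={self.objective:.6g}, iterations={self.iterations}, "
            f"converged={self.converged}",
        ]
        for name in self.free_names:
            val = getattr(self.params, name)
            se = self.std_errors.get(name, np.nan)
            lines.append(f"  {name:>4} = {val: .6g}  (asymptotic se {se:.3g})")
        return "\n".join(lines)


def _default_init(data: RegressionDataset, params_fixed: dict) -> RGRParams:
    """Data-driven starting values: s_m at the stage midpoint, k=0.3, b=1,
    a scaled so the surface maximum matches the 95th percentile of |RGR|."""
    s_mid = float((data.s_weekly.min() + data.s_weekly.max()) / 2.0)
    s_max = params_fixed.get("s_max", 92.0)
    s_mid = min(max(s_mid, 1.0), s_max - 1.0)
    trial = RGRParams(s_m=s_mid, a=1.0, b=1.0, k=0.3, **params_fixed)
    theta_grid = np.linspace(0.1, trial.theta_max - 0.1, 200)
    s_grid = np.linspace(min(data.s_weekly.min(), s_mid), s_max - 0.1, 200)
    peak = float(np.max(rgr_surface(theta_grid[None, :], s_grid[:, None], trial)))
    target = float(np.percentile(np.abs(data.rgr_obs), 95))
    a0 = max(target / peak, 1e-6) if peak > 0 else 1e-3
    return RGRParams(s_m=s_mid, a=a0, b=1.0, k=0.3, **params_fixed)


def _project(x: np.ndarray, names: list[str], s_max: float) -> np.ndarray:
    """Project a free-parameter vector onto the feasible box."""
    out = x.copy()
    for i, name in enumerate(names):
        if name == "s_m":
            out[i] = np.clip(out[i], 1e-3, s_max - 1e-3)
        elif name == "a":
            out[i] = max(out[i], 0.0)
        elif name == "k":
            out[i] = max(out[i], 1e-6)
    return out


def _predict(params: RGRParams, data: RegressionDataset, with_enemies: bool) -> np.ndarray:
    if with_enemies:
        return rgr_with_enemies(data.theta_weekly, data.s_weekly, data.E, data.M, params)
    return rgr_surface(data.theta_weekly, data.s_weekly, params)


def _jacobian(
    params: RGRParams,
    data: RegressionDataset,
    names: list[str],
    with_enemies: bool,
    s_max: float,
) -> np.ndarray:
    """Finite-difference Jacobian of the model predictions.

    Central differences, projected onto the feasible box so a parameter
    sitting on its bound degrades gracefully to a one-sided difference.
    """
    x0 = params.free_values(with_enemies)
    J = np.empty((len(data), len(names)))
    for i in range(len(names)):
        h = 1e-6 * max(1.0, abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        xp = _project(xp, names, s_max)
        xm = _project(xm, names, s_max)
        denom = xp[i] - xm[i]
        if denom == 0.0:  # pinned parameter: no identifiable direction
            J[:, i] = 0.0
            continue
        fp = _predict(params.replace_free(xp, with_enemies), data, with_enemies)
        fm = _predict(params.replace_free(xm, with_enemies), data, with_enemies)
        J[:, i] = (fp - fm) / denom
    return J


def fit_rgr_model(
    data: RegressionDataset,
    init: RGRParams | None = None,
    fixed: dict | None = None,
    with_enemies: bool = False,
    max_iter: int = 200,
    tol: float = 1e-8,
    method: str = "gauss-newton",
) -> FitResult:
    """Fit the RGR surface to pooled observations by nonlinear least squares.

    Gauss-Newton with step halving: each iteration solves the linearized
    normal equations and halves the step until the objective decreases.
    Convergence when the relative objective decrease drops below ``tol``
    (default 1e-8) or after ``max_iter`` iterations (then ``converged`` is
    False — no exception).  ``method="lm"`` delegates the minimization to a
    trust-region Levenberg-Marquardt-type routine for stubborn starts.

    ``fixed`` overrides the fixed constants, e.g. ``{"theta_max": 30,
    "s_max": 92}``.
    """
    fixed = dict(fixed or {})
    fixed.setdefault("theta_max", 30.0)
    fixed.setdefault("s_max", 92.0)
    if with_enemies and not data.has_enemies:
        raise ValueError("dataset has no enemy counts; cannot fit the extended model")

    if init is None:
        init = _default_init(data, fixed)
    else:
        init = RGRParams(**{**init.to_dict(), **fixed})
    if with_enemies and init.c_E is None:
        init = RGRParams(**{**init.to_dict(), "c_E": 0.0, "c_M": 0.0})

    names = init.free_names(with_enemies)
    n, p = len(data), len(names)
    if n <= p:
        raise ValueError(f"need more records than free parameters (n={n}, p={p})")

    params = init
    x = _project(init.free_values(with_enemies), names, fixed["s_max"])
    params = params.replace_free(x, with_enemies)
    resid = data.rgr_obs - _predict(params, data, with_enemies)
    sse = float(resid @ resid)
    converged = False
    iterations = 0

    if method == "lm":
        from scipy.optimize import least_squares

        def fun(xv):
            pv = init.replace_free(_project(xv, names, fixed["s_max"]), with_enemies)
            return data.rgr_obs - _predict(pv, data, with_enemies)

        sol = least_squares(fun, x, method="trf", xtol=1e-12, ftol=1e-12)
        x = _project(sol.x, names, fixed["s_max"])
        params = init.replace_free(x, with_enemies)
        resid = data.rgr_obs - _predict(params, data, with_enemies)
        sse = float(resid @ resid)
        iterations = int(sol.nfev)
        converged = bool(sol.success)
    elif method == "gauss-newton":
        for iterations in range(1, max_iter + 1):
            J = _jacobian(params, data, names, with_enemies, fixed["s_max"])
            JtJ = J.T @ J
            # lstsq tolerates rank deficiency (the a-b direction can be
            # near-collinear); the final covariance reports it explicitly
            delta, *_ = np.linalg.lstsq(JtJ, J.T @ resid, rcond=None)
            step = 1.0
            improved = False
            for _ in range(40):
                x_new = _project(x + step * delta, names, fixed["s_max"])
                p_new = params.replace_free(x_new, with_enemies)
                r_new = data.rgr_obs - _predict(p_new, data, with_enemies)
                sse_new = float(r_new @ r_new)
                if sse_new < sse:
                    improved = True
                    break
                step /= 2.0
            if not improved:
                converged = True  # no descent direction left: stationary point
                break
            rel_drop = (sse - sse_new) / max(sse, 1e-300)
            x, params, resid, sse = x_new, p_new, r_new, sse_new
            if rel_drop < tol:
                converged = True
                break
    else:
        raise ValueError(f"unknown method {method!r}")

    J = _jacobian(params, data, names, with_enemies, fixed["s_max"])
    corr, se, singular = _asymptotic_correlations(J, sse, n, p, names)
    return FitResult(
        params=params,
        free_names=names,
        residuals=resid,
        fitted=data.rgr_obs - resid,
        correlations=corr,
        std_errors=se,
        iterations=iterations,
        objective=sse,
        converged=converged,
        n=n,
        p=p,
        singular=singular,
    )


def _asymptotic_correlations(J, sse, n, p, names):
    JtJ = J.T @ J
    singular = False
    cond = np.linalg.cond(JtJ)
    if not np.isfinite(cond) or cond > 1e12:
        singular = True
    try:
        cov = np.linalg.inv(JtJ) * (sse / max(n - p, 1))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ) * (sse / max(n - p, 1))
        singular = True
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    if singular:
        off = np.abs(corr - np.eye(p))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        warnings.warn(
            f"near-singular Jacobian cross-product (cond={cond:.3g}); "
            f"most entangled pair: {names[i]}-{names[j]} "
            f"(correlation {corr[i, j]:.3f})",
            SingularJacobianWarning,
            stacklevel=3,
        )
    order = [nm for nm in CORRELATION_ORDER if nm in names] + [
        nm for nm in names if nm not in CORRELATION_ORDER
    ]
    corr_df = pd.DataFrame(corr, index=names, columns=names).loc[order, order]
    se = pd.Series(sd, index=names)
    return corr_df, se, singular


def param_correlations(fit: FitResult) -> pd.DataFrame:
    """Asymptotic correlation matrix of the free parameter estimates.

    Rows/columns in the conventional reporting order (s_m, b, k, a, then any
    enemy coefficients).  Raises on a singular covariance.
    """
    if fit.singular:
        raise np.linalg.LinAlgError(
            "parameter covariance is singular; correlations are not identifiable"
        )
    return fit.correlations
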