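"""Fit and validation statistics for the RGR regression.

The validation philosophy: the fitted surface is judged against held-out
observations by the bisector — the line where predicted equals observed —
rather than by refitting a regression of observed on predicted.  The
bisector R² (1 minus the ratio of bisector-residual to total sum of
squares, each divided by N−1) equals 1 only for perfect prediction and can
go negative when predictions are worse than the observed mean.  Companion
diagnostics: an ANOVA-style variance partition with an F ratio, the
Durbin-Watson statistic for serial correlation of residuals within fields,
an origin-constrained regression slope (bias check), residual
mean/median/skewness, and a 2×2 sign-error matrix counting growth predicted
in the wrong direction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "AnovaTable",
    "SignErrorMatrix",
    "ValidationReport",
    "anova_table",
    "model_r2",
    "durbin_watson",
    "bisector_r2",
    "origin_regression",
    "sign_error_matrix",
    "residual_summary",
    "validation_report",
]


@dataclass(frozen=True)
class AnovaTable:
    """Variance partition of a (possibly nonlinear) least-squares fit.

    For a nonlinear model the three sums of squares need not be exactly
    additive (ss_model + ss_error ≠ ss_total in general); they are reported
    as computed, never reconciled.
    """

    ss_total: float
    ss_model: float
    ss_error: float
    df_total: int
    df_model: int
    df_error: int
    ms_total: float
    ms_model: float
    ms_error: float
    f_stat: float
    p_value: float

    def to_text(self) -> str:
        rows = [
            ("Total", self.ss_total, self.df_total, self.ms_total, "", ""),
            ("Model", self.ss_model, self.df_model, self.ms_model,
             f"{self.f_stat:.2f}", f"{self.p_value:.5g}"),
            ("Error", self.ss_error, self.df_error, self.ms_error, "", ""),
        ]
        out = [f"{'Source':<8}{'SS':>10}{'df':>6}{'MS':>12}{'F':>10}{'P-value':>14}"]
        for name, ss, df, ms, f, p in rows:
            out.append(f"{name:<8}{ss:>10.4f}{df:>6d}{ms:>12.6f}{f:>10}{p:>14}")
        return "\n".join(out)

    def to_dict(self) -> dict:
        return asdict(self)


def anova_table(observed, fitted, p: int) -> AnovaTable:
    """ANOVA partition: total SS about the mean, model SS of the fitted
    values about the mean, error SS of the residuals.

    F = MS_model / MS_error on (p, n−p) degrees of freedom; a perfect fit
    reports F = +inf.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("observed and fitted must be 1-D arrays of equal length")
    n = y.size
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_model = float(np.sum((yhat - ybar) ** 2))
    ss_error = float(np.sum((y - yhat) ** 2))
    df_total, df_model, df_error = n - 1, p, n - p
    ms_total = ss_total / df_total
    ms_model = ss_model / df_model
    ms_error = ss_error / df_error
    if ms_error == 0.0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ms_model / ms_error
        p_value = float(stats.f.sf(f_stat, df_model, df_error))
    return AnovaTable(
        ss_total=ss_total, ss_model=ss_model, ss_error=ss_error,
        df_total=df_total, df_model=df_model, df_error=df_error,
        ms_total=ms_total, ms_model=ms_model, ms_error=ms_error,
        f_stat=float(f_stat), p_value=p_value,
    )


def model_r2(anova: AnovaTable) -> float:
    """Proportion of total SS explained by the model, as a percentage."""
    if anova.ss_total <= 0:
        raise ValueError("total sum of squares is zero; R² undefined")
    return 100.0 * anova.ss_model / anova.ss_total


def durbin_watson(residuals, groups=None) -> tuple[float, float]:
    """Durbin-Watson statistic with a one-sided normal-approximation p-value.

    DW = Σ (e_i − e_{i−1})² / Σ e_i², with successive differences taken only
    within each group (field), never across a field boundary.  Returns
    ``(dw, p_value)`` where the p-value tests positive autocorrelation
    (small DW) under DW ≈ N(2, 4/n); it is an approximation, not the exact
    Pan/beta distribution.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0.0:
        raise ValueError("all residuals are zero")
    if groups is None:
        num = float(np.sum(np.diff(e) ** 2))
    else:
        g = np.asarray(groups)
        if g.shape != e.shape:
            raise ValueError("groups must align with residuals")
        num = 0.0
        for gi in pd_unique_stable(g):
            sub = e[g == gi]
            if sub.size > 1:
                num += float(np.sum(np.diff(sub) ** 2))
    dw = num / denom
    z = (dw - 2.0) * np.sqrt(e.size) / 2.0
    p_value = float(stats.norm.cdf(z))
    return dw, p_value


def pd_unique_stable(values):
    """Unique values preserving first-appearance order."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def bisector_r2(observed, predicted) -> float:
    """Goodness of prediction relative to the bisector (predicted = observed).

    1 − [Σ(y_i − ŷ_i)²/(N−1)] / [Σ(y_i − ȳ)²/(N−1)], with ŷ taken as-is (no
    refit).  Equals 1 iff the prediction is perfect; 0 for predictions no
    better than the observed mean; negative when they are worse.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are constant; index undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def origin_regression(observed, predicted) -> tuple[float, float]:
    """Slope and R² of the regression of observed on predicted through 0.

    slope = Σ y ŷ / Σ ŷ²; R² compares the constrained line's residuals with
    the spread of the observations about their mean.  A slope near 1 means
    the prediction is unbiased on average.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("need equal-length vectors")
    denom = float(yhat @ yhat)
    if denom == 0.0:
        raise ValueError("all predictions are zero; slope undefined")
    slope = float(y @ yhat) / denom
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are constant; R² undefined")
    r2 = 1.0 - float(np.sum((y - slope * yhat) ** 2)) / sst
    return slope, r2


@dataclass(frozen=True)
class SignErrorMatrix:
    """2×2 cross-classification of observed vs predicted RGR sign.

    ``counts[i, j]``: rows observed (0=positive, 1=negative), columns
    predicted (0=positive, 1=negative).  Zero values classify as positive —
    a flat population is not a decline (configurable at construction).
    """

    counts: tuple[tuple[int, int], tuple[int, int]]

    @property
    def total(self) -> int:
        return sum(sum(row) for row in self.counts)

    @property
    def n_errors(self) -> int:
        return self.counts[0][1] + self.counts[1][0]

    @property
    def error_rate(self) -> float:
        """Proportion of sign disagreements, as a percentage."""
        return 100.0 * self.n_errors / self.total

    def to_text(self) -> str:
        (pp, pn), (np_, nn) = self.counts
        return (
            "              Predicted\n"
            "              Positive  Negative\n"
            f"Obs Positive  {pp:>8d}  {pn:>8d}\n"
            f"Obs Negative  {np_:>8d}  {nn:>8d}\n"
            f"Sign errors: {self.n_errors}/{self.total} ({self.error_rate:.2f}%)"
        )


def sign_error_matrix(observed, predicted, zero_is_positive: bool = True) -> SignErrorMatrix:
    """Count cases where the direction of population change was mispredicted."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("need equal-length non-empty vectors")
    if zero_is_positive:
        obs_neg = y < 0
        pred_neg = yhat < 0
    else:
        obs_neg = y <= 0
        pred_neg = yhat <= 0
    counts = (
        (int(np.sum(~obs_neg & ~pred_neg)), int(np.sum(~obs_neg & pred_neg))),
        (int(np.sum(obs_neg & ~pred_neg)), int(np.sum(obs_neg & pred_neg))),
    )
    return SignErrorMatrix(counts=counts)


def residual_summary(residuals) -> dict:
    """Mean, median and adjusted Fisher-Pearson sample skewness (G1)."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    return {
        "mean": float(np.mean(e)),
        "median": float(np.median(e)),
        "skewness": float(stats.skew(e, bias=False)),
    }


@dataclass
class ValidationReport:
    """Held-out prediction quality of a fitted RGR surface."""

    r2_bisector: float
    origin_slope: float
    origin_r2: float
    residual_mean: float
    residual_median: float
    residual_skewness: float
    sign_errors: SignErrorMatrix
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sign_errors"] = {
            "counts": self.sign_errors.counts,
            "n_errors": self.sign_errors.n_errors,
            "total": self.sign_errors.total,
            "error_rate_pct": self.sign_errors.error_rate,
        }
        return d

    def to_text(self) -> str:
        return (
            f"Validation on {self.n} held-out records\n"
            f"  bisector R^2      : {100 * self.r2_bisector:.2f}%\n"
            f"  origin slope      : {self.origin_slope:.2f}\n"
            f"  origin R^2        : {100 * self.origin_r2:.2f}%\n"
            f"  residual mean     : {self.residual_mean:.4f}\n"
            f"  residual median   : {self.residual_median:.4f}\n"
            f"  residual skewness : {self.residual_skewness:.3f}\n"
            + self.sign_errors.to_text()
        )


def validation_report(observed, predicted) -> ValidationReport:
    """Full held-out validation: bisector R², bias slope, residual shape,
    and the sign-error matrix."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    slope, origin_r2_ = origin_regression(y, yhat)
    summ = residual_summary(y - yhat)
    return ValidationReport(
        r2_bisector=bisector_r2(y, yhat),
        origin_slope=slope,
        origin_r2=origin_r2_,
        residual_mean=summ["mean"],
        residual_median=summ["median"],
        residual_skewness=summ["skewness"],
        sign_errors=sign_error_matrix(y, yhat),
        n=y.size,
    )
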