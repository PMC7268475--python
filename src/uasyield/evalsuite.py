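"""Quantitative model assessment.

Error metrics (bias, absolute bias, RMS, robust scale of residuals,
relative and absolute percent errors, Nash-Sutcliffe efficiency), a
bisquare-weighted robust linear fit of predicted against measured
yield with externally studentized residual outlier flagging, a robust
Jarque-Bera normality test, and family-grouped test-set errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats as sps

from uasyield.errors import (
    DegreesOfFreedomError,
    FitError,
    NumericDomainError,
    SampleSizeError,
)
from uasyield.triples import NMAD_FACTOR


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------


@dataclass
class ErrorReport:
    """Prediction error metrics, in the target's units and percent.

    ``eta`` is the Nash-Sutcliffe model-efficiency index; 1 for a
    perfect prediction, below 0 when the model is worse than predicting
    the mean.
    """

    mbe: float
    ambe: float
    rmse: float
    nmad_resid: float
    re_pct: float
    ae_pct: float
    eta: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def error_metrics(pred, act, eta_as_printed: bool = False) -> ErrorReport:
    """Compute the full error report for predictions against actuals.

    MBE is the mean signed residual, AMBE the mean absolute residual,
    RMSE the root mean square residual, NMAD the robust (1.4826 MAD)
    scale of the residuals; RE and AE are the mean signed and absolute
    residuals relative to the actual value, in percent.

    The Nash-Sutcliffe index defaults to the standard form
    ``1 - sum((pred - act)^2) / sum((act - mean(act))^2)``; with
    ``eta_as_printed=True`` the denominator deviations are taken about
    the predictions instead (a variant that appears in some applied
    reports but does not pin eta to 1 at perfect agreement).
    """
    pred = np.asarray(pred, dtype=float).ravel()
    act = np.asarray(act, dtype=float).ravel()
    if pred.shape != act.shape or pred.size == 0:
        raise SampleSizeError("pred and act must be equal-length and non-empty")
    if np.any(act == 0):
        raise NumericDomainError("zero actual value in relative error")
    resid = pred - act
    mad = float(np.median(np.abs(resid - np.median(resid))))
    act_mean = act.mean()
    if eta_as_printed:
        denom = np.sum((pred - act_mean) ** 2)
    else:
        denom = np.sum((act - act_mean) ** 2)
    eta = 1.0 - float(np.sum(resid**2) / denom) if denom > 0 else (
        1.0 if np.allclose(resid, 0) else float("-inf")
    )
    return ErrorReport(
        mbe=float(resid.mean()),
        ambe=float(np.abs(resid).mean()),
        rmse=float(np.sqrt(np.mean(resid**2))),
        nmad_resid=NMAD_FACTOR * mad,
        re_pct=float(100.0 * np.mean(resid / act)),
        ae_pct=float(100.0 * np.mean(np.abs(resid / act))),
        eta=eta,
    )


# ---------------------------------------------------------------------------
# robust linear fit
# ---------------------------------------------------------------------------


@dataclass
class RobustFit:
    """Bisquare linear fit with studentized-residual outlier flags."""

    slope: float
    intercept: float
    r2: float                      # computed on the non-outlier set
    sr: np.ndarray                 # externally studentized residuals
    outliers: np.ndarray           # boolean flags
    max_abs_sr: float
    threshold: float               # two-tailed t critical value
    x: np.ndarray
    y: np.ndarray
    resid: np.ndarray
    rmse: float
    nmad: float

    @property
    def n_outliers(self) -> int:
        return int(self.outliers.sum())


def _wls_line(x, y, w):
    sw = w.sum()
    if sw == 0:
        raise FitError("all bisquare weights vanished")
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0:
        raise FitError("zero weighted variance in x")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    return slope, ym - slope * xm


def robust_linear_fit(
    x,
    y,
    alpha: float = 0.05,
    c: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> RobustFit:
    """IRLS linear fit with Tukey bisquare weights.

    ``x`` is the measured and ``y`` the predicted quantity.  The scale
    at each iteration is the 1.4826-MAD of the current residuals; the
    tuning constant 4.685 gives 95% Gaussian efficiency.  Outliers are
    then flagged from the externally studentized residuals at level
    ``alpha`` and R^2 is reported on the remaining points.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise SampleSizeError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise FitError("degenerate x: zero variance")

    w = np.ones_like(x)
    slope, intercept = _wls_line(x, y, w)
    for _ in range(max_iter):
        resid = y - (slope * x + intercept)
        scale = NMAD_FACTOR * np.median(np.abs(resid - np.median(resid)))
        if scale == 0:  # perfect (or near-perfect) fit
            break
        u = resid / (c * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        new_slope, new_intercept = _wls_line(x, y, w)
        if max(abs(new_slope - slope), abs(new_intercept - intercept)) < tol:
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept

    resid = y - (slope * x + intercept)
    sr, threshold = _studentize(x, resid, alpha)
    outliers = np.abs(sr) > threshold
    keep = ~outliers
    yk, rk = y[keep], resid[keep]
    ss_tot = np.sum((yk - yk.mean()) ** 2)
    r2 = 1.0 - float(np.sum(rk**2) / ss_tot) if ss_tot > 0 else 1.0
    mad = np.median(np.abs(resid - np.median(resid)))
    return RobustFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        sr=sr,
        outliers=outliers,
        max_abs_sr=float(np.max(np.abs(sr))),
        threshold=float(threshold),
        x=x,
        y=y,
        resid=resid,
        rmse=float(np.sqrt(np.mean(resid**2))),
        nmad=float(NMAD_FACTOR * mad),
    )


def _studentize(x: np.ndarray, resid: np.ndarray, alpha: float):
    """Externally studentized residuals for a straight-line fit.

    ``sr_i = r_i / sqrt(MS_Res(-i) * (1 - h_ii))`` where ``MS_Res(-i)``
    is the residual mean square with observation i removed and ``h_ii``
    the hat-matrix leverage of the [1, x] design.  The critical value is
    the two-tailed t quantile with n - p - 1 degrees of freedom (p = 2).
    """
    n, p = x.size, 2
    if n <= p + 1:
        raise DegreesOfFreedomError(f"need n > {p + 1} observations, got {n}")
    xm = x.mean()
    sxx = np.sum((x - xm) ** 2)
    h = 1.0 / n + (x - xm) ** 2 / sxx
    s2 = np.sum(resid**2) / (n - p)
    # leave-one-out residual mean square, in closed form
    s2_loo = ((n - p) * s2 - resid**2 / (1 - h)) / (n - p - 1)
    s2_loo = np.maximum(s2_loo, 0.0)
    denom = np.sqrt(s2_loo * (1 - h))
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(denom > 0, resid / denom, 0.0)
    threshold = sps.t.ppf(1 - alpha / 2, n - p - 1)
    return sr, float(threshold)


def studentized_outliers(fit: RobustFit, alpha: float = 0.05) -> np.ndarray:
    """Re-flag outliers of an existing fit at a different level."""
    sr, threshold = _studentize(fit.x, fit.resid, alpha)
    return np.abs(sr) > threshold


# ---------------------------------------------------------------------------
# robust normality test
# ---------------------------------------------------------------------------


def robust_jarque_bera(values, alpha: float = 0.05) -> tuple[float, bool]:
    """Robust Jarque-Bera normality test (MAD-scaled moment version).

    Skewness and kurtosis are formed from central moments scaled by
    ``J = sqrt(pi/2) * mean(|x - median|)``, a robust dispersion that is
    consistent with the SD under normality:

    ``RJB = n/6 * (m3 / J^3)^2 + n/64 * (m4 / J^4 - 3)^2``

    and is compared against the chi-square(2) critical value at
    ``alpha``.  Returns ``(statistic, reject)``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise SampleSizeError("need at least 10 values")
    j = np.sqrt(np.pi / 2) * np.mean(np.abs(x - np.median(x)))
    if j == 0:
        raise NumericDomainError("constant sample: robust scale is zero")
    xc = x - x.mean()
    m3 = np.mean(xc**3)
    m4 = np.mean(xc**4)
    stat = x.size / 6.0 * (m3 / j**3) ** 2 + x.size / 64.0 * (m4 / j**4 - 3.0) ** 2
    crit = sps.chi2.ppf(1 - alpha, df=2)
    return float(stat), bool(stat > crit)


# ---------------------------------------------------------------------------
# family-grouped errors
# ---------------------------------------------------------------------------


def family_errors(
    ae_per_plot: pd.Series,
    family_labels: pd.Series,
    min_n: int = 4,
    max_n: int = 6,
) -> pd.DataFrame:
    """Mean absolute percent error per family on the test set.

    Families are only reported when they have between ``min_n`` and
    ``max_n`` predicted plots — enough members for the mean to be
    meaningful but few enough that the grouping stays within one trial
    replicate.  Sorted ascending (best-predicted family first).
    """
    df = pd.DataFrame({"ae": ae_per_plot, "family": family_labels})
    grouped = df.groupby("family")["ae"].agg(["mean", "count"])
    kept = grouped[(grouped["count"] >= min_n) & (grouped["count"] <= max_n)]
    out = kept.rename(columns={"mean": "mean_ae", "count": "n_plots"})
    return out.sort_values("mean_ae").reset_index()
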