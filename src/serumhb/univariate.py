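"""Univariate calibration: OLS lines, inverse prediction, Redbance transform.

Covers both the direct UV-VIS method (absorbance at 540 nm vs Hb) and the
RGB-univariate method, where the red channel mean is first converted to a
pseudo-absorbance ("Redbance") before fitting the same kind of line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearFit",
    "LinearityAnova",
    "redbance",
    "ols_fit",
    "predict_hb",
    "anova_linearity",
    "confidence_interval",
    "fit_to_frame",
]


@dataclass(frozen=True)
class LinearFit:
    """Univariate OLS result, retaining the normal-equations matrix so that
    the joint (intercept, slope) confidence-region test can be run later."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    ci_half_intercept: float
    ci_half_slope: float
    r: float
    n: int
    residual_sd: float
    xtx: np.ndarray  # 2x2: [[n, sum x], [sum x, sum x^2]]

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a linear fit needs at least 3 points")
        if abs(self.r) > 1.0 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        if self.ci_half_intercept < 0 or self.ci_half_slope < 0:
            raise ValueError("CI half-widths must be non-negative")
        if self.residual_sd < 0:
            raise ValueError("residual SD must be non-negative")


class LinearityAnova(NamedTuple):
    f_stat: float
    p_value: float
    perfect_fit: bool


def redbance(r_value):
    """Pseudo-absorbance of the red channel: -log10(R / 256).

    Channel values are clamped to [1, 256] before the transform so the
    darkest representable colour maps to ~2.408 and log(0) never occurs.
    The value 256 (one past the channel maximum) is accepted purely so the
    colourless limit evaluates to exactly 0.  Inputs <= 0 are rejected.
    """
    r = np.asarray(r_value, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("red channel value must be positive")
    out = -np.log10(np.clip(r, 1.0, 256.0) / 256.0)
    return float(out) if out.ndim == 0 else out


def ols_fit(x, y, alpha: float = 0.05) -> LinearFit:
    """Closed-form least squares of signal (y) on concentration (x) with
    Student-t confidence half-widths at level 1 - alpha."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 points are required")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate design: x has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    residual_sd = float(np.sqrt(sse / (n - 2)))
    se_slope = residual_sd / np.sqrt(sxx)
    se_intercept = residual_sd * np.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    xtx = np.array([[n, float(np.sum(x))], [float(np.sum(x)), float(np.sum(x**2))]])
    return LinearFit(
        intercept=intercept,
        slope=float(slope),
        se_intercept=float(se_intercept),
        se_slope=float(se_slope),
        ci_half_intercept=tcrit * float(se_intercept),
        ci_half_slope=tcrit * float(se_slope),
        r=float(r),
        n=n,
        residual_sd=residual_sd,
        xtx=xtx,
    )


def predict_hb(fit: LinearFit, signal):
    """Inverse prediction (signal - intercept) / slope.

    Sub-blank signals yield negative concentrations on purpose; truncation
    is the caller's policy (blank SDs feed the detection limit downstream).
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    out = (np.asarray(signal, dtype=float) - fit.intercept) / fit.slope
    return float(out) if out.ndim == 0 else out


def anova_linearity(fit: LinearFit) -> LinearityAnova:
    """Regression ANOVA: F = (r^2 / (1 - r^2)) * (n - 2) on (1, n-2) df."""
    r2 = fit.r**2
    df2 = fit.n - 2
    if r2 >= 1.0:
        return LinearityAnova(f_stat=float("inf"), p_value=0.0, perfect_fit=True)
    f = (r2 / (1.0 - r2)) * df2
    p = float(stats.f.sf(f, 1, df2))
    return LinearityAnova(f_stat=float(f), p_value=p, perfect_fit=False)


def confidence_interval(estimate: float, half_width: float) -> tuple[float, float]:
    if half_width < 0:
        raise ValueError("half-width must be non-negative")
    return (estimate - half_width, estimate + half_width)


def fit_to_frame(fit: LinearFit, label: str = "") -> pd.DataFrame:
    """One-row table of the scalar fit fields for CSV serialization."""
    return pd.DataFrame(
        [
            {
                "label": label,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "se_intercept": fit.se_intercept,
                "se_slope": fit.se_slope,
                "ci_half_intercept": fit.ci_half_intercept,
                "ci_half_slope": fit.ci_half_slope,
                "r": fit.r,
                "n": fit.n,
                "residual_sd": fit.residual_sd,
            }
        ]
    )
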