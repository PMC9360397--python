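"""Sample splitting, nested cross-validation and method-comparison statistics.

Comparison of a candidate method against the reference uses three classical
tools: the regression of predictions on reference values against the line
of equality, a paired t test on the per-sample differences, and the
elliptical joint confidence region (EJCR) for (intercept, slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import LinearFit, ols_fit

__all__ = [
    "SplitPlan",
    "CVResult",
    "ComparisonReport",
    "PairedT",
    "EJCRResult",
    "split_calibration",
    "nested_cv",
    "paired_t",
    "equality_line",
    "ejcr_test",
    "compare_methods",
]


@dataclass(frozen=True)
class SplitPlan:
    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    fraction: float
    stratified_by: str
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"calibration and validation overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class CVResult:
    fold_assignments: dict  # sample_id -> fold index (1-based)
    sample_ids: tuple[str, ...]
    predictions: np.ndarray
    references: np.ndarray
    per_fold_rmse: tuple[float, ...]


class PairedT(NamedTuple):
    mean_diff: float
    sd_diff: float
    t_cal: float
    t_crit: float
    n: int


class EJCRResult(NamedTuple):
    inside: bool
    statistic: float
    critical: float


@dataclass(frozen=True)
class ComparisonReport:
    method: str
    equality_fit: LinearFit
    mean_diff: float
    sd_diff: float
    t_cal: float
    t_crit: float
    ejcr_inside: bool
    ejcr_statistic: float
    ejcr_critical: float
    alpha: float = 0.05


def split_calibration(samples: pd.DataFrame, fraction: float = 0.70, seed: int = 42,
                      stratify_column: str = "fraction") -> SplitPlan:
    """Stratified random calibration/validation split.

    Within each haemolysis level, round(fraction * level size) samples go to
    calibration; on the 70-sample design this reproduces the 49/21 split.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    cal: list[str] = []
    val: list[str] = []
    for level, group in samples.groupby(stratify_column, sort=True):
        ids = group["sample_id"].to_numpy()
        if ids.size < 2:
            raise ValueError(f"haemolysis level {level} has fewer than 2 samples")
        order = rng.permutation(ids.size)
        n_cal = int(round(fraction * ids.size))
        n_cal = min(max(n_cal, 1), ids.size - 1)
        cal.extend(ids[order[:n_cal]])
        val.extend(ids[order[n_cal:]])
    return SplitPlan(
        calibration_ids=tuple(sorted(cal)),
        validation_ids=tuple(sorted(val)),
        fraction=fraction,
        stratified_by=stratify_column,
        seed=seed,
    )


def _fold_ids(samples: pd.DataFrame, k: int, seed: int) -> list[np.ndarray]:
    """Folds are animals when the animal count equals k (one cow per fold);
    otherwise a seeded stratified assignment is used with a warning."""
    animals = samples["animal_id"].unique()
    if animals.size == k:
        return [samples.loc[samples["animal_id"] == a, "sample_id"].to_numpy()
                for a in sorted(animals)]
    warnings.warn(
        f"animal count ({animals.size}) differs from fold count ({k}); "
        "falling back to stratified random folds",
        stacklevel=3,
    )
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    start = 0
    for _, group in samples.groupby("fraction", sort=True):
        ids = group["sample_id"].to_numpy()
        ids = ids[rng.permutation(ids.size)]
        for i, sid in enumerate(ids):
            folds[(start + i) % k].append(sid)
        start += ids.size
    return [np.asarray(f) for f in folds if f]


def nested_cv(
    samples: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame], object],
    predict_fn: Callable[[object, pd.DataFrame], np.ndarray],
    k: int = 10,
    seed: int = 42,
    reference_column: str = "hb_ref",
) -> CVResult:
    """K-fold cross-validation with animal-wise folds.

    Each fold's model is fitted on the remaining samples and predicts its
    own fold once, so the pooled predictions cover every sample exactly once.
    """
    folds = _fold_ids(samples, k, seed)
    indexed = samples.set_index("sample_id", drop=False)
    assignments: dict[str, int] = {}
    ids: list[str] = []
    preds: list[np.ndarray] = []
    refs: list[np.ndarray] = []
    fold_rmse: list[float] = []
    for fold_idx, fold in enumerate(folds, start=1):
        test = indexed.loc[fold]
        train = indexed.drop(index=fold)
        model = fit_fn(train.reset_index(drop=True))
        p = np.asarray(predict_fn(model, test.reset_index(drop=True)), dtype=float)
        r = test[reference_column].to_numpy(dtype=float)
        if p.shape != r.shape:
            raise ValueError("predict_fn must return one prediction per sample")
        for sid in fold:
            assignments[sid] = fold_idx
        ids.extend(fold)
        preds.append(p)
        refs.append(r)
        fold_rmse.append(float(np.sqrt(np.mean((p - r) ** 2))))
    return CVResult(
        fold_assignments=assignments,
        sample_ids=tuple(ids),
        predictions=np.concatenate(preds),
        references=np.concatenate(refs),
        per_fold_rmse=tuple(fold_rmse),
    )


def paired_t(predicted, reference, alpha: float = 0.05) -> PairedT:
    """Paired t statistic t = mean(d) * sqrt(n) / sd(d) on the per-sample
    differences, with the two-sided critical value at n - 1 df."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("predicted and reference must be 1-D and equal length")
    n = p.size
    if n < 2:
        raise ValueError("at least 2 pairs are required")
    d = p - r
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        t_cal = 0.0 if mean_diff == 0.0 else float("inf")
    else:
        t_cal = mean_diff * np.sqrt(n) / sd_diff
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    return PairedT(mean_diff=mean_diff, sd_diff=sd_diff, t_cal=float(t_cal),
                   t_crit=t_crit, n=n)


def equality_line(predicted, reference) -> LinearFit:
    """OLS of predicted (y) on reference (x); agreement means the fit is
    statistically indistinguishable from slope 1, intercept 0."""
    return ols_fit(reference, predicted)


def ejcr_test(fit: LinearFit, beta0: float = 0.0, beta1: float = 1.0,
              alpha: float = 0.05) -> EJCRResult:
    """Elliptical joint confidence-region test for (intercept, slope).

    (b - beta)' X'X (b - beta) <= 2 s^2 F(1-alpha; 2, n-2) places the
    hypothesised pair inside the 1-alpha joint region.
    """
    if fit.n <= 2:
        raise ValueError("EJCR needs more than 2 points")
    b = np.array([fit.intercept, fit.slope])
    beta = np.array([beta0, beta1])
    diff = b - beta
    statistic = float(diff @ fit.xtx @ diff)
    s2 = fit.residual_sd**2
    critical = float(2.0 * s2 * stats.f.ppf(1.0 - alpha, 2, fit.n - 2))
    return EJCRResult(inside=bool(statistic <= critical), statistic=statistic,
                      critical=critical)


def compare_methods(method: str, predicted, reference, alpha: float = 0.05) -> ComparisonReport:
    """Full agreement report: equality line, paired t, EJCR."""
    fit = equality_line(predicted, reference)
    t = paired_t(predicted, reference, alpha=alpha)
    ejcr = ejcr_test(fit, alpha=alpha)
    return ComparisonReport(
        method=method,
        equality_fit=fit,
        mean_diff=t.mean_diff,
        sd_diff=t.sd_diff,
        t_cal=t.t_cal,
        t_crit=t.t_crit,
        ejcr_inside=ejcr.inside,
        ejcr_statistic=ejcr.statistic,
        ejcr_critical=ejcr.critical,
        alpha=alpha,
    )
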