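"""Analytical figures of merit: precision (CV%), LOD, LOQ, linearity, recovery."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MeritReport",
    "cv_percent",
    "lod_loq",
    "mean_recovery",
    "merit_report",
    "reports_to_frame",
]

#: Hb levels (g/L) at which precision is studied.
PRECISION_LEVELS = (0.5, 2.5, 10.0)

#: Upper end of the tested linear range (g/L).
LINEARITY_HIGH = 10.0


@dataclass(frozen=True)
class MeritReport:
    method: str
    cv_by_level: dict  # Hb level (g/L) -> CV%
    lod: float | None
    loq: float | None
    linearity_low: float | None
    linearity_high: float | None
    mean_recovery: float | None


def cv_percent(replicate_values) -> float:
    """Coefficient of variation: sample SD over mean, times 100."""
    v = np.asarray(replicate_values, dtype=float)
    if v.size < 2:
        raise ValueError("at least 2 replicate values are required")
    mean = float(v.mean())
    if mean == 0.0:
        raise ValueError("CV is undefined for zero-mean replicates")
    return float(v.std(ddof=1) / mean * 100.0)


def lod_loq(blank_predictions) -> tuple[float, float]:
    """LOD = 3x and LOQ = 10x the sample SD of the blank determinations.

    Ten blanks are expected; other counts are accepted with a warning.
    Blank predictions may legitimately be negative (inverse prediction of
    sub-blank signals)."""
    v = np.asarray(blank_predictions, dtype=float)
    if v.size < 2:
        raise ValueError("at least 2 blank determinations are required")
    if v.size != 10:
        warnings.warn(f"LOD/LOQ defined for 10 blanks; got {v.size}", stacklevel=2)
    sd = float(v.std(ddof=1))
    return 3.0 * sd, 10.0 * sd


def mean_recovery(predicted, reference) -> float:
    """Mean of 100 * predicted / reference over pairs with positive reference.

    Zero-reference blanks are excluded (the ratio is undefined there)."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError("predicted and reference must have equal length")
    keep = r > 0.0
    if not np.any(keep):
        raise ValueError("recovery needs at least one pair with positive reference")
    return float(np.mean(100.0 * p[keep] / r[keep]))


def merit_report(
    method: str,
    replicate_predictions: dict | None = None,
    blank_predictions=None,
    validation_predicted=None,
    validation_reference=None,
) -> MeritReport:
    """Assemble a Table-1-style row; missing ingredients yield None fields.

    ``replicate_predictions`` maps an Hb level (g/L) to the predicted
    concentrations of its replicate specimens.  The linearity range runs
    from the LOD up to the top tested level.
    """
    cv_by_level: dict = {}
    if replicate_predictions:
        for level, values in sorted(replicate_predictions.items()):
            cv_by_level[float(level)] = cv_percent(values)
    lod = loq = lin_low = lin_high = None
    if blank_predictions is not None:
        lod, loq = lod_loq(blank_predictions)
        lin_low, lin_high = lod, LINEARITY_HIGH
    recovery = None
    if validation_predicted is not None and validation_reference is not None:
        recovery = mean_recovery(validation_predicted, validation_reference)
    return MeritReport(
        method=method,
        cv_by_level=cv_by_level,
        lod=lod,
        loq=loq,
        linearity_low=lin_low,
        linearity_high=lin_high,
        mean_recovery=recovery,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Table-1-shaped frame: one row per figure of merit, one column per method."""
    levels = sorted({lvl for rep in reports for lvl in rep.cv_by_level})
    rows = [f"cv_percent_at_{lvl:g}" for lvl in levels] + [
        "lod", "loq", "linearity_low", "linearity_high", "mean_recovery",
    ]
    data = {}
    for rep in reports:
        col = [rep.cv_by_level.get(lvl, math.nan) for lvl in levels]
        col += [
            math.nan if rep.lod is None else rep.lod,
            math.nan if rep.loq is None else rep.loq,
            math.nan if rep.linearity_low is None else rep.linearity_low,
            math.nan if rep.linearity_high is None else rep.linearity_high,
            math.nan if rep.mean_recovery is None else rep.mean_recovery,
        ]
        data[rep.method] = col
    return pd.DataFrame(data, index=rows)
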