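"""End-to-end orchestration: simulate -> calibrate -> validate -> report.

Everything is driven by a :class:`PipelineConfig`, all randomness flows
through explicit seeds, and every artifact written is recorded in a
manifest with a content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import merit as merit_mod
from . import multivariate as mv
from . import univariate as uv
from . import validation as val
from .synthetic import (
    STUDY_FRACTIONS,
    ForwardModelParams,
    generate_design,
    generate_replicates,
    generate_samples,
    write_samples,
)

__all__ = ["PipelineConfig", "AnalysisResult", "analyse_samples", "run_pipeline", "METHODS"]

METHODS = ("uv", "red", "pls", "ann")
PREDICTORS = ["r_mean", "g_mean", "b_mean", "intensity"]

logger = logging.getLogger("serumhb")


@dataclass(frozen=True)
class PipelineConfig:
    n_animals: int = 10
    fractions: tuple[float, ...] = STUDY_FRACTIONS
    seed: int = 42
    split_seed: int = 42
    split_fraction: float = 0.70
    cv_folds: int = 10
    methods: tuple[str, ...] = METHODS
    n_lf: int | None = None          # None -> cross-validated selection
    ann_seed: int = 42
    ann_max_epochs: int = 500
    ann_learning_rate: float = 0.2
    ann_momentum: float = 0.5
    merit_seed: int = 1042
    n_replicates: int = 10
    n_blanks: int = 10
    # recovery is only meaningful at quantifiable levels; pairs whose
    # reference lies below this (g/L) are excluded from mean recovery
    recovery_min_ref: float = 0.5
    params: ForwardModelParams = field(default_factory=ForwardModelParams)

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown} (choose from {METHODS})")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "params" in raw and not isinstance(raw["params"], ForwardModelParams):
            raw["params"] = ForwardModelParams(**raw["params"])
        if "fractions" in raw:
            raw["fractions"] = tuple(float(f) for f in raw["fractions"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        known = {f.name for f in fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["fractions"] = list(self.fractions)
        raw["methods"] = list(self.methods)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


class AnalysisResult(NamedTuple):
    comparisons: list[val.ComparisonReport]
    merits: list[merit_mod.MeritReport]
    univariate_fits: dict[str, uv.LinearFit]
    n_lf: int | None


def _ann_spec(config: PipelineConfig) -> mv.ANNSpec:
    return mv.ANNSpec(
        seed=config.ann_seed,
        max_epochs=config.ann_max_epochs,
        learning_rate=config.ann_learning_rate,
        momentum=config.ann_momentum,
    )


def _univariate_predictor(fit: uv.LinearFit, method: str) -> Callable:
    def predict(df: pd.DataFrame) -> np.ndarray:
        if method == "uv":
            signal = df["absorbance540"].to_numpy()
        else:
            signal = uv.redbance(df["r_mean"].to_numpy())
        return uv.predict_hb(fit, signal)

    return predict


def analyse_samples(samples: pd.DataFrame, config: PipelineConfig) -> AnalysisResult:
    """Calibrate, validate and compute figures of merit for every method.

    Univariate methods (uv, red) use the stratified 70/30 split; the
    multivariate methods (pls, ann) use animal-wise nested cross-validation.
    """
    plan = val.split_calibration(samples, fraction=config.split_fraction,
                                 seed=config.split_seed)
    cal = samples[samples["sample_id"].isin(plan.calibration_ids)]
    valset = samples[samples["sample_id"].isin(plan.validation_ids)]
    logger.info("split seed=%d calibration=%d validation=%d",
                config.split_seed, len(cal), len(valset))

    comparisons: list[val.ComparisonReport] = []
    merits: list[merit_mod.MeritReport] = []
    fits: dict[str, uv.LinearFit] = {}
    selected_n_lf: int | None = None

    for method in ("uv", "red"):
        if method not in config.methods:
            continue
        if method == "uv":
            signal = cal["absorbance540"].to_numpy()
        else:
            signal = uv.redbance(cal["r_mean"].to_numpy())
        fit = uv.ols_fit(cal["hb_ref"].to_numpy(), signal)
        fits[method] = fit
        logger.info("%s calibration: intercept=%.4f slope=%.4f r=%.4f",
                    method, fit.intercept, fit.slope, fit.r)
        predictor = _univariate_predictor(fit, method)
        pred = predictor(valset)
        ref = valset["hb_ref"].to_numpy()
        comparisons.append(val.compare_methods(method, pred, ref))
        merits.append(_merit_for(config, method, predictor, pred, ref))

    if "pls" in config.methods:
        X = samples[PREDICTORS].to_numpy()
        y = samples["hb_ref"].to_numpy()
        selected_n_lf = config.n_lf or mv.select_n_lf(X, y, max_lf=4, seed=config.seed)
        logger.info("PLSR latent factors: %d", selected_n_lf)

        def fit_pls(df, a=selected_n_lf):
            return mv.pls_fit(df[PREDICTORS].to_numpy(), df["hb_ref"].to_numpy(), n_lf=a)

        def predict_pls(model, df):
            return mv.pls_predict(model, df[PREDICTORS].to_numpy())

        cv = val.nested_cv(samples, fit_pls, predict_pls, k=config.cv_folds,
                           seed=config.seed)
        comparisons.append(val.compare_methods("pls", cv.predictions, cv.references))
        full = fit_pls(samples)
        merits.append(_merit_for(config, "pls",
                                 lambda df, m=full: mv.pls_predict(m, df[PREDICTORS].to_numpy()),
                                 cv.predictions, cv.references))

    if "ann" in config.methods:
        def fit_ann(df):
            model = mv.ann_init(_ann_spec(config))
            return mv.ann_train(model, df[PREDICTORS].to_numpy(), df["hb_ref"].to_numpy())

        def predict_ann(model, df):
            return mv.ann_predict(model, df[PREDICTORS].to_numpy())

        cv = val.nested_cv(samples, fit_ann, predict_ann, k=config.cv_folds,
                           seed=config.seed)
        comparisons.append(val.compare_methods("ann", cv.predictions, cv.references))
        full = fit_ann(samples)
        merits.append(_merit_for(config, "ann",
                                 lambda df, m=full: mv.ann_predict(m, df[PREDICTORS].to_numpy()),
                                 cv.predictions, cv.references))

    return AnalysisResult(comparisons=comparisons, merits=merits,
                          univariate_fits=fits, n_lf=selected_n_lf)


def _merit_for(config: PipelineConfig, method: str, predictor, val_pred, val_ref
               ) -> merit_mod.MeritReport:
    """Figures of merit from freshly simulated replicate and blank specimens."""
    replicate_predictions = {}
    for i, level in enumerate(merit_mod.PRECISION_LEVELS):
        reps = generate_replicates(level, config.n_replicates, config.params,
                                   seed=config.merit_seed + i)
        replicate_predictions[level] = predictor(reps)
    blanks = generate_replicates(0.0, config.n_blanks, config.params,
                                 seed=config.merit_seed + 100)
    val_pred = np.asarray(val_pred, dtype=float)
    val_ref = np.asarray(val_ref, dtype=float)
    keep = val_ref >= config.recovery_min_ref
    return merit_mod.merit_report(
        method,
        replicate_predictions=replicate_predictions,
        blank_predictions=predictor(blanks),
        validation_predicted=val_pred[keep],
        validation_reference=val_ref[keep],
    )


def comparison_row(report: val.ComparisonReport) -> dict:
    fit = report.equality_fit
    return {
        "method": report.method,
        "intercept": fit.intercept,
        "slope": fit.slope,
        "ci_half_intercept": fit.ci_half_intercept,
        "ci_half_slope": fit.ci_half_slope,
        "r": fit.r,
        "n": fit.n,
        "mean_diff": report.mean_diff,
        "sd_diff": report.sd_diff,
        "t_cal": report.t_cal,
        "t_crit": report.t_crit,
        "ejcr_statistic": report.ejcr_statistic,
        "ejcr_critical": report.ejcr_critical,
        "ejcr_inside": report.ejcr_inside,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis and return a manifest of the written artifacts.

    Artifacts: samples.csv, calibration_{uv,red}.csv, comparison.csv,
    merit.csv, manifest.json and pipeline.log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    artifacts: list[Path] = []
    try:
        logger.info("design seed=%d n_animals=%d fractions=%s",
                    config.seed, config.n_animals, list(config.fractions))
        design = generate_design(config.n_animals, config.fractions, seed=config.seed)
        samples = generate_samples(design, config.params)
        samples_path = outdir / "samples.csv"
        write_samples(samples, samples_path)
        artifacts.append(samples_path)
        logger.info("wrote %s (%d rows)", samples_path, len(samples))

        result = analyse_samples(samples, config)

        for method, fit in result.univariate_fits.items():
            path = outdir / f"calibration_{method}.csv"
            uv.fit_to_frame(fit, method).to_csv(path, index=False)
            artifacts.append(path)

        comparison_path = outdir / "comparison.csv"
        pd.DataFrame([comparison_row(c) for c in result.comparisons]).to_csv(
            comparison_path, index=False)
        artifacts.append(comparison_path)

        merit_path = outdir / "merit.csv"
        merit_mod.reports_to_frame(result.merits).to_csv(merit_path, index_label="figure")
        artifacts.append(merit_path)

        manifest = {
            "config": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                              encoding="utf-8")
        logger.info("wrote manifest with %d artifacts", len(artifacts))
        return manifest
    except Exception:
        # retain partial outputs alongside a manifest of what was written
        manifest = {"artifacts": {p.name: _sha256(p) for p in artifacts if p.exists()},
                    "status": "failed"}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                              encoding="utf-8")
        logger.exception("pipeline failed; partial manifest retained")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
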