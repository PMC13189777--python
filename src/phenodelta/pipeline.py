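"""End-to-end two-stage pipeline: score → ΔPhenoAge → screen → best subset.

Stage 1 is a pooled partial-correlation screen of every lifestyle factor
against ΔPhenoAge adjusting for sex and ΔAge; stage 2 fits exact
best-subset (minimum-AIC) linear models separately for men and women with
ΔAge forced in.  Every artifact is a provenance-headed CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import PipelineConfig, write_csv_with_provenance
from .phenoage import six_marker_spec
from .screening import ScreenReport, screen_factors
from .simulate import FACTOR_COLUMNS, score_cohort
from .subset import SubsetModel, best_subset

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where the artifacts landed."""

    cohort: pd.DataFrame
    screen: ScreenReport
    models: dict                      # sex -> SubsetModel
    artifacts: dict = field(default_factory=dict)  # name -> Path


def _provenance(config: PipelineConfig, stage: str) -> dict:
    return {
        "generator": f"phenodelta {__version__}",
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "coefficients": six_marker_spec().version,
    }


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame,
                 write: bool = True) -> PipelineResult:
    """Run scoring, screening and sex-stratified subset selection.

    ``cohort`` must carry the two-visit biomarker panels (or pre-scored
    PhenoAge columns) and the lifestyle factors.  Artifacts (screen report,
    one model report per sex, summary tables) are written under
    ``config.output_dir`` unless ``write=False``.
    """
    try:
        if config.outcome not in cohort.columns:
            cohort = score_cohort(cohort)
            if config.outcome not in cohort.columns:
                raise KeyError(f"outcome column {config.outcome!r} absent after scoring")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'score' failed: {exc}") from exc

    factors = list(config.factors) if config.factors is not None else [
        c for c in FACTOR_COLUMNS if c in cohort.columns]
    work = cohort.copy()
    if "sex_indicator" in config.covariates and "sex_indicator" not in work.columns:
        work["sex_indicator"] = (work[config.sex_col] == "male").astype(float)

    try:
        report = screen_factors(work, config.outcome, config.covariates,
                                factor_names=factors, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'screen' failed: {exc}") from exc

    candidates = [f for f in report.selected if f not in config.forced]
    models: dict = {}
    try:
        for sex, grp in work.groupby(config.sex_col):
            models[sex] = best_subset(candidates, list(config.forced), grp,
                                      config.outcome)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'select' failed: {exc}") from exc

    result = PipelineResult(cohort=cohort, screen=report, models=models)
    if write:
        outdir = Path(config.output_dir)
        screen_path = outdir / "screen.csv"
        write_csv_with_provenance(report.results, screen_path,
                                  _provenance(config, "screen"))
        result.artifacts["screen"] = screen_path
        for sex, model in models.items():
            table = _model_table(model)
            meta = _provenance(config, f"select[{sex}]")
            meta["adjusted_r2"] = f"{100 * model.fit.r2_adj:.2f}%"
            if len(model.vif):
                meta["max_vif"] = f"{model.vif.max():.2f}"
            path = outdir / f"model_{sex}.csv"
            write_csv_with_provenance(table, path, meta)
            result.artifacts[f"model_{sex}"] = path
        from .simulate import summarize_cohort
        summary = summarize_cohort(cohort)
        for name in ("continuous", "categorical"):
            path = outdir / f"summary_{name}.csv"
            write_csv_with_provenance(summary[name], path,
                                      _provenance(config, f"summarize[{name}]"))
            result.artifacts[f"summary_{name}"] = path
    return result


def _model_table(model: SubsetModel) -> pd.DataFrame:
    fit = model.fit
    rows = []
    for name in fit.beta.index:
        rows.append({
            "predictor": name,
            "beta": fit.beta[name],
            "se": fit.se[name],
            "p": fit.p[name],
            "stars": _stars(fit.p[name]),
            "vif": model.vif.get(name, np.nan) if len(model.vif) else np.nan,
            "forced": name in model.forced,
        })
    return pd.DataFrame(rows)
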