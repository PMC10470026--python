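"""End-to-end orchestration: train on one cohort, validate on another.

``run_pipeline`` wires the stages together — univariate gene screen,
lasso-Cox selection, bootstrap Coef/SD weighting of genes and cells, TM and
TME scoring, per-cohort median splits, subgroup assignment and survival
evaluation — and writes all artifacts (selection.json, weights.json,
scores.tsv, labels.tsv, stats.json, run.log) under the output directory.
The validation cohort is scored with the training weights but split at its
own score medians.  Every output is reproducible from config + seed alone;
run.log records versions, seeds and dropped resamples.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import TMTMEClassifier
from .io import (
    intersect_samples,
    read_clinical,
    read_expression,
    read_fractions,
    read_gene_list,
    write_json,
    write_tsv,
)
from .survival import DAYS_PER_YEAR, ValidationError

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


@dataclass
class CohortPaths:
    expression: str
    fractions: str
    clinical: str

    @classmethod
    def from_dict(cls, d: dict, which: str) -> "CohortPaths":
        missing = [k for k in ("expression", "fractions", "clinical") if k not in d]
        if missing:
            raise ValidationError(f"{which} cohort config lacks {missing}")
        return cls(**{k: str(d[k]) for k in ("expression", "fractions", "clinical")})


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    training: CohortPaths
    validation: CohortPaths | None = None
    gene_list: str | None = None          # candidate telomere genes; default all
    cells: list | None = None             # designated favorable-cell signature
    covariates: list = field(default_factory=list)
    expression_orientation: str = "genes_by_samples"
    screen_alpha: float = 0.05
    cell_alpha: float = 0.05
    lambda_rule: str = "min"
    cv_folds: int = 5
    B: int = 1000
    ties: str = "efron"
    tie_policy: str = "low"
    horizons: list = field(default_factory=lambda: [3.0, 5.0, 7.0])
    days_per_year: float = DAYS_PER_YEAR
    seed: int = 0
    outdir: str = "tmtme_run"

    def __post_init__(self):
        if any(h <= 0 for h in self.horizons):
            raise ValidationError("horizons must be positive (years)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "training" not in raw:
            raise ValidationError(f"config {path} must define a 'training' cohort")
        kwargs = dict(raw)
        kwargs["training"] = CohortPaths.from_dict(raw["training"], "training")
        if raw.get("validation"):
            kwargs["validation"] = CohortPaths.from_dict(raw["validation"], "validation")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _load_cohort(paths: CohortPaths, config: PipelineConfig, which: str):
    with _stage(f"read[{which}]"):
        expr = read_expression(paths.expression,
                               orientation=config.expression_orientation)
        frac = read_fractions(paths.fractions)
        surv, extra = read_clinical(paths.clinical)
        expr, frac, surv, dropped = intersect_samples(expr, frac, surv)
        extra = extra.reindex(expr.index)
    return expr, frac, surv, extra, dropped


def _evaluate_cohort(model: TMTMEClassifier, expr, frac, surv, extra,
                     config: PipelineConfig, which: str, outdir: Path) -> dict:
    X = expr.join(frac)
    cov = None
    if config.covariates:
        missing = [c for c in config.covariates if c not in extra.columns]
        if missing:
            raise ValidationError(f"{which}: clinical covariates absent: {missing}")
        cov = extra[config.covariates].astype(float)
    with _stage(f"evaluate[{which}]"):
        report = model.evaluate(X, surv, horizons=tuple(config.horizons),
                                covariates=cov, days_per_year=config.days_per_year)
        labels = model.predict_subgroups(X)
        scores = model.transform(X)
        scores["risk_score"] = model.decision_function(X)
    cdir = outdir / which
    cdir.mkdir(parents=True, exist_ok=True)
    write_tsv(scores.reset_index(), cdir / "scores.tsv")
    write_tsv(labels.to_frame(), cdir / "labels.tsv")
    write_json(report, cdir / "stats.json")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full TM-TME construction; returns the stats report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"tmtme {__version__} | numpy {np.__version__} | pandas {pd.__version__}",
                 f"seed {config.seed}"]

    expr, frac, surv, extra, dropped = _load_cohort(config.training, config, "training")
    log_lines.append(f"training: {expr.shape[0]} samples, {expr.shape[1]} genes, "
                     f"{frac.shape[1]} cell types, {surv.n_events} events, "
                     f"{len(dropped)} samples excluded by id intersection")

    if config.gene_list:
        with _stage("gene_list"):
            candidates = read_gene_list(config.gene_list)
            absent = [g for g in candidates if g not in expr.columns]
            if absent:
                logger.warning("%d candidate gene(s) absent from expression: %s%s",
                               len(absent), absent[:5], "..." if len(absent) > 5 else "")
            gene_cols = [g for g in candidates if g in expr.columns]
            if not gene_cols:
                raise ValidationError("no candidate gene found in the expression matrix")
    else:
        gene_cols = list(expr.columns)

    model = TMTMEClassifier(
        gene_cols=gene_cols, cell_cols=list(frac.columns), cells=config.cells,
        screen_alpha=config.screen_alpha, cell_alpha=config.cell_alpha,
        lambda_rule=config.lambda_rule, cv_folds=config.cv_folds,
        B=config.B, ties=config.ties, tie_policy=config.tie_policy,
        seed=config.seed)
    with _stage("train"):
        model.fit(expr.join(frac), surv)
    log_lines += [
        f"screen: {len(model.screened_genes_)} / {len(gene_cols)} genes at "
        f"alpha={config.screen_alpha}",
        f"lasso: {len(model.selected_genes_)} genes at lambda="
        f"{model.selector_.lambda_:.6g}",
        f"cells: {len(model.selected_cells_)} in TME signature",
        f"gene bootstrap: {model.gene_weights_.n_converged}/{model.gene_weights_.n_resamples} "
        f"refits converged (seed {model.gene_weights_.seed})",
        f"cell bootstrap: {model.cell_weights_.n_converged}/{model.cell_weights_.n_resamples} "
        f"refits converged (seed {model.cell_weights_.seed})",
    ]

    write_json(model.selector_.result().to_dict()
               | {"screened_genes": model.screened_genes_,
                  "candidate_genes": len(gene_cols)},
               outdir / "selection.json")
    write_json({"genes": model.gene_weights_.to_dict(),
                "cells": model.cell_weights_.to_dict()}, outdir / "weights.json")

    config_dump = config.to_dict()
    config_dump.pop("outdir", None)  # same analysis, different destination => same stats
    stats = {"config": config_dump, "seed": config.seed,
             "selected_genes": model.selected_genes_,
             "selected_cells": model.selected_cells_}
    stats["training"] = _evaluate_cohort(model, expr, frac, surv, extra,
                                         config, "training", outdir)

    if config.validation is not None:
        vexpr, vfrac, vsurv, vextra, vdrop = _load_cohort(config.validation,
                                                          config, "validation")
        log_lines.append(f"validation: {vexpr.shape[0]} samples, "
                         f"{vsurv.n_events} events, {len(vdrop)} excluded")
        stats["validation"] = _evaluate_cohort(model, vexpr, vfrac, vsurv, vextra,
                                               config, "validation", outdir)

    write_json(stats, outdir / "stats.json")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return stats
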