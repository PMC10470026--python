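"""Synthetic glioma-style cohorts for exercising the TM-TME pipeline.

A cohort consists of (a) a samples x genes expression matrix on the
log2(TPM+1) scale, (b) a samples x cell-types immune-fraction matrix on the
probability simplex (the shape of a CIBERSORT output), and (c) a
right-censored overall-survival outcome.  Survival times follow a Cox model
with an exponential baseline hazard whose linear predictor combines
standardized signal-gene expression and raw cell fractions, so the planted
log-hazard effects are exact ground truth.  Censoring is independent
exponential, with its rate solved numerically so the expected censored
fraction matches ``censoring_target``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .survival import SurvivalData, ValidationError

DAYS_PER_YEAR = 365.25

#: Default planted design: 10 signal genes of mixed sign at |log-hazard| 0.5
#: per expression SD, and 5 favorable immune cells at log-hazard -3 per unit
#: fraction, among 10 cell types.
DEFAULT_SIGNAL_EFFECTS = (0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5)
DEFAULT_CELL_EFFECTS = (-3.0, -3.0, -3.0, -3.0, -3.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters of one synthetic cohort.

    ``signal_effects`` are log hazard ratios per standard deviation of
    (truncated-normal) signal-gene expression; ``cell_effects`` are log
    hazard ratios per unit fraction, one per cell type, with the favorable
    cells carrying negative entries.  ``baseline_hazard`` is the exponential
    event rate per day for a sample at the covariate baseline; the default
    puts the baseline median survival near five years.
    """

    n_samples: int = 600
    n_genes: int = 200
    n_signal_genes: int = 10
    signal_effects: tuple = DEFAULT_SIGNAL_EFFECTS
    n_cell_types: int = 10
    favorable_cells: tuple = (0, 1, 2, 3, 4)
    cell_effects: tuple = DEFAULT_CELL_EFFECTS
    baseline_hazard: float = math.log(2) / (5 * DAYS_PER_YEAR)
    censoring_target: float = 0.3
    expression_mean: float = 3.0
    expression_sd: float = 1.2
    dirichlet_concentration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ValidationError(f"invalid config field {name!r}: {why}")

        if self.n_samples < 2:
            bad("n_samples", "must be a positive integer >= 2")
        if self.n_genes < 1:
            bad("n_genes", "must be a positive integer")
        if not 0 <= self.n_signal_genes <= self.n_genes:
            bad("n_signal_genes", "must lie in [0, n_genes]")
        if len(self.signal_effects) != self.n_signal_genes:
            bad("signal_effects", f"length {len(self.signal_effects)} != "
                f"n_signal_genes {self.n_signal_genes}")
        if self.n_cell_types < 5:
            bad("n_cell_types", "must be >= 5")
        if len(self.cell_effects) != self.n_cell_types:
            bad("cell_effects", f"length {len(self.cell_effects)} != "
                f"n_cell_types {self.n_cell_types}")
        if any(not 0 <= j < self.n_cell_types for j in self.favorable_cells):
            bad("favorable_cells", "indices must lie in [0, n_cell_types)")
        if self.baseline_hazard <= 0:
            bad("baseline_hazard", "must be positive")
        if not 0 < self.censoring_target < 1:
            bad("censoring_target", "must lie strictly inside (0, 1)")
        if self.expression_sd <= 0:
            bad("expression_sd", "must be positive")
        if self.dirichlet_concentration <= 0:
            bad("dirichlet_concentration", "must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("signal_effects", "favorable_cells", "cell_effects"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        d = dict(d)
        for key in ("signal_effects", "favorable_cells", "cell_effects"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """One generated cohort plus the ground truth that produced it."""

    expression: pd.DataFrame       # samples x genes, log2(TPM+1)-like
    fractions: pd.DataFrame        # samples x cell types, rows on the simplex
    survival: SurvivalData
    truth: dict

    @property
    def sample_ids(self) -> np.ndarray:
        return self.survival.sample_ids

    def features(self) -> pd.DataFrame:
        """Expression and fraction columns joined on sample id."""
        return self.expression.join(self.fractions)


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with E[fraction censored] = target.

    With event ~ Exp(h_i) and censoring ~ Exp(c) independent, sample i is
    censored with probability c / (c + h_i); solve the cohort mean for c.
    """

    def mean_censored(log_c):
        c = math.exp(log_c)
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = math.log(hazards.min()) - 20, math.log(hazards.max()) + 20
    return math.exp(optimize.brentq(mean_censored, lo, hi, xtol=1e-12))


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_samples, config.n_genes, config.n_cell_types

    sample_ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    gene_ids = np.array([f"G{i:04d}" for i in range(g)], dtype=object)
    cell_ids = np.array([f"Cell{j:02d}" for j in range(k)], dtype=object)

    expr = rng.normal(config.expression_mean, config.expression_sd, size=(n, g))
    np.clip(expr, 0.0, None, out=expr)  # log2(TPM+1) values are non-negative

    frac = rng.dirichlet(np.full(k, config.dirichlet_concentration), size=n)

    signal = np.asarray(config.signal_effects, dtype=float)
    cell_eff = np.asarray(config.cell_effects, dtype=float)
    # effects act per expression SD, so planted sizes are scale-free
    z_signal = (expr[:, : config.n_signal_genes] - config.expression_mean) / config.expression_sd
    lp = z_signal @ signal + frac @ cell_eff
    hazards = config.baseline_hazard * np.exp(lp)

    event_time = rng.exponential(1.0 / hazards)
    cens_rate = _solve_censoring_rate(hazards, config.censoring_target)
    cens_time = rng.exponential(1.0 / cens_rate, size=n)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    time = np.maximum(time, 1e-9)  # strictly positive by contract

    truth = {
        "gene_effects": {str(gid): float(b)
                         for gid, b in zip(gene_ids[: config.n_signal_genes], signal)},
        "cell_effects": {str(cid): float(b) for cid, b in zip(cell_ids, cell_eff)},
        "favorable_cells": [str(cell_ids[j]) for j in config.favorable_cells],
        "baseline_hazard": config.baseline_hazard,
        "censoring_rate": cens_rate,
        "censoring_target": config.censoring_target,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    expression = pd.DataFrame(expr, index=pd.Index(sample_ids, name="sample_id"),
                              columns=gene_ids)
    fractions = pd.DataFrame(frac, index=pd.Index(sample_ids, name="sample_id"),
                             columns=cell_ids)
    survival = SurvivalData(sample_ids, time, event)
    return SyntheticCohort(expression=expression, fractions=fractions,
                           survival=survival, truth=truth)
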