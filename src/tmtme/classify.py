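"""The TM-TME classifier: median-split subgroups and their evaluation.

Each cohort is split at its *own* sample medians of the TM and TME scores
(medians are never carried over from a training cohort), crossed into four
subgroups, and the two concordant subgroups (TM_L+TME_L, TM_H+TME_H) are
merged into "Mixed".  Evaluation covers per-subgroup Kaplan-Meier curves,
the 3-group log-rank test, Cox models of the subgroup labels (reference
TM_L+TME_H), and IPCW time-dependent AUC at the requested horizons.

``TMTMEClassifier`` bundles the whole construction as a scikit-learn
estimator: ``fit`` learns the gene signature and the Coef/SD weights on a
training cohort; ``predict`` scores a (possibly different) cohort and
labels it with that cohort's own medians, mirroring the train/validate
transfer protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .survival import (
    DAYS_PER_YEAR,
    SurvivalData,
    ValidationError,
    as_survival,
    fit_cox,
    km_estimate,
    logrank_test,
    td_roc,
)
from .selection import LassoCoxSelector, UnivariateCoxScreen
from .scoring import BootstrapCoxWeighter, ScoreVector, tm_score, tme_score

logger = logging.getLogger(__name__)

FOUR_LEVELS = ("TM_L+TME_H", "TM_L+TME_L", "TM_H+TME_H", "TM_H+TME_L")
THREE_LEVELS = ("TM_L+TME_H", "Mixed", "TM_H+TME_L")
MERGED = ("TM_L+TME_L", "TM_H+TME_H")


def median_split(scores, tie_policy: str = "low"):
    """Split a score vector at its sample median into 'low' / 'high'.

    Scores exactly at the median go to 'low' by default (``tie_policy``
    'high' flips that).  All-identical scores make the split undefined.
    """
    if isinstance(scores, ScoreVector):
        values = scores.score
    else:
        values = np.asarray(scores, dtype=float)
    if values.shape[0] < 2:
        raise ValidationError("median split needs at least 2 samples")
    if np.ptp(values) == 0:
        raise ValidationError("all scores identical; median split undefined")
    med = float(np.median(values))
    if tie_policy == "low":
        labels = np.where(values <= med, "low", "high")
    elif tie_policy == "high":
        labels = np.where(values < med, "low", "high")
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    return labels, med


@dataclass
class SubgroupLabels:
    """TM-TME subgroup assignments plus the medians that produced them."""

    sample_ids: np.ndarray
    tm_group: np.ndarray      # 'low' / 'high'
    tme_group: np.ndarray     # 'low' / 'high'
    four_level: np.ndarray
    three_level: np.ndarray
    tm_median: float
    tme_median: float

    def __len__(self):
        return self.sample_ids.shape[0]

    def counts(self, level: str = "three") -> dict:
        labels = self.three_level if level == "three" else self.four_level
        order = THREE_LEVELS if level == "three" else FOUR_LEVELS
        return {g: int((labels == g).sum()) for g in order}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids, "tm_group": self.tm_group,
            "tme_group": self.tme_group, "four_level": self.four_level,
            "three_level": self.three_level})


def assign_subgroups(tm_labels, tme_labels, sample_ids=None,
                     tm_median: float = float("nan"),
                     tme_median: float = float("nan")) -> SubgroupLabels:
    """Cross TM and TME low/high labels into the four- and three-level groups.

    Accepts plain arrays (aligned positionally) or pandas Series indexed by
    sample id, in which case the sample sets must coincide.
    """
    if isinstance(tm_labels, pd.Series) and isinstance(tme_labels, pd.Series):
        sym = set(tm_labels.index).symmetric_difference(tme_labels.index)
        if sym:
            raise ValidationError(
                f"TM and TME label sample sets differ: {sorted(map(str, sym))[:10]}")
        sample_ids = tm_labels.index.to_numpy(dtype=object)
        tme_labels = tme_labels.reindex(tm_labels.index)
        tm = tm_labels.to_numpy()
        tme = tme_labels.to_numpy()
    else:
        tm = np.asarray(tm_labels)
        tme = np.asarray(tme_labels)
        if tm.shape != tme.shape:
            raise ValidationError("TM and TME label vectors differ in length")
        if sample_ids is None:
            sample_ids = np.arange(tm.shape[0]).astype(object)
    for arr, name in ((tm, "tm"), (tme, "tme")):
        if not np.isin(arr, ["low", "high"]).all():
            raise ValidationError(f"{name} labels must be 'low' or 'high'")
    four = np.char.add(np.char.add(
        np.where(tm == "low", "TM_L", "TM_H"), "+"),
        np.where(tme == "low", "TME_L", "TME_H"))
    three = np.where(np.isin(four, MERGED), "Mixed", four)
    return SubgroupLabels(sample_ids=np.asarray(sample_ids, dtype=object),
                          tm_group=tm, tme_group=tme,
                          four_level=four, three_level=three,
                          tm_median=tm_median, tme_median=tme_median)


def build_subgroups(tm: ScoreVector, tme: ScoreVector,
                    tie_policy: str = "low") -> SubgroupLabels:
    """Median-split both scores and cross them (one cohort, its own medians)."""
    if not np.array_equal(tm.sample_ids, tme.sample_ids):
        raise ValidationError("TM and TME score vectors cover different samples")
    tm_lab, tm_med = median_split(tm, tie_policy)
    tme_lab, tme_med = median_split(tme, tie_policy)
    return assign_subgroups(tm_lab, tme_lab, sample_ids=tm.sample_ids,
                            tm_median=tm_med, tme_median=tme_med)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def combined_risk_score(tm: ScoreVector, tme: ScoreVector) -> np.ndarray:
    """Continuous TM-TME risk: standardized TM minus standardized TME."""
    return _zscore(tm.score) - _zscore(tme.score)


def evaluate_classifier(labels: SubgroupLabels, survival: SurvivalData,
                        scores: dict | None = None,
                        horizons=(3.0, 5.0, 7.0),
                        covariates: pd.DataFrame | None = None,
                        days_per_year: float = DAYS_PER_YEAR) -> dict:
    """Survival evaluation of the three-level TM-TME subgroups.

    Produces per-subgroup KM curves, the multi-group log-rank test, Cox
    hazard ratios of the subgroup labels versus TM_L+TME_H (univariate, and
    multivariate when clinical ``covariates`` are supplied), and the IPCW
    time-dependent AUC of the combined risk score (and of TM / TME alone)
    at each horizon, given in years.
    """
    survival = survival.reindex(labels.sample_ids)
    three = labels.three_level
    present = [g for g in THREE_LEVELS if (three == g).sum() > 0]
    report: dict = {"subgroup_counts": labels.counts("three"),
                    "four_level_counts": labels.counts("four"),
                    "tm_median": labels.tm_median, "tme_median": labels.tme_median,
                    "n_samples": len(labels), "n_events": survival.n_events}

    if len(present) < 2:
        logger.warning("fewer than two populated subgroups; survival contrasts skipped")
        report["logrank"] = None
        report["km"] = {}
        return report

    mask = np.isin(three, present)
    km = km_estimate(survival.subset(mask), three[mask])
    report["km"] = {g: curve.to_dict() for g, curve in km.items()}
    report["median_survival"] = {g: km[g].median_survival() for g in present}
    report["logrank"] = logrank_test(survival.subset(mask), three[mask]).to_dict()

    # Cox models of the subgroup label, reference TM_L+TME_H
    dummies = pd.DataFrame(
        {f"group[{g}]": (three == g).astype(float) for g in THREE_LEVELS[1:]
         if g in present},
        index=pd.Index(labels.sample_ids))
    if dummies.shape[1] >= 1:
        report["cox_univariate"] = fit_cox(dummies, survival).to_dict()
        if covariates is not None:
            cov = covariates.reindex(dummies.index)
            if cov.isna().any().any():
                raise ValidationError("covariates missing for some labelled samples")
            report["cox_multivariate"] = fit_cox(dummies.join(cov), survival).to_dict()

    if scores:
        tm, tme = scores.get("TM"), scores.get("TME")
        named = {}
        if tm is not None and tme is not None:
            named["risk"] = combined_risk_score(tm, tme)
        if tm is not None:
            named["tm"] = tm.score
        if tme is not None:
            named["tme"] = -np.asarray(tme.score)  # high TME = good; flip to risk
        auc: dict = {name: {} for name in named}
        for h in horizons:
            t_h = h * days_per_year
            for name, vec in named.items():
                try:
                    auc[name][f"{h:g}y"] = td_roc(vec, survival, t_h).auc
                except ValidationError as exc:
                    logger.warning("AUC at %gy for %s skipped: %s", h, name, exc)
                    auc[name][f"{h:g}y"] = None
        report["auc"] = auc
        report["horizons_years"] = list(horizons)
        report["days_per_year"] = days_per_year
    return report


# ---------------------------------------------------------------------------
# the composite estimator
# ---------------------------------------------------------------------------

class TMTMEClassifier(BaseEstimator):
    """End-to-end TM-TME classifier construction as a sklearn estimator.

    ``fit(X, y)`` takes a samples x features DataFrame whose columns include
    candidate genes (``gene_cols``) and immune-cell fractions
    (``cell_cols``) plus a right-censored outcome ``y`` (SurvivalData or a
    scikit-survival structured array), and learns:

    * ``screened_genes_`` — genes passing the univariate Cox screen;
    * ``selected_genes_`` — the lasso-Cox signature;
    * ``gene_weights_`` / ``cell_weights_`` — bootstrap-stabilized Coef/SD
      weights for the TM and TME scores;
    * ``tm_median_`` / ``tme_median_`` — the *training* cohort medians
      (reported for reference only).

    ``predict(X)`` recomputes TM/TME scores with the learned weights and
    splits at the medians of the cohort being predicted, per the transfer
    protocol; training medians are never applied to another cohort.

    The immune-cell signature either is given explicitly (``cells``, the
    usual case when the favorable cell types are known) or is discovered by
    a univariate screen keeping favorable (negative-coefficient) cells at
    ``cell_alpha``, falling back to all cell columns with a warning.
    """

    def __init__(self, gene_cols=None, cell_cols=None, cells=None,
                 screen_alpha: float = 0.05, cell_alpha: float = 0.05,
                 lambda_rule: str = "min", cv_folds: int = 5,
                 B: int = 1000, ties: str = "efron",
                 tie_policy: str = "low", allow_missing: bool = False,
                 seed: int = 0):
        self.gene_cols = gene_cols
        self.cell_cols = cell_cols
        self.cells = cells
        self.screen_alpha = screen_alpha
        self.cell_alpha = cell_alpha
        self.lambda_rule = lambda_rule
        self.cv_folds = cv_folds
        self.B = B
        self.ties = ties
        self.tie_policy = tie_policy
        self.allow_missing = allow_missing
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _split_columns(self, X: pd.DataFrame):
        if self.cell_cols is None:
            raise ValueError("cell_cols must name the immune-fraction columns")
        cell_cols = [c for c in self.cell_cols]
        gene_cols = ([c for c in X.columns if c not in set(cell_cols)]
                     if self.gene_cols is None else list(self.gene_cols))
        missing = [c for c in gene_cols + cell_cols if c not in X.columns]
        if missing:
            raise KeyError(f"columns absent from the input matrix: {missing[:10]}")
        return gene_cols, cell_cols

    # -- estimator API -----------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named gene and cell columns")
        gene_cols, cell_cols = self._split_columns(X)
        surv = as_survival(y, sample_ids=X.index.to_numpy())

        screen = UnivariateCoxScreen(alpha=self.screen_alpha, ties=self.ties)
        screen.fit(X[gene_cols], surv)
        self.screen_ = screen
        self.screened_genes_ = screen.screened_genes_
        if len(self.screened_genes_) < 2:
            raise RuntimeError(
                f"only {len(self.screened_genes_)} gene(s) passed the univariate "
                f"screen at alpha={self.screen_alpha}; cannot build a signature")

        selector = LassoCoxSelector(lambda_rule=self.lambda_rule,
                                    cv_folds=self.cv_folds, seed=self.seed)
        selector.fit(X[self.screened_genes_], surv)
        self.selector_ = selector
        self.selected_genes_ = selector.selected_genes_
        if not self.selected_genes_:
            raise RuntimeError("lasso selection returned an empty gene signature")

        if self.cells is not None:
            cell_sig = [str(c) for c in self.cells]
            absent = [c for c in cell_sig if c not in cell_cols]
            if absent:
                raise KeyError(f"designated signature cells absent: {absent}")
        else:
            cell_screen = UnivariateCoxScreen(alpha=self.cell_alpha,
                                              ties=self.ties, sign="negative")
            cell_screen.fit(X[cell_cols], surv)
            cell_sig = cell_screen.screened_genes_
            if not cell_sig:
                logger.warning("no favorable cell passed the screen at alpha=%g; "
                               "using all %d cell types", self.cell_alpha,
                               len(cell_cols))
                cell_sig = list(cell_cols)
        self.selected_cells_ = cell_sig

        self.gene_weighter_ = BootstrapCoxWeighter(
            kind="TM", B=self.B, seed=self.seed, ties=self.ties,
            allow_missing=self.allow_missing)
        self.gene_weighter_.fit(X[self.selected_genes_], surv)
        self.gene_weights_ = self.gene_weighter_.weights_

        self.cell_weighter_ = BootstrapCoxWeighter(
            kind="TME", B=self.B, seed=self.seed + 1, ties=self.ties,
            allow_missing=self.allow_missing)
        self.cell_weighter_.fit(X[cell_sig], surv)
        self.cell_weights_ = self.cell_weighter_.weights_

        tm = self.tm_score(X)
        tme = self.tme_score(X)
        _, self.tm_median_ = median_split(tm, self.tie_policy)
        _, self.tme_median_ = median_split(tme, self.tie_policy)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def tm_score(self, X: pd.DataFrame) -> ScoreVector:
        return tm_score(X, self.gene_weights_, allow_missing=self.allow_missing)

    def tme_score(self, X: pd.DataFrame) -> ScoreVector:
        return tme_score(X, self.cell_weights_, allow_missing=self.allow_missing)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """TM and TME scores for each sample of ``X``."""
        tm = self.tm_score(X)
        tme = self.tme_score(X)
        return pd.DataFrame({"tm_score": tm.score, "tme_score": tme.score},
                            index=pd.Index(tm.sample_ids, name="sample_id"))

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous risk (higher = worse): z(TM score) - z(TME score)."""
        return combined_risk_score(self.tm_score(X), self.tme_score(X))

    def predict_subgroups(self, X: pd.DataFrame) -> SubgroupLabels:
        """Label ``X`` with the learned weights and ``X``'s own medians."""
        return build_subgroups(self.tm_score(X), self.tme_score(X),
                               tie_policy=self.tie_policy)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Three-level subgroup label per sample of ``X``."""
        return self.predict_subgroups(X).three_level

    def evaluate(self, X: pd.DataFrame, y, horizons=(3.0, 5.0, 7.0),
                 covariates: pd.DataFrame | None = None,
                 days_per_year: float = DAYS_PER_YEAR) -> dict:
        surv = as_survival(y, sample_ids=X.index.to_numpy())
        labels = self.predict_subgroups(X)
        scores = {"TM": self.tm_score(X), "TME": self.tme_score(X)}
        return evaluate_classifier(labels, surv, scores=scores, horizons=horizons,
                                   covariates=covariates, days_per_year=days_per_year)
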