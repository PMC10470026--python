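"""Candidate-gene reduction: univariate Cox screen and lasso-Cox selection.

Both stages are scikit-learn feature selectors operating on a samples x
genes DataFrame with a right-censored outcome, so they compose with
sklearn pipelines.  The penalized stage fits an L1 Cox path (glmnet-style
coordinate descent via scikit-survival) and picks the penalty by K-fold
cross-validated partial-likelihood deviance (Verweij-van Houwelingen),
with an optional bootstrap stability-selection mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sksurv.linear_model import CoxnetSurvivalAnalysis

from ._cox import CoxEngine
from .survival import SurvivalData, as_survival, univariate_cox_screen

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of the screen + penalized-selection cascade."""

    screened_genes: list
    selected_genes: list
    lambda_used: float
    fold_seeds: list

    def to_dict(self) -> dict:
        return {"screened_genes": list(self.screened_genes),
                "selected_genes": list(self.selected_genes),
                "lambda_used": self.lambda_used,
                "fold_seeds": list(self.fold_seeds)}


def _feature_names(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X.columns, dtype=object)
    return np.array([f"x{i}" for i in range(np.asarray(X).shape[1])], dtype=object)


class UnivariateCoxScreen(SelectorMixin, BaseEstimator):
    """Keep features whose univariate Cox Wald p-value falls below ``alpha``.

    Fitted attributes: ``results_`` (DataFrame of passing features sorted by
    p), ``support_`` (boolean mask over input columns), ``screened_genes_``.
    """

    def __init__(self, alpha: float = 0.05, ties: str = "efron",
                 sign: str | None = None):
        self.alpha = alpha
        self.ties = ties
        #: optionally keep only one coefficient sign: "negative" mirrors the
        #: favorable-cell convention, "positive" risk features, None both.
        self.sign = sign

    def fit(self, X, y):
        names = _feature_names(X)
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X), columns=names)
        surv = as_survival(y, sample_ids=getattr(Xdf, "index", None))
        res = univariate_cox_screen(Xdf, surv, alpha=self.alpha, ties=self.ties)
        if self.sign == "negative":
            res = res[res["coefficient"] < 0].reset_index(drop=True)
        elif self.sign == "positive":
            res = res[res["coefficient"] > 0].reset_index(drop=True)
        self.results_ = res
        self.feature_names_in_ = names
        self.n_features_in_ = names.shape[0]
        self.support_ = np.isin(names, res["gene"].to_numpy())
        self.screened_genes_ = [str(g) for g in names[self.support_]]
        return self

    def _get_support_mask(self):
        return self.support_


class LassoCoxSelector(SelectorMixin, BaseEstimator):
    """L1-penalized Cox selection with cross-validated penalty choice.

    The lasso path is fitted by cyclical coordinate descent on the partial
    likelihood (scikit-survival's Coxnet); the penalty is picked by K-fold
    cross-validated deviance ``-2 [ll_all(beta_fold) - ll_train(beta_fold)]``
    under ``lambda_rule`` ("min" or "1se").  ``mode="stability"`` instead
    keeps features selected in at least ``stability_threshold`` of
    ``n_bootstrap`` resamples at the cross-validated penalty.
    """

    def __init__(self, lambda_rule: str = "min", cv_folds: int = 5,
                 n_alphas: int = 50, alpha_min_ratio: float = 0.01,
                 alphas=None, mode: str = "cv", n_bootstrap: int = 100,
                 stability_threshold: float = 0.6, seed: int = 0):
        self.lambda_rule = lambda_rule
        self.cv_folds = cv_folds
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.alphas = alphas
        self.mode = mode
        self.n_bootstrap = n_bootstrap
        self.stability_threshold = stability_threshold
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _path(self, X: np.ndarray, y: np.ndarray, alphas=None) -> CoxnetSurvivalAnalysis:
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=self.n_alphas,
            alpha_min_ratio=self.alpha_min_ratio,
            alphas=alphas, fit_baseline_model=False, max_iter=100000)
        model.fit(X, y)
        return model

    def _cv_deviance(self, X: np.ndarray, surv: SurvivalData, alphas: np.ndarray):
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        # folds are drawn over the id-sorted sample order, so fold membership
        # (and hence the selected set) is invariant to input row order
        canon = np.argsort(np.asarray(surv.sample_ids, dtype=str), kind="stable")
        perm = canon[rng.permutation(n)]
        folds = np.array_split(perm, self.cv_folds)
        eng_all = CoxEngine(surv.time, surv.event)
        dev = np.zeros((self.cv_folds, alphas.shape[0]))
        y = surv.to_structured()
        for kf, test_idx in enumerate(folds):
            train = np.setdiff1d(perm, test_idx)
            if surv.event[train].sum() < 1:
                raise ValueError("a cross-validation training fold has no events; "
                                 "reduce cv_folds")
            eng_tr = CoxEngine(surv.time[train], surv.event[train])
            model = self._path(X[train], y[train], alphas=list(alphas))
            coefs = model.coef_  # p x n_alphas
            fitted = np.asarray(model.alphas_)
            for ia, a in enumerate(alphas):
                ja = int(np.argmin(np.abs(fitted - a)))
                beta = coefs[:, ja]
                ll_all = eng_all.loglik(X, beta)
                ll_train = eng_tr.loglik(X[train], beta)
                dev[kf, ia] = -2.0 * (ll_all - ll_train)
        return dev

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        names = _feature_names(X)
        Xarr = np.asarray(X, dtype=float)
        if Xarr.shape[1] < 2:
            raise ValueError("lasso selection requires at least 2 screened genes")
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be at least 3")
        surv = as_survival(y, sample_ids=getattr(X, "index", None))
        if surv.n_events < self.cv_folds:
            raise ValueError(f"fewer events ({surv.n_events}) than folds "
                             f"({self.cv_folds}); cross-validation undefined")
        ystruct = surv.to_structured()
        path = self._path(Xarr, ystruct, alphas=self.alphas)
        alphas = np.asarray(path.alphas_)
        self.alphas_ = alphas
        self.coef_path_ = path.coef_

        dev = self._cv_deviance(Xarr, surv, alphas)
        mean_dev = dev.sum(axis=0)
        se_dev = dev.std(axis=0, ddof=1) * np.sqrt(self.cv_folds)
        self.cv_deviance_ = mean_dev
        if self.lambda_rule == "min":
            best = int(np.argmin(mean_dev))
        elif self.lambda_rule == "1se":
            imin = int(np.argmin(mean_dev))
            within = mean_dev <= mean_dev[imin] + se_dev[imin]
            best = int(np.flatnonzero(within)[0])  # path is descending in alpha
        else:
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        self.lambda_ = float(alphas[best])
        self.coef_ = path.coef_[:, best]

        if self.mode == "cv":
            support = self.coef_ != 0
        elif self.mode == "stability":
            support = self._stability_support(Xarr, surv, names)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not support.any():
            logger.warning("no gene entered the lasso path at the chosen penalty; "
                           "selection is empty")
        self.support_ = support
        self.feature_names_in_ = names
        self.n_features_in_ = names.shape[0]
        self.selected_genes_ = [str(g) for g in names[support]]
        return self

    def _stability_support(self, X: np.ndarray, surv: SurvivalData, names):
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        counts = np.zeros(X.shape[1])
        done = 0
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, n, n)
            if surv.event[idx].sum() < 2 or (np.ptp(X[idx], axis=0) == 0).any():
                continue
            try:
                model = self._path(X[idx], surv.to_structured()[idx],
                                   alphas=[self.lambda_])
            except Exception:  # degenerate resample
                continue
            counts += model.coef_[:, 0] != 0
            done += 1
        if done == 0:
            raise RuntimeError("no bootstrap resample produced a valid lasso fit")
        self.stability_frequencies_ = counts / done
        return self.stability_frequencies_ >= self.stability_threshold

    def _get_support_mask(self):
        return self.support_

    def result(self) -> SelectionResult:
        return SelectionResult(
            screened_genes=[str(g) for g in self.feature_names_in_],
            selected_genes=self.selected_genes_,
            lambda_used=self.lambda_,
            fold_seeds=[self.seed])


def lasso_cox_select(expression: pd.DataFrame, survival: SurvivalData,
                     lambda_rule: str = "min", cv_folds: int = 5,
                     seed: int = 0, **kwargs) -> SelectionResult:
    """Select signature genes from the screened expression matrix.

    Thin wrapper over :class:`LassoCoxSelector`; see its docstring for the
    penalty path and cross-validation details.
    """
    sel = LassoCoxSelector(lambda_rule=lambda_rule, cv_folds=cv_folds,
                           seed=seed, **kwargs)
    sel.fit(expression, survival)
    return sel.result()
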