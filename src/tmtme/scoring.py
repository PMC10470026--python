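"""Bootstrap-stabilized Cox weighting and the TM / TME score formulas.

The weight of each signature feature is Coef / SD: the multivariate Cox
coefficient of the feature on the full cohort, divided by the standard
deviation of that coefficient across bootstrap refits.  Scores are then
plain weighted sums:

    TM score(sample)  =  sum_i  (Coef_i / SD_i) * expression[sample, gene_i]
    TME score(sample) = -sum_j  (Coef_j / SD_j) * fraction[sample, cell_j]

The leading minus of the TME score lives in :func:`tme_score`, never in the
stored weights, so a ``BootstrapWeights`` object always equals the plain
Coef/SD ratio regardless of which score it feeds.  With favorable (negative
coefficient) cells, the minus makes a higher TME score mean a better
prognosis, while a higher TM score means a worse one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._cox import CoxEngine
from .survival import SurvivalData, as_survival, fit_cox

logger = logging.getLogger(__name__)

MIN_CONVERGED_FRACTION = 0.9


@dataclass
class BootstrapWeights:
    """Per-feature Coef, bootstrap SD, and weight = Coef / SD."""

    feature_names: list
    coef: np.ndarray
    sd: np.ndarray
    weight: np.ndarray
    n_resamples: int
    n_converged: int
    seed: int
    sign_convention: str = "tm"  # which score formula the weights feed

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (len(self.feature_names) == self.coef.shape[0]
                == self.sd.shape[0] == self.weight.shape[0]):
            raise ValueError("feature_names, coef, sd and weight lengths differ")
        if (self.sd <= 0).any():
            raise ValueError("bootstrap SDs must be strictly positive")

    def to_dict(self) -> dict:
        return {"feature_names": list(map(str, self.feature_names)),
                "coef": self.coef.tolist(), "sd": self.sd.tolist(),
                "weight": self.weight.tolist(),
                "n_resamples": self.n_resamples, "n_converged": self.n_converged,
                "seed": self.seed, "sign_convention": self.sign_convention}

    @classmethod
    def from_dict(cls, d: dict) -> "BootstrapWeights":
        return cls(feature_names=list(d["feature_names"]),
                   coef=np.asarray(d["coef"]), sd=np.asarray(d["sd"]),
                   weight=np.asarray(d["weight"]), n_resamples=int(d["n_resamples"]),
                   n_converged=int(d["n_converged"]), seed=int(d["seed"]),
                   sign_convention=d.get("sign_convention", "tm"))


@dataclass
class ScoreVector:
    """One risk score per sample (kind 'TM' or 'TME')."""

    sample_ids: np.ndarray
    score: np.ndarray
    kind: str

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.score = np.asarray(self.score, dtype=float)
        if self.sample_ids.shape != self.score.shape:
            raise ValueError("sample_ids and score lengths differ")
        if not np.isfinite(self.score).all():
            raise ValueError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=pd.Index(self.sample_ids, name="sample_id"),
                         name=f"{self.kind.lower()}_score")


def bootstrap_cox_weights(features: pd.DataFrame, survival: SurvivalData,
                          B: int = 1000, seed: int = 0, ties: str = "efron",
                          mode: str = "bootstrap", subsample_fraction: float = 0.8,
                          coef_source: str = "full",
                          sign_convention: str = "tm") -> BootstrapWeights:
    """Estimate Coef / SD weights for one feature block (genes or cells).

    One multivariate Cox fit on the full cohort supplies Coef (or the
    bootstrap mean, with ``coef_source="bootstrap_mean"``); ``B`` resamples
    with replacement of size n (or subsamples without replacement at
    ``subsample_fraction``, with ``mode="subsample"``) are each refitted and
    the per-feature SD is taken across converged refits.  Resamples with no
    events, a constant feature, or a non-converged fit are dropped and
    counted; fewer than 90% usable refits is an error.
    """
    if B < 2:
        raise ValueError("B must be at least 2: a standard deviation over "
                         "bootstrap coefficients is undefined otherwise")
    if mode not in ("bootstrap", "subsample"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features))
    names = [str(c) for c in features.columns]
    full = fit_cox(features, survival, ties=ties)

    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    m = n if mode == "bootstrap" else max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    coefs = []
    for _ in range(B):
        idx = (rng.integers(0, n, n) if mode == "bootstrap"
               else rng.choice(n, size=m, replace=False))
        ev = survival.event[idx]
        Xi = X[idx]
        if ev.sum() < 1 or (np.ptp(Xi, axis=0) == 0).any():
            continue
        eng = CoxEngine(survival.time[idx], ev, ties=ties)
        res = eng.fit(Xi)
        if res.converged and np.isfinite(res.beta).all():
            coefs.append(res.beta)
    n_converged = len(coefs)
    if n_converged < MIN_CONVERGED_FRACTION * B:
        raise RuntimeError(
            f"only {n_converged}/{B} bootstrap refits converged; "
            f"weights would be unreliable")
    coefs = np.asarray(coefs)
    sd = coefs.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise RuntimeError("a bootstrap coefficient SD is zero; weights undefined")
    coef = full.coefficients if coef_source == "full" else coefs.mean(axis=0)
    return BootstrapWeights(feature_names=names, coef=coef, sd=sd,
                            weight=coef / sd, n_resamples=B, n_converged=n_converged,
                            seed=seed, sign_convention=sign_convention)


def _aligned_matrix(data: pd.DataFrame, weights: BootstrapWeights,
                    what: str, allow_missing: bool):
    names = list(weights.feature_names)
    missing = [f for f in names if f not in data.columns]
    if missing:
        if not allow_missing:
            raise KeyError(f"signature {what}(s) absent from the matrix: {missing}")
        logger.warning("dropping %d signature %s(s) absent from the matrix: %s",
                       len(missing), what, missing)
        keep = [f for f in names if f not in missing]
        idx = [names.index(f) for f in keep]
        return data[keep].to_numpy(dtype=float), weights.weight[idx]
    return data[names].to_numpy(dtype=float), weights.weight


def tm_score(expression: pd.DataFrame, weights: BootstrapWeights,
             allow_missing: bool = False) -> ScoreVector:
    """TM score: weighted sum of signature-gene expression (weight = Coef/SD)."""
    X, w = _aligned_matrix(expression, weights, "gene", allow_missing)
    return ScoreVector(sample_ids=np.asarray(expression.index, dtype=object),
                       score=X @ w, kind="TM")


def tme_score(fractions: pd.DataFrame, weights: BootstrapWeights,
              allow_missing: bool = False) -> ScoreVector:
    """TME score: *negated* weighted sum of signature-cell fractions."""
    F, w = _aligned_matrix(fractions, weights, "cell", allow_missing)
    return ScoreVector(sample_ids=np.asarray(fractions.index, dtype=object),
                       score=-(F @ w), kind="TME")


class BootstrapCoxWeighter(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper: fit learns Coef/SD weights, transform scores.

    ``kind="TM"`` emits the weighted sum; ``kind="TME"`` emits its negation
    per the TME score formula.
    """

    def __init__(self, kind: str = "TM", B: int = 1000, seed: int = 0,
                 ties: str = "efron", mode: str = "bootstrap",
                 subsample_fraction: float = 0.8, coef_source: str = "full",
                 allow_missing: bool = False):
        self.kind = kind
        self.B = B
        self.seed = seed
        self.ties = ties
        self.mode = mode
        self.subsample_fraction = subsample_fraction
        self.coef_source = coef_source
        self.allow_missing = allow_missing

    def fit(self, X, y):
        if self.kind not in ("TM", "TME"):
            raise ValueError("kind must be 'TM' or 'TME'")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        surv = as_survival(y, sample_ids=getattr(X, "index", None))
        self.weights_ = bootstrap_cox_weights(
            Xdf, surv, B=self.B, seed=self.seed, ties=self.ties, mode=self.mode,
            subsample_fraction=self.subsample_fraction,
            coef_source=self.coef_source,
            sign_convention=self.kind.lower())
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.n_features_in_ = Xdf.shape[1]
        return self

    def score_vector(self, X) -> ScoreVector:
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X), columns=self.feature_names_in_)
        fn = tm_score if self.kind == "TM" else tme_score
        return fn(Xdf, self.weights_, allow_missing=self.allow_missing)

    def transform(self, X) -> np.ndarray:
        return self.score_vector(X).score[:, None]
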