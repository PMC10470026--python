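"""Survival statistics underpinning the TM-TME pipeline.

Implements right-censored survival containers, Cox proportional-hazards
fitting (Efron tie correction by default), a vectorized univariate Cox
screen, the Kaplan-Meier product-limit estimator, the k-sample log-rank
test, and the IPCW cumulative/dynamic time-dependent ROC.

All estimators are asymptotic-standard: Wald p-values for Cox fits,
chi-square reference for the log-rank statistic, Kaplan-Meier estimate of
the censoring distribution for the ROC weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import (  # noqa: F401  (re-exported error types)
    CoxEngine,
    CoxError,
    NoEventsError,
    NonIdentifiableError,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


class ValidationError(ValueError):
    """An input table violates the pipeline's input contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalData:
    """Right-censored overall-survival outcome, one row per sample.

    `time` is follow-up in a single cohort-wide unit (days by convention);
    `event` is 1 when death was observed and 0 when follow-up was censored.
    """

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.sample_ids, dtype=object)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if not (ids.shape == time.shape == event.shape):
            raise ValidationError("sample_ids, time and event must have equal length")
        if pd.Index(ids).has_duplicates:
            dup = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup[:5]}")
        if np.isnan(time).any():
            raise ValidationError("missing survival times")
        if (time <= 0).any():
            bad = ids[time <= 0][:5].tolist()
            raise ValidationError(f"non-positive survival times for samples {bad}")
        ev = np.unique(event[~pd.isna(event)])
        if pd.isna(event).any() or not np.isin(ev, [0, 1]).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (death)")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_col: str = "sample_id",
                   time_col: str = "time", event_col: str = "event") -> "SurvivalData":
        for col in (id_col, time_col, event_col):
            if col not in df.columns:
                raise ValidationError(f"clinical table lacks required column {col!r}")
        return cls(df[id_col].to_numpy(), df[time_col].to_numpy(), df[event_col].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "time": self.time,
                             "event": self.event})

    def subset(self, mask_or_index) -> "SurvivalData":
        return SurvivalData(self.sample_ids[mask_or_index], self.time[mask_or_index],
                            self.event[mask_or_index])

    def reindex(self, sample_ids) -> "SurvivalData":
        pos = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (pos < 0).any():
            missing = np.asarray(sample_ids)[pos < 0][:5].tolist()
            raise ValidationError(f"samples absent from survival data: {missing}")
        return self.subset(pos)

    def to_structured(self) -> np.ndarray:
        """Structured (event, time) array as scikit-survival expects."""
        out = np.empty(len(self), dtype=[("event", "?"), ("time", "<f8")])
        out["event"] = self.event.astype(bool)
        out["time"] = self.time
        return out


def as_survival(y, sample_ids=None) -> SurvivalData:
    """Coerce a survival outcome to :class:`SurvivalData`.

    Accepts SurvivalData, a (event, time) structured array (scikit-survival
    convention), or a DataFrame with sample_id/time/event columns.
    """
    if isinstance(y, SurvivalData):
        return y
    if isinstance(y, pd.DataFrame):
        return SurvivalData.from_frame(y)
    arr = np.asarray(y)
    if arr.dtype.names and set(arr.dtype.names) >= {"event", "time"}:
        ids = np.arange(arr.shape[0]) if sample_ids is None else sample_ids
        return SurvivalData(np.asarray(ids, dtype=object), arr["time"],
                            arr["event"].astype(int))
    raise ValidationError("cannot interpret survival outcome; pass SurvivalData, a "
                          "structured (event, time) array, or a clinical DataFrame")


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (log hazard-ratio scale)."""

    covariates: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_events: int
    n_samples: int
    ties: str = "efron"

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def z(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def confidence_intervals(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.coefficients - q * self.standard_errors
        hi = self.coefficients + q * self.standard_errors
        return np.column_stack([lo, hi])

    def to_dict(self) -> dict:
        ci = self.confidence_intervals()
        return {
            "covariates": list(map(str, self.covariates)),
            "coef": self.coefficients.tolist(),
            "se": self.standard_errors.tolist(),
            "hr": self.hazard_ratios.tolist(),
            "hr_ci95_low": np.exp(ci[:, 0]).tolist(),
            "hr_ci95_high": np.exp(ci[:, 1]).tolist(),
            "p": self.p_values.tolist(),
            "log_partial_likelihood": self.log_partial_likelihood,
            "converged": bool(self.converged),
            "n_events": self.n_events,
            "n_samples": self.n_samples,
            "ties": self.ties,
        }


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events_at: np.ndarray
    label: str | None = None

    def evaluate(self, t: np.ndarray, left: bool = False) -> np.ndarray:
        """Step-function evaluation S(t); `left=True` gives the left limit S(t-)."""
        side = "left" if left else "right"
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float), side=side)
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def median_survival(self) -> float:
        """Smallest event time with S(t) <= 0.5, or +inf if never reached."""
        below = self.survival <= 0.5
        return float(self.event_times[below][0]) if below.any() else float("inf")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "time": self.event_times.tolist(),
            "survival": self.survival.tolist(),
            "at_risk": self.at_risk.tolist(),
            "n_events": self.n_events_at.tolist(),
            "median_survival": self.median_survival() if np.isfinite(self.median_survival()) else None,
        }


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


@dataclass
class TimeDependentROC:
    """IPCW cumulative-cases / dynamic-controls ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {"horizon": self.horizon, "auc": self.auc,
                "n_cases": self.n_cases, "n_controls": self.n_controls}


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------

def _check_covariates(X: np.ndarray, names) -> None:
    const = np.ptp(X, axis=0) == 0
    if const.any():
        bad = [str(names[i]) for i in np.flatnonzero(const)]
        raise NonIdentifiableError(
            f"covariate(s) constant across samples, coefficient not identifiable: {bad}")


def fit_cox(covariates, survival: SurvivalData, ties: str = "efron",
            engine: CoxEngine | None = None) -> CoxFit:
    """Fit a multivariate Cox proportional-hazards model.

    Maximizes the tie-corrected partial likelihood by damped Newton
    iteration; standard errors come from the inverse observed information.
    `covariates` may be a DataFrame (column names kept) or a 2-D array.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if X.shape[1] < 1:
        raise CoxError("at least one covariate is required")
    if X.shape[0] != len(survival):
        raise CoxError("covariate rows do not match the survival table")
    if np.isnan(X).any():
        raise ValidationError("missing values in covariates")
    _check_covariates(X, names)
    eng = engine if engine is not None else CoxEngine(survival.time, survival.event, ties=ties)
    res = eng.fit(X)
    if not res.converged:
        logger.warning("Cox fit did not converge in %d iterations (max |grad| = %.3g)",
                       res.n_iter, res.grad_norm)
    return CoxFit(covariates=names, coefficients=res.beta, standard_errors=res.se,
                  log_partial_likelihood=res.loglik, converged=res.converged,
                  n_events=survival.n_events, n_samples=len(survival), ties=eng.ties)


def univariate_cox_screen(expression: pd.DataFrame, survival: SurvivalData,
                          alpha: float = 0.05, ties: str = "efron") -> pd.DataFrame:
    """Single-gene Cox screen: one univariate fit per expression column.

    Returns the genes with Wald p < alpha sorted by p, as a DataFrame with
    columns gene/coefficient/se/p.  Zero-variance genes are skipped with a
    warning; non-converged fits are likewise excluded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly inside (0, 1)")
    if expression.shape[1] == 0:
        raise ValueError("empty gene set supplied to the univariate screen")
    X = expression.to_numpy(dtype=float)
    genes = np.asarray(expression.columns, dtype=object)
    keep = np.ptp(X, axis=0) > 0
    if not keep.all():
        dropped = genes[~keep].tolist()
        logger.warning("skipping %d zero-variance gene(s) in screen: %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    X = X[:, keep]
    genes = genes[keep]
    if X.shape[1] == 0:
        raise ValueError("all genes have zero variance")
    eng = CoxEngine(survival.time, survival.event, ties=ties)
    beta, se, converged = eng.fit_univariate_batch(X)
    if not converged.all():
        logger.warning("%d gene fit(s) did not converge and were excluded",
                       int((~converged).sum()))
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame({"gene": genes, "coefficient": beta, "se": se, "p": p})
    out = out[converged & (out["p"] < alpha)].sort_values("p", kind="stable")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def _km_single(time: np.ndarray, event: np.ndarray, label=None) -> KMCurve:
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq, start = np.unique(t, return_index=True)
    d = np.bincount(np.searchsorted(uniq, t), weights=e.astype(float))
    n_at_risk = t.shape[0] - start
    has_event = d > 0
    et = uniq[has_event]
    dd = d[has_event]
    nn = n_at_risk[has_event]
    surv = np.cumprod(1.0 - dd / nn)
    return KMCurve(event_times=et, survival=surv, at_risk=nn.astype(int),
                   n_events_at=dd.astype(int), label=label)


def km_estimate(survival: SurvivalData, labels=None):
    """Kaplan-Meier product-limit estimate, optionally per group.

    Without `labels` returns a single :class:`KMCurve`; with `labels` (one
    per sample) returns a dict of curves keyed by group label.
    """
    if labels is None:
        return _km_single(survival.time, survival.event)
    labels = np.asarray(labels)
    if labels.shape[0] != len(survival):
        raise ValidationError("labels length does not match survival data")
    out = {}
    for g in pd.unique(labels):
        mask = labels == g
        if not mask.any():
            raise ValidationError(f"empty group {g!r}")
        out[g] = _km_single(survival.time[mask], survival.event[mask], label=str(g))
    return out


def logrank_test(survival: SurvivalData, labels) -> LogRankResult:
    """k-sample log-rank test (chi-square with k-1 degrees of freedom)."""
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    k = groups.shape[0]
    if k < 2:
        raise ValidationError("log-rank test requires at least two groups")
    if survival.n_events == 0:
        raise NoEventsError("log-rank test requires at least one event")
    time, event = survival.time, survival.event
    event_times = np.unique(time[event == 1])
    gmat = np.column_stack([labels == g for g in groups]).astype(float)  # n x k
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        dying = (time == t) & (event == 1)
        n_t = at_risk.sum()
        d_t = dying.sum()
        n_gt = gmat[at_risk].sum(axis=0)
        O += gmat[dying].sum(axis=0)
        E += d_t * n_gt / n_t
        if n_t > 1:
            frac = n_gt / n_t
            V += d_t * (n_t - d_t) / (n_t - 1) * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

def td_roc(scores, survival: SurvivalData, horizon: float) -> TimeDependentROC:
    """Time-dependent ROC at `horizon` for a higher-is-riskier score.

    Cumulative-cases / dynamic-controls definition: cases die by the
    horizon, controls are still at risk past it.  Inverse probability of
    censoring weights come from the Kaplan-Meier estimate of the censoring
    distribution; the AUC is the trapezoidal area over the threshold sweep,
    which equals the censoring-weighted Mann-Whitney statistic (ties get
    half credit).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(survival):
        raise ValidationError("scores length does not match survival data")
    time, event = survival.time, survival.event
    if horizon <= 0 or horizon >= time.max():
        raise ValidationError("horizon must lie within the observed follow-up")
    case = (time <= horizon) & (event == 1)
    ctrl = time > horizon
    if not case.any():
        raise ValidationError("no cases (events) observed by the horizon")
    if not ctrl.any():
        raise ValidationError("no controls remain at risk past the horizon")
    cens_km = _km_single(time, 1 - event)  # censoring distribution G
    g_case = cens_km.evaluate(time[case], left=True)
    g_ctrl = float(cens_km.evaluate(np.array([horizon]))[0])
    if g_ctrl <= 0 or (g_case <= 0).any():
        raise ValidationError("censoring survival reaches zero before the horizon; "
                              "IPCW weights undefined")
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_ctrl)
    s_case, s_ctrl = scores[case], scores[ctrl]

    thresholds = np.unique(np.concatenate([s_case, s_ctrl]))[::-1]
    # weighted fraction of cases / controls at or above each threshold
    def cum_weight(s, w):
        order = np.argsort(-s, kind="stable")
        s_sorted, w_sorted = s[order], w[order]
        cw = np.cumsum(w_sorted)
        idx = np.searchsorted(-s_sorted, -thresholds, side="right")
        return np.concatenate(([0.0], cw))[idx]

    tpr = cum_weight(s_case, w_case) / w_case.sum()
    fpr = cum_weight(s_ctrl, w_ctrl) / w_ctrl.sum()
    tpr = np.concatenate(([0.0], tpr))
    fpr = np.concatenate(([0.0], fpr))
    auc = float(np.trapezoid(tpr, fpr))
    return TimeDependentROC(horizon=float(horizon), thresholds=thresholds,
                            sensitivities=tpr[1:], specificities=1.0 - fpr[1:],
                            auc=auc, n_cases=int(case.sum()), n_controls=int(ctrl.sum()))
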