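"""Damped-Newton solver for the Cox proportional-hazards partial likelihood.

This is the numerical core shared by the model fits, the univariate gene
screen and the bootstrap weighting.  It maximizes the Efron- (default) or
Breslow-corrected partial likelihood.  Risk-set sums are computed with
reverse cumulative sums over time-sorted samples, and the Efron tie
correction is applied through a flattened (event-time, within-tie-index)
expansion so no Python loop runs over event times.

Conventions: `time` strictly positive, `event` in {0, 1}; censored samples
observed at an event time are counted in the risk set at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_ITER = 100
GRAD_TOL = 1e-8


class CoxError(ValueError):
    """Invalid input to a Cox partial-likelihood fit."""


class NonIdentifiableError(CoxError):
    """A covariate is constant across samples, so its coefficient is not identifiable."""


class NoEventsError(CoxError):
    """All observations are censored; the partial likelihood is empty."""


@dataclass
class NewtonResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    grad_norm: float
    converged: bool
    n_iter: int
    information: np.ndarray


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class CoxEngine:
    """Precomputed risk-set structure for one (time, event) outcome.

    Building the engine once and fitting many covariate matrices against it
    (as the gene screen and the bootstrap do) avoids re-sorting per fit.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, ties: str = "efron"):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}; use 'efron' or 'breslow'")
        if event.sum() < 1:
            raise NoEventsError("no events observed; the partial likelihood is empty")
        self.ties = ties
        self.n = time.shape[0]
        order = np.argsort(time, kind="stable")
        self.order = order
        t = time[order]
        e = event[order].astype(float)
        self.sorted_event = e
        uniq, start = np.unique(t, return_index=True)
        gid = np.searchsorted(uniq, t)
        # deaths per unique time
        d = np.bincount(gid, weights=e, minlength=uniq.shape[0])
        ev_groups = np.flatnonzero(d > 0)
        self.event_group_start = start[ev_groups]  # risk set = sorted[start:]
        self.d = d[ev_groups]
        # map each event sample (sorted order) to its position among event groups
        self.event_rows = np.flatnonzero(e == 1)
        self.event_gid = np.searchsorted(ev_groups, gid[self.event_rows])
        self.n_event_groups = ev_groups.shape[0]
        # Efron expansion: one row per (event group g, within-tie index l)
        d_int = self.d.astype(int)
        self.rep = np.repeat(np.arange(self.n_event_groups), d_int)
        offs = np.concatenate(([0], np.cumsum(d_int)))[:-1]
        l = np.arange(d_int.sum()) - np.repeat(offs, d_int)
        if ties == "efron":
            self.frac = l / np.repeat(self.d, d_int)
        else:
            self.frac = np.zeros(l.shape[0])

    # ---- multivariate fit -------------------------------------------------

    def loglik_grad_info(self, Xs: np.ndarray, beta: np.ndarray, want_info: bool = True):
        """Partial log-likelihood, gradient and observed information at `beta`.

        `Xs` must already be in the engine's sorted sample order.
        """
        n, k = Xs.shape
        eta = Xs @ beta
        c = eta.max()
        w = np.exp(eta - c)
        wx = w[:, None] * Xs
        S_R = _rev_cumsum(w)[self.event_group_start]
        Sx_R = _rev_cumsum(wx)[self.event_group_start]
        ev = self.event_rows
        S_D = np.zeros(self.n_event_groups)
        np.add.at(S_D, self.event_gid, w[ev])
        Sx_D = np.zeros((self.n_event_groups, k))
        np.add.at(Sx_D, self.event_gid, wx[ev])

        f = self.frac[:, None]
        phi = S_R[self.rep] - self.frac * S_D[self.rep]
        mu = (Sx_R[self.rep] - f * Sx_D[self.rep]) / phi[:, None]
        ll = eta[ev].sum() - np.log(phi).sum() - phi.shape[0] * c
        grad = Xs[ev].sum(axis=0) - mu.sum(axis=0)
        if not want_info:
            return ll, grad, None
        wxx = wx[:, :, None] * Xs[:, None, :]
        Sxx_R = _rev_cumsum(wxx)[self.event_group_start]
        Sxx_D = np.zeros((self.n_event_groups, k, k))
        np.add.at(Sxx_D, self.event_gid, wxx[ev])
        term = (Sxx_R[self.rep] - f[:, :, None] * Sxx_D[self.rep]) / phi[:, None, None]
        info = term.sum(axis=0) - mu.T @ mu
        return ll, grad, info

    def fit(self, X: np.ndarray, beta0: np.ndarray | None = None,
            max_iter: int = MAX_ITER, tol: float = GRAD_TOL) -> NewtonResult:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != self.n:
            raise CoxError("covariate matrix shape does not match the outcome")
        k = X.shape[1]
        Xs = X[self.order]
        beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        ll, grad, info = self.loglik_grad_info(Xs, beta)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step-halving on partial-likelihood decrease
            alpha = 1.0
            for _ in range(30):
                beta_new = beta + alpha * step
                ll_new, grad_new, info_new = self.loglik_grad_info(Xs, beta_new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                alpha /= 2.0
            else:
                break
            beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        else:
            it = max_iter
        if not converged and np.max(np.abs(grad)) < tol:
            converged = True
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        return NewtonResult(beta=beta, se=se, loglik=float(ll),
                            grad_norm=float(np.max(np.abs(grad))),
                            converged=converged, n_iter=it, information=info)

    def loglik(self, X: np.ndarray, beta: np.ndarray) -> float:
        Xs = np.asarray(X, dtype=float)[self.order]
        ll, _, _ = self.loglik_grad_info(Xs, np.asarray(beta, dtype=float), want_info=False)
        return float(ll)

    # ---- vectorized single-covariate fits --------------------------------

    def fit_univariate_batch(self, X: np.ndarray, max_iter: int = MAX_ITER,
                             tol: float = GRAD_TOL, max_step: float = 1.0):
        """Fit one single-covariate Cox model per column of `X`, all at once.

        Newton iterations run in parallel across columns with per-column
        step capping (|delta| <= max_step) in place of step-halving; the
        1-D partial likelihood is concave so capped Newton is safe.

        Returns (beta, se, converged), each of shape (n_columns,).
        """
        X = np.asarray(X, dtype=float)
        Xs = X[self.order]
        n, G = Xs.shape
        beta = np.zeros(G)
        ev = self.event_rows
        x_ev_sum = Xs[ev].sum(axis=0)
        active = np.ones(G, dtype=bool)
        info = np.full(G, np.nan)
        for _ in range(max_iter):
            if not active.any():
                break
            eta = Xs[:, active] * beta[active]
            c = eta.max(axis=0)
            W = np.exp(eta - c)
            WX = W * Xs[:, active]
            WXX = WX * Xs[:, active]
            S_R = _rev_cumsum(W)[self.event_group_start]
            Sx_R = _rev_cumsum(WX)[self.event_group_start]
            Sxx_R = _rev_cumsum(WXX)[self.event_group_start]
            S_D = np.zeros((self.n_event_groups, active.sum()))
            Sx_D = np.zeros_like(S_D)
            Sxx_D = np.zeros_like(S_D)
            np.add.at(S_D, self.event_gid, W[ev])
            np.add.at(Sx_D, self.event_gid, WX[ev])
            np.add.at(Sxx_D, self.event_gid, WXX[ev])
            f = self.frac[:, None]
            phi = S_R[self.rep] - f * S_D[self.rep]
            mu = (Sx_R[self.rep] - f * Sx_D[self.rep]) / phi
            g = x_ev_sum[active] - mu.sum(axis=0)
            h = ((Sxx_R[self.rep] - f * Sxx_D[self.rep]) / phi - mu ** 2).sum(axis=0)
            info_act = info[active]
            info_act[:] = h
            info[active] = info_act
            done = np.abs(g) < tol
            step = np.clip(g / np.maximum(h, 1e-300), -max_step, max_step)
            idx = np.flatnonzero(active)
            beta[idx[~done]] += step[~done]
            active[idx[done]] = False
        converged = ~active
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
        return beta, se, converged
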