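"""Independent brute-force oracles used to validate the survival statistics.

Everything here is written as plain loops over risk sets, deliberately
sharing no code with the package internals.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def efron_loglik_1d(beta, x, time, event):
    """Exact single-covariate Efron partial log-likelihood by direct loops."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = np.flatnonzero((time == t) & (event == 1))
        risk = np.flatnonzero(time >= t)
        d = len(deaths)
        s_risk = np.exp(beta * x[risk]).sum()
        s_death = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for el in range(d):
            ll -= np.log(s_risk - (el / d) * s_death)
    return ll


def brute_cox_1d(x, time, event, lo=-10.0, hi=10.0):
    """Golden-section/Brent maximizer of the exact 1-D partial likelihood."""
    res = minimize_scalar(lambda b: -efron_loglik_1d(b, x, time, event),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def pairwise_auc(scores_case, scores_ctrl):
    """Mann-Whitney AUC by explicit pair counting (ties get half credit)."""
    num = 0.0
    for si in scores_case:
        for sj in scores_ctrl:
            if si > sj:
                num += 1.0
            elif si == sj:
                num += 0.5
    return num / (len(scores_case) * len(scores_ctrl))


def logrank_2group(time, event, group):
    """Two-group log-rank chi-square by the direct O-E / V table."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dying = (time == t) & (event == 1)
        n = at_risk.sum()
        d = dying.sum()
        n1 = (at_risk & (group == group[0])).sum()
        o1 = (dying & (group == group[0])).sum()
        e1 = d * n1 / n
        o_minus_e += o1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def km_by_hand(time, event):
    """Product-limit estimate via an explicit loop; returns (times, S)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
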