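"""Bootstrap Coef/SD weights and the TM / TME score formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmtme.scoring import (
    BootstrapCoxWeighter,
    BootstrapWeights,
    bootstrap_cox_weights,
    tm_score,
    tme_score,
)
from tmtme.simulate import SyntheticCohortConfig, generate_cohort
from tmtme.survival import SurvivalData


def _weights(names, w):
    w = np.asarray(w, float)
    sd = np.ones_like(w)
    return BootstrapWeights(feature_names=list(names), coef=w, sd=sd, weight=w,
                            n_resamples=2, n_converged=2, seed=0)


# ---------------------------------------------------------------------------
# score formulas
# ---------------------------------------------------------------------------

def test_tm_score_direct_arithmetic():
    expr = pd.DataFrame([[1.5, 2.0]], columns=["g1", "g2"], index=["s1"])
    sv = tm_score(expr, _weights(["g1", "g2"], [2.0, -1.0]))
    assert sv.score[0] == pytest.approx(1.0, abs=1e-12)
    zeros = tm_score(expr * 0.0, _weights(["g1", "g2"], [2.0, -1.0]))
    assert zeros.score[0] == 0.0


def test_tme_score_applies_leading_minus():
    frac = pd.DataFrame([[0.2]], columns=["c1"], index=["s1"])
    sv = tme_score(frac, _weights(["c1"], [-0.5]))
    assert sv.score[0] == pytest.approx(0.1, abs=1e-12)
    assert tme_score(frac * 0.0, _weights(["c1"], [-0.5])).score[0] == 0.0


def test_tm_score_monotone_in_positive_weight_gene():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.uniform(1, 5, size=(10, 3)), columns=list("abc"))
    w = _weights(list("abc"), [0.7, -0.2, 0.1])
    base = tm_score(expr, w).score
    bumped = expr.copy()
    bumped["a"] *= 2
    assert (tm_score(bumped, w).score > base).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_score_linearity(seed):
    rng = np.random.default_rng(seed)
    k = 4
    w = _weights([f"g{i}" for i in range(k)], rng.normal(size=k))
    x = rng.normal(size=(3, k))
    y = rng.normal(size=(3, k))
    a, b = rng.normal(size=2)
    cols = list(w.feature_names)
    sx = tm_score(pd.DataFrame(x, columns=cols), w).score
    sy = tm_score(pd.DataFrame(y, columns=cols), w).score
    sxy = tm_score(pd.DataFrame(a * x + b * y, columns=cols), w).score
    np.testing.assert_allclose(sxy, a * sx + b * sy, atol=1e-9)


def test_missing_signature_gene_is_hard_error():
    expr = pd.DataFrame([[1.0]], columns=["g1"], index=["s1"])
    w = _weights(["g1", "g2"], [1.0, 1.0])
    with pytest.raises(KeyError, match="g2"):
        tm_score(expr, w)
    dropped = tm_score(expr, w, allow_missing=True)
    assert dropped.score[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# bootstrap weighting
# ---------------------------------------------------------------------------

def test_single_resample_rejected(planted_cohort):
    genes = sorted(planted_cohort.truth["gene_effects"])[:3]
    with pytest.raises(ValueError, match="B"):
        bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=1)


def test_weights_deterministic_given_seed(planted_cohort):
    genes = sorted(planted_cohort.truth["gene_effects"])[:4]
    a = bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=25, seed=5)
    b = bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=25, seed=5)
    assert np.array_equal(a.weight, b.weight)
    assert np.array_equal(a.sd, b.sd)
    c = bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=25, seed=6)
    assert not np.array_equal(a.weight, c.weight)


def test_weight_identity_and_positive_sd(planted_cohort):
    genes = sorted(planted_cohort.truth["gene_effects"])[:4]
    w = bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=30, seed=0)
    np.testing.assert_allclose(w.weight * w.sd, w.coef, atol=1e-12)
    assert (w.sd > 0).all()
    assert w.n_converged <= w.n_resamples


def test_planted_gene_weight_sign_recovery():
    """A +0.8 standardized log-hazard gene gets a positive weight (5 seeds)."""
    for seed in range(5):
        cohort = generate_cohort(SyntheticCohortConfig(
            seed=seed, n_samples=500, n_genes=20, n_signal_genes=1,
            signal_effects=(0.8,)))
        gene = next(iter(cohort.truth["gene_effects"]))
        w = bootstrap_cox_weights(cohort.expression[[gene]], cohort.survival,
                                  B=50, seed=seed)
        assert w.weight[0] > 0, f"seed {seed}"


def test_subsample_mode_runs(planted_cohort):
    genes = sorted(planted_cohort.truth["gene_effects"])[:3]
    w = bootstrap_cox_weights(planted_cohort.expression[genes],
                              planted_cohort.survival, B=20, seed=0,
                              mode="subsample", subsample_fraction=0.7)
    assert w.n_converged >= 18


def test_raising_favorable_fraction_raises_tme_score(trained_model, planted_cohort):
    """All-negative fitted cell weights: more favorable infiltrate, higher score."""
    w = trained_model.cell_weights_
    assert (w.weight < 0).all()
    frac = planted_cohort.fractions.iloc[:5].copy()
    base = tme_score(frac, w).score
    for cell in w.feature_names:
        bumped = frac.copy()
        bumped[cell] += 0.05
        assert (tme_score(bumped, w).score > base).all()


def test_weighter_transformer_roundtrip(planted_cohort):
    genes = sorted(planted_cohort.truth["gene_effects"])[:4]
    est = BootstrapCoxWeighter(kind="TM", B=20, seed=0)
    est.fit(planted_cohort.expression[genes], planted_cohort.survival)
    out = est.transform(planted_cohort.expression[genes])
    manual = tm_score(planted_cohort.expression[genes], est.weights_).score
    np.testing.assert_allclose(out[:, 0], manual, atol=1e-12)
    params = est.get_params()
    assert params["B"] == 20 and params["kind"] == "TM"
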