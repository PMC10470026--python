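import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tmtme.classify import TMTMEClassifier
from tmtme.simulate import SyntheticCohortConfig, generate_cohort
from tmtme.survival import SurvivalData


def null_config(seed, n_samples=300, n_genes=100, **kw):
    """Cohort config with every planted effect removed."""
    return SyntheticCohortConfig(
        seed=seed, n_samples=n_samples, n_genes=n_genes,
        n_signal_genes=0, signal_effects=(),
        cell_effects=(0.0,) * 10, favorable_cells=(), **kw)


@pytest.fixture(scope="session")
def planted_cohort():
    """One default planted cohort (n=600, 10 signal genes, 5 favorable cells)."""
    return generate_cohort(SyntheticCohortConfig(seed=42))


@pytest.fixture(scope="session")
def held_out_cohort():
    return generate_cohort(SyntheticCohortConfig(seed=4242))


@pytest.fixture(scope="session")
def trained_model(planted_cohort):
    """A TM-TME classifier fitted on the planted cohort (B=100)."""
    clf = TMTMEClassifier(
        cell_cols=list(planted_cohort.fractions.columns),
        cells=planted_cohort.truth["favorable_cells"],
        B=100, seed=0)
    clf.fit(planted_cohort.features(), planted_cohort.survival)
    return clf


@pytest.fixture
def toy_survival():
    """The 4-sample hand-computable outcome: events at 1 and 3, censored at 2 and 4."""
    return SurvivalData(np.array(["a", "b", "c", "d"], dtype=object),
                        [1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
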