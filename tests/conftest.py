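import numpy as np
import pandas as pd
import pytest

from rulefuse.diagnostic import published_model, published_ruleset
from rulefuse.extract import EnsembleConfig
from rulefuse.features import FeatureTable
from rulefuse.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def pub_model():
    return published_model()


@pytest.fixture(scope="session")
def pub_rules():
    return published_ruleset()


@pytest.fixture(scope="session")
def zero_indicators(pub_rules):
    """Indicator matrix of three samples on which no rule fires."""
    return pd.DataFrame({r.id: [0, 0, 0] for r in pub_rules})


@pytest.fixture(scope="session")
def lesion_cohort():
    """Small published-model cohort reused across tests."""
    return generate_cohort(
        CohortConfig(n=150, seed=5, label_mechanism="published_model")
    )


@pytest.fixture(scope="session")
def small_ensembles():
    """Ensemble configuration small enough for unit tests."""
    return EnsembleConfig(
        gb_n_estimators=30, rf_n_estimators=30, ada_n_estimators=10
    )


@pytest.fixture()
def toy_table():
    """Six samples, one continuous and one binary feature, labels."""
    frame = pd.DataFrame(
        {
            "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "flag": [0, 1, 0, 1, 0, 1],
        }
    )
    labels = pd.Series([0, 1, 0, 1, 0, 1])
    return FeatureTable(frame, labels=labels)
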