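import numpy as np
import pandas as pd
import pytest

import radharmon as rh


@pytest.fixture(scope="session")
def effect_cohort():
    """Default effect-scenario cohort: 104+104 subjects, 86 features,
    50 genes, location-dominated batch effect (2 SD), 3 causal pairs."""
    return rh.generate_cohort(rh.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """No batch effect, no causal pairs."""
    return rh.generate_cohort(rh.SimulationConfig.null(seed=5))


@pytest.fixture
def tiny_matrix():
    """Hand-sized two-batch matrix for exact-value checks."""
    rng = np.random.default_rng(42)
    subj = [f"s{i}" for i in range(10)]
    vals = pd.DataFrame(rng.normal(size=(10, 5)),
                        index=subj, columns=[f"f{j}" for j in range(5)])
    batch = pd.Series([1] * 5 + [2] * 5, index=subj)
    return rh.FeatureMatrix(values=vals, batch=batch)


def make_feature_matrix(values, batch, prefix="f"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    subj = [f"s{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=subj,
                      columns=[f"{prefix}{j}" for j in range(values.shape[1])])
    return rh.FeatureMatrix(values=df, batch=pd.Series(list(batch), index=subj))
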