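import numpy as np
import pandas as pd
import pytest

from ucurve.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort at the default (paper-regime) generator settings."""
    cfg = SynthConfig(seed=42, n_subjects=2000)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_covariates(rng):
    n = 400
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n).astype(float),
        "age": rng.normal(10, 0.6, n),
        "site": pd.Categorical(rng.choice(["a", "b", "c"], n)),
    })
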