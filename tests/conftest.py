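import numpy as np
import pandas as pd
import pytest

import lipidsig as L
from lipidsig import tableio


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic study with ground truth (shared, read-only)."""
    return L.simulate_study(L.SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast study: 300 features, 12 planted discriminators."""
    config = L.SimConfig(n_features=300, n_discriminatory=12, n_age_assoc=3, seed=5)
    return L.simulate_study(config)


def make_table(intensities, roles, classes=None, dilution=None, injection=None,
               age=None, sex=None):
    """Assemble a FeatureTable from raw pieces; ids generated positionally."""
    intensities = np.asarray(intensities, dtype=float)
    n, p = intensities.shape
    sample_ids = [f"s{i}" for i in range(n)]
    feature_ids = [f"f{j}" for j in range(p)]
    samples = pd.DataFrame(
        {
            "role": roles,
            "class": classes if classes is not None else [np.nan] * n,
            "injection_order": injection if injection is not None else range(1, n + 1),
            "dilution_factor": dilution if dilution is not None else [np.nan] * n,
            "age_months": age if age is not None else [np.nan] * n,
            "sex": sex if sex is not None else [np.nan] * n,
        },
        index=sample_ids,
    )
    features = pd.DataFrame(
        {"mz": 100.0, "rt_min": 1.0, "annotation": "UNKNOWN", "annotation_level": 4},
        index=feature_ids,
    )
    return tableio.FeatureTable(
        pd.DataFrame(intensities, index=sample_ids, columns=feature_ids),
        samples,
        features,
    )


@pytest.fixture
def two_class_table():
    """20 + 20 study samples, 5 features, feature f0 strongly class-separated."""
    rng = np.random.default_rng(42)
    n = 40
    y = np.array([1.0] * 20 + [0.0] * 20)
    X = rng.lognormal(mean=8, sigma=0.3, size=(n, 5))
    X[:, 0] *= np.exp(1.5 * (y - 0.5))
    return make_table(
        X,
        roles=["study"] * n,
        classes=["bacterial"] * 20 + ["viral"] * 20,
        age=list(rng.uniform(1, 100, size=n)),
        sex=list(rng.choice(["male", "female"], size=n)),
    )
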