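import numpy as np
import pytest

from toxsig import synthetic
from toxsig.expression import compute_group_profiles


@pytest.fixture(scope="session")
def default_data():
    """Full-scale synthetic dataset with the study design (seed 0)."""
    ds, truth = synthetic.generate(synthetic.SyntheticDesign(seed=0))
    return ds, truth


@pytest.fixture(scope="session")
def day14_defined(default_data):
    ds, _ = default_data
    profiles = compute_group_profiles(ds, 14)
    return [p for p in profiles if p.class_label in ("GC", "NGC", "NC")]


@pytest.fixture(scope="session")
def small_data():
    """Scaled-down dataset (500 probesets, 4 replicates) for fast tests."""
    design = synthetic.SyntheticDesign(n_probesets=500, replicates=4, seed=7)
    return synthetic.generate(design)


def planted_matrix(n_per_class=20, n_features=100, n_planted=2, effect=2.0, seed=0):
    """Simple planted-signal benchmark: first `n_planted` features shifted by
    `effect` standard deviations in the positive class, the rest pure noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (2 * n_per_class, n_features))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1, :n_planted] += effect
    return X, y


@pytest.fixture
def planted_Xy():
    return planted_matrix()
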