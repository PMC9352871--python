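import numpy as np
import pytest

from gaselect import FeatureTable, SyntheticSpec, generate


@pytest.fixture
def tiny_table():
    """4 samples x 3 features, balanced labels."""
    return FeatureTable(
        sample_ids=("s1", "s2", "s3", "s4"),
        feature_names=("fa", "fb", "fc"),
        values=np.array(
            [[1.0, 2.0, 3.0],
             [4.0, 5.0, 6.0],
             [7.0, 8.0, 9.0],
             [10.0, 11.0, 12.0]]
        ),
        labels=np.array([1, 1, 0, 0]),
    )


@pytest.fixture
def separable_table():
    """One feature ('sep') perfectly separates the classes; the rest is
    pure noise."""
    rng = np.random.default_rng(42)
    n = 40
    y = np.repeat([0, 1], n // 2)
    sep = np.where(y == 1, 5.0, -5.0) + 0.1 * rng.standard_normal(n)
    noise = rng.standard_normal((n, 9))
    values = np.column_stack([noise[:, :4], sep, noise[:, 4:]])
    names = tuple(f"n{i}" for i in range(4)) + ("sep",) + tuple(
        f"m{i}" for i in range(5)
    )
    ids = tuple(f"p{i:02d}" for i in range(n))
    return FeatureTable(ids, names, values, y)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted-signal cohort shared by slower tests."""
    spec = SyntheticSpec(
        n_samples=50, n_features=30, n_informative=5, n_redundant=3,
        effect_size=1.5, seed=11,
    )
    return generate(spec)
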