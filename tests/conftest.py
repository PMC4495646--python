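import numpy as np
import pytest

from quantro import FeatureMatrix


@pytest.fixture
def worked_matrix() -> FeatureMatrix:
    """Hand-checked 3-feature, 2+2-sample matrix.

    After median centering the sample quantile functions are
    g1: [-1,0,1], [-2,0,2] and g2: [-4,0,4], [-5,0,5], for which the
    Mallows-distance decomposition is SS = (20/3, 6, 2/3) and F = 18;
    the three distinct two-vs-two splits give null F values {18, 2/9, 0}.
    """
    values = np.array(
        [[-1.0, -2.0, -4.0, -5.0],
         [0.0, 0.0, 0.0, 0.0],
         [1.0, 2.0, 4.0, 5.0]]
    )
    return FeatureMatrix(values, groups=np.array(["g1", "g1", "g2", "g2"], dtype=object))


def random_grouped_matrix(rng: np.random.Generator, n_features=None, sizes=None) -> FeatureMatrix:
    """Random grouped matrix with varied K and (possibly unbalanced) n_k."""
    if sizes is None:
        k = rng.integers(2, 5)
        sizes = rng.integers(1, 5, size=k)
        while (sizes >= 2).sum() < 2:
            sizes = rng.integers(1, 5, size=k)
    if n_features is None:
        n_features = int(rng.integers(10, 1001))
    n_t = int(np.sum(sizes))
    values = rng.normal(size=(n_features, n_t)) * rng.uniform(0.5, 3)
    groups = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
    return FeatureMatrix(values, groups=groups.astype(object))
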