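import numpy as np
import pytest

from llarrma.containers import CaseControlResponse, GenotypeMatrix
from llarrma.lasso import center_columns


def random_case_control(rng, n=80, m=6, effect=0.8, n_causal=1):
    """Small well-conditioned logistic instance for solver tests."""
    from scipy.special import expit

    X = rng.integers(0, 3, size=(n, m)).astype(float)
    # guard against constant columns in tiny draws
    for j in range(m):
        while X[:, j].min() == X[:, j].max():
            X[:, j] = rng.integers(0, 3, size=n)
    beta = np.zeros(m)
    beta[:n_causal] = effect
    Xc, _ = center_columns(X)
    y = rng.binomial(1, expit(Xc @ beta))
    while y.min() == y.max():
        y = rng.binomial(1, expit(Xc @ beta))
    return X, y


@pytest.fixture
def toy_genotypes():
    values = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 1.0],
            [0.0, 2.0, 2.0],
        ]
    )
    return GenotypeMatrix(values, ["s1", "s2", "s3"], ["a", "b", "c", "d"],
                          positions=np.array([100, 200, 300]))


@pytest.fixture
def balanced_response():
    return CaseControlResponse(np.array([1, 0, 1, 0]))
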