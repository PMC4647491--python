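import numpy as np
import pandas as pd
import pytest

from codewise import benchmark_config, generate_feature_table


@pytest.fixture(scope="session")
def benchmark():
    """The synthetic labelled benchmark: 3,000 coding + 1,000 noncoding rows."""
    X, y = generate_feature_table(benchmark_config(seed=42))
    return X, y


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable 2-feature toy set: coding near (+1,+1),
    noncoding near (-1,-1), 20 points each."""
    rng = np.random.default_rng(7)
    X = np.vstack([
        rng.normal([1.0, 1.0], 0.1, (20, 2)),
        rng.normal([-1.0, -1.0], 0.1, (20, 2)),
    ])
    y = np.array([1] * 20 + [-1] * 20)
    X = pd.DataFrame(X, columns=["f1", "f2"])
    return X, y
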