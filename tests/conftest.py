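import numpy as np
import pandas as pd
import pytest

from mirsig import SyntheticSpec, generate_labeled_expression
from mirsig.ensemble import EnsembleConfig, EnsembleFeatureSelection

# ensemble configuration used on the 600x200 benchmark: full roster, one run
# of 5-fold CV per family, 50 trees per tree ensemble, 20-feature tally and
# signature (10% of the features, mirroring the 100-of-1046 protocol)
BENCHMARK_CONFIG = EnsembleConfig(
    n_runs=1,
    n_folds=5,
    top_k_tally=20,
    signature_size=20,
    seed=1,
    n_estimators=50,
)


@pytest.fixture(scope="session")
def benchmark_data():
    """Default synthetic benchmark: 600 samples, 8 unbalanced classes,
    200 features of which 20 planted, effect 1.5."""
    return generate_labeled_expression(SyntheticSpec())


@pytest.fixture(scope="session")
def benchmark_selection(benchmark_data):
    """Fitted ensemble selection on the benchmark (shared: it is the slow part)."""
    X, labels, _ = benchmark_data
    return EnsembleFeatureSelection(X, labels["tumor_type"].to_numpy(), BENCHMARK_CONFIG).fit()


@pytest.fixture
def toy4():
    """Small 4-class dataset for fast protocol tests."""
    spec = SyntheticSpec(
        n_samples=120,
        n_classes=4,
        class_proportions=(0.4, 0.3, 0.2, 0.1),
        n_features=10,
        n_informative=5,
        effect_size=2.0,
        seed=2,
    )
    return generate_labeled_expression(spec)


@pytest.fixture
def separable2():
    """Linearly separable 2-class toy."""
    rng = np.random.default_rng(0)
    n = 60
    x1 = rng.normal(0, 0.3, size=(n, 2)) + [0, 0]
    x2 = rng.normal(0, 0.3, size=(n, 2)) + [8, 8]
    X = pd.DataFrame(
        np.vstack([x1, x2]),
        columns=["fA", "fB"],
        index=[f"s{i}" for i in range(2 * n)],
    )
    y = np.array(["neg"] * n + ["pos"] * n)
    return X, y
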