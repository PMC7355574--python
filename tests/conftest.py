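import numpy as np
import pandas as pd
import pytest

import sigselect as ss


@pytest.fixture
def small_em():
    """4 genes x 6 samples, two classes, no missing values."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(0.0, 1.0, size=(4, 6)),
        index=["GA", "GB", "GC", "GD"],
        columns=[f"s{i}" for i in range(6)],
    )
    labels = pd.Series(
        ["A", "A", "A", "B", "B", "B"], index=values.columns
    )
    return ss.ExpressionMatrix(values=values, class_labels=labels)


@pytest.fixture(scope="session")
def fast_dataset():
    """Small synthetic dataset tuned for quick pipeline tests."""
    spec = ss.SyntheticSpec(
        n_genes=30,
        n_per_class=(10, 12),
        planted_genes=5,
        effect_size=2.5,
        block_structure=((5, 0.5),),
        seed=7,
    )
    return ss.generate(spec)


@pytest.fixture
def fast_config():
    return ss.CVConfiguration(
        k_outer=5, k_inner=3, n_tau=8, lambda_grid=(0.1, 1.0), seed=7
    )
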