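import numpy as np
import pandas as pd
import pytest

from sigsift import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """4 balanced classes x 12 samples, 120 genes, 6 strongly planted."""
    cfg = SyntheticConfig(
        class_sizes=(12, 12, 12, 12),
        n_genes=120,
        n_informative=6,
        effect_size=4.0,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_matrix(rng, n_genes=8, n_samples=5, prefix="g"):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"{prefix}s{j}" for j in range(n_samples)],
    )
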