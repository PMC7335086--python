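import numpy as np
import pandas as pd
import pytest

from rcclust.config_io import ExpressionMatrix, RCCConfig
from rcclust.simulate import SyntheticSpec, simulate_flat


@pytest.fixture(scope="session")
def small_groups():
    """Three well-separated groups of 20 samples, 300 genes (fast fixture)."""
    spec = SyntheticSpec(
        group_sizes=(20, 20, 20),
        n_genes=300,
        markers_per_group=30,
        effect_log2=4.0,
        noise_sd=1.0,
        seed=42,
    )
    return simulate_flat(spec)


@pytest.fixture(scope="session")
def random_matrix():
    """Structureless 60-gene x 24-sample log-expression matrix."""
    rng = np.random.default_rng(7)
    vals = np.clip(rng.normal(5, 1, size=(60, 1)) + rng.normal(0, 1, (60, 24)), 0, None)
    return ExpressionMatrix(
        vals,
        [f"g{i:03d}" for i in range(60)],
        [f"s{j:02d}" for j in range(24)],
    )


@pytest.fixture
def fast_config():
    """Bulk config with few consensus repeats for second-scale recursion tests."""
    return RCCConfig(data_type="bulk", seed=5, repeats_per_process=15)


@pytest.fixture
def expression_csv(tmp_path):
    def _write(df: pd.DataFrame, name="expr.csv"):
        path = tmp_path / name
        df.to_csv(path)
        return path

    return _write
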