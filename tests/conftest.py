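import numpy as np
import pytest

from spotalign import SyntheticConfig, gen_dataset, gen_study


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale study: 64 spots, 3 types, 40 genes, 32-px patches."""
    return SyntheticConfig(n_rows=8, n_cols=8, k=3, d=40, r_signal=3,
                           patch_px=32, count_depth=2000, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    ds, truth = gen_dataset(tiny_config, sample_id="tiny")
    return ds, truth


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    """Two slides sharing type-level parameters."""
    return gen_study(tiny_config, n_slides=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
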