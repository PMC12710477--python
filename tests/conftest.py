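import numpy as np
import pytest

import fewshot_synergy as fs


@pytest.fixture(scope="session")
def tiny_world():
    """A small synthetic world shared by read-only tests."""
    return fs.make_world(
        fs.SyntheticWorldConfig(
            n_drugs=12, n_cell_lines=8, samples_per_cell_line=30, seed=3
        )
    )


@pytest.fixture(scope="session")
def small_config():
    return fs.desk_config(
        gcn_dims=(16, 16, 24),
        cnn_channels=(2, 4),
        fd_hidden=16,
        fd_out=8,
        fc_out=8,
        head_hidden=16,
        dropout=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
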