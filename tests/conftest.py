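import numpy as np
import pytest

from seedsortnet import (
    NetworkConfig,
    StageEntry,
    SyntheticSpec,
    build_network,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


TINY_PLAN = (
    StageEntry("root", 32),
    StageEntry("shield", 64, repeats=2),
    StageEntry("sfsam", 64),
    StageEntry("maxblurpool", 64),
    StageEntry("globalavgpool", 64),
    StageEntry("head", 2),
)


@pytest.fixture
def tiny_config():
    """A shallow single-stage network for fast training tests."""
    return NetworkConfig(input_size=32, stage_plan=TINY_PLAN,
                         root_branch_channels=16)


@pytest.fixture
def tiny_net(tiny_config):
    return build_network(tiny_config, seed=0)


@pytest.fixture(scope="session")
def default_net():
    """The full published architecture (built once per session)."""
    return build_network(NetworkConfig(), seed=0)


@pytest.fixture(scope="session")
def noiseless_small():
    """64 clean synthetic images (32 per class) at native resolution."""
    return generate_dataset(SyntheticSpec(n_per_class=32, noise_sd=0.0, rng_seed=0))
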