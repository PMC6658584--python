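import numpy as np
import pytest

from snnclust.network import NetworkConfig, build_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(**overrides) -> NetworkConfig:
    """A small LIF network config that runs in well under a second."""
    defaults = dict(
        n_classes=2,
        image_shape=(4, 4),
        n_cn_groups=3,
        cn_group_size=5,
        an_group_size=8,
        teach_size=10,
        backend="lif",
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


@pytest.fixture
def tiny_net(rng):
    return build_network(tiny_config(), rng)
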