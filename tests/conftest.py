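import numpy as np
import pytest

from v1net.config import load_config, materialize
from v1net.network import build_network


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return load_config()


def make_network(seed=0, **overrides):
    """Small helper: network from defaults with network-section overrides."""
    cfg = load_config(overrides={"network": {k: float(v) if k.startswith("W")
                                             or "w_" in k or "rate" in k
                                             else v
                                             for k, v in overrides.items()}})
    cfg["seed"] = seed
    net_cfg, neuron, plast = materialize(cfg)
    return build_network(net_cfg, neuron, plast)


@pytest.fixture()
def tiny_network():
    """A 4E/2I network with quiet noise, for fast engine tests."""
    return make_network(n_E=4, n_I=2, noise_rate=0.0)
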