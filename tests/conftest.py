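import logging

import numpy as np
import pytest

from sonofc.core import NodeAtlas, Region
from sonofc.synth import build_network

# the high-pass fallback warning is expected on short runs and floods logs
logging.getLogger("sonofc.preprocess").setLevel(logging.ERROR)
logging.getLogger("sonofc.connectivity").setLevel(logging.ERROR)


@pytest.fixture
def toy_atlas() -> NodeAtlas:
    """4 nodes, 2 points each: two bilateral, two midline."""
    return NodeAtlas(
        [
            Region("alpha.L", "alpha", "left", (0,)),
            Region("alpha.R", "alpha", "right", (1,)),
            Region("beta", "beta", "midline", (2, 3)),
            Region("gamma.L", "gamma", "left", (4,)),
            Region("gamma.R", "gamma", "right", (5,)),
            Region("delta", "delta", "midline", (6, 7)),
        ],
        roles={"alpha": {"sonication_target", "fingerprint_target"},
               "beta": {"fingerprint_target", "apriori_heatmap"},
               "gamma": {"fingerprint_target", "apriori_heatmap"},
               "delta": {"fingerprint_target", "apriori_heatmap", "control"}},
    )


@pytest.fixture
def toy_network():
    """4-node network: one 2-node module pair, moderate coupling."""
    return build_network(
        4, 0.6, 0.1, [[0, 1], [2, 3]],
        node_names=("alpha", "beta", "gamma", "delta"),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
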