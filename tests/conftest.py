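import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from emgnet.minet import BinaryNet
from emgnet.synthetic import SimConfig, generate_recording


def make_net(n, edges, labels=None):
    """Small helper: BinaryNet from an edge list over 0-based indices."""
    labels = labels or [f"V{i + 1}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return BinaryNet(labels=labels, adjacency=adj)


@pytest.fixture(scope="session")
def path3():
    """Path graph 1-2-3."""
    return make_net(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def two_group_recording():
    """Six channels in two latent groups, strong coupling, one repetition."""
    cfg = SimConfig(
        n_channels=6,
        n_repetitions=2,
        group_assignment={"V1": 0, "V2": 0, "V3": 0, "V4": 1, "V5": 1, "V6": 1},
        group_strength=0.8,
        seed=11,
    )
    rec, truth = generate_recording(cfg)
    return rec, truth
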