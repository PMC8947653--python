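"""Shared fixtures: seeded RNG and trained clarity networks.

Two training scales are shared across the suite: a quick network (1200
pairs, 3 epochs) for unit-level behavior, and a desk-scale network (5000
pairs, 10 epochs) for the end-to-end quality checks.  Both are trained once
per session.
"""

import numpy as np
import pytest

from medfuse import NetworkConfig, generate_patch_pairs, train_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def quick_weights():
    pairs = generate_patch_pairs(1200, 16, (1.0, 3.0), seed=3)
    return train_network(pairs, NetworkConfig(epochs=3, seed=11))


@pytest.fixture(scope="session")
def desk_weights():
    """Desk-scale training: 5000 synthetic 16x16 pairs, 10 epochs of SGD."""
    pairs = generate_patch_pairs(5000, 16, (1.0, 3.0), seed=3)
    return train_network(pairs, NetworkConfig(learning_rate=0.01, epochs=10, seed=11))
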