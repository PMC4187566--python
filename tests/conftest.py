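"""Shared fixtures: small seeded phantoms reused across the suite.

Phantom rendering plus detection costs seconds per volume, so the expensive
volumes are session-scoped and shared; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from acinostat.phantom import TreeParams, generate_airway_tree, voxelize_tree


def make_phantom(
    n_acini: int,
    seed: int,
    gen_range=(4, 8),
    dual_fraction: float = 0.0,
    voxel_size: float = 2.35,
    noise_sd: float = 10.0,
    **overrides,
):
    params = TreeParams(
        n_acini_target=n_acini,
        seed=seed,
        generation_range_entrances=gen_range,
        dual_entrance_fraction=dual_fraction,
        **overrides,
    )
    tree = generate_airway_tree(params)
    return voxelize_tree(tree, voxel_size, noise_sd=noise_sd, seed=seed)


@pytest.fixture(scope="session")
def phantom13():
    """13 acini, unbranched transitional bronchioles only."""
    return make_phantom(13, seed=1)


@pytest.fixture(scope="session")
def phantom13_dual():
    """13 acini with some branched (dual-entrance) transitional bronchioles."""
    return make_phantom(13, seed=3, dual_fraction=0.3)


@pytest.fixture(scope="session")
def phantom25():
    """25 acini with the default dual-entrance fraction."""
    return make_phantom(25, seed=11, gen_range=(4, 9), dual_fraction=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(20140704)
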