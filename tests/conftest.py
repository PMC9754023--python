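"""Shared synthetic-scene fixtures (session-scoped: scenes are deterministic
given their seed, so they are rendered once and reused read-only)."""

import numpy as np
import pytest

from nucspat3d import scenes
from nucspat3d.core import ImageStack

VOXEL = (0.1, 0.05, 0.05)


@pytest.fixture(scope="session")
def interphase():
    """Default interphase scene: 8 CC, 20 nanoCC, 150 clusters, seed 1."""
    return scenes.make_interphase_scene(seed=1)


@pytest.fixture(scope="session")
def interphase_small():
    """Lighter interphase scene for segmentation unit tests."""
    return scenes.make_interphase_scene(seed=1, n_clusters=20)


@pytest.fixture(scope="session")
def ne_scene():
    return scenes.make_ne_scene(seed=2)


@pytest.fixture(scope="session")
def meiotic_scene():
    return scenes.make_meiotic_scene(seed=1, n_foci=60)


@pytest.fixture(scope="session")
def chromosome_scene():
    return scenes.make_chromosome_scene(seed=1)


@pytest.fixture(scope="session")
def rabl_scene():
    return scenes.make_rabl_scene(seed=1, configuration="rabl")


@pytest.fixture(scope="session")
def non_rabl_scene():
    return scenes.make_rabl_scene(seed=1, configuration="non_rabl")


@pytest.fixture(scope="session")
def anaphase_scene():
    return scenes.make_anaphase_scene(seed=3, angle=30.0)


def make_stack(arrays, voxel_size=VOXEL, names=None, **kw):
    """Small helper: build an ImageStack from per-channel arrays."""
    data = np.stack([np.asarray(a, float) for a in arrays])
    return ImageStack(data, voxel_size, names or [f"ch{i}" for i in range(len(arrays))], **kw)
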