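import math

import numpy as np
import pytest
from skimage import draw

from budtrack import ColonyConfig, grow_colony


def disk_mask(shape, center, radius):
    img = np.zeros(shape, bool)
    rr, cc = draw.disk(center, radius, shape=shape)
    img[rr, cc] = True
    return img


def random_label_frame(rng, shape=(48, 48), max_objects=6):
    """Random frame of up to max_objects disjoint-ish disks."""
    img = np.zeros(shape, np.int32)
    n = int(rng.integers(1, max_objects + 1))
    for lab in range(1, n + 1):
        r = int(rng.integers(3, 7))
        cy = int(rng.integers(r, shape[0] - r))
        cx = int(rng.integers(r, shape[1] - r))
        rr, cc = draw.disk((cy, cx), r, shape=shape)
        img[rr, cc] = lab
    return img


def make_dumbbell(shape, c1, r1, c2, r2):
    """Two overlapping/touching disks as one label, plus the two truth masks.

    Overlap pixels belong to the larger disk in the truth partition.
    """
    big = disk_mask(shape, c1, r1)
    small = disk_mask(shape, c2, r2)
    merged = (big | small).astype(np.int32)
    return merged, big, small & ~big


@pytest.fixture(scope="session")
def colony():
    """A default 3-founder colony used by several test modules."""
    return grow_colony(ColonyConfig(n_founders=3, frames=30, seed=1))


@pytest.fixture(scope="session")
def small_colony():
    """One founder, a dozen frames: a single full cell cycle plus a second bud."""
    return grow_colony(ColonyConfig(n_founders=1, frames=16, frame_shape=(128, 128), seed=4))
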