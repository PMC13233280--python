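from __future__ import annotations

import numpy as np
import pytest

from deltarad.preprocess import DiscretizedROI


def make_droi(levels: np.ndarray, voxel_volume: float = 1.0) -> DiscretizedROI:
    """Wrap an integer level grid (0 = background) as a DiscretizedROI."""
    levels = np.asarray(levels, dtype=np.int64)
    return DiscretizedROI(levels=levels, Ng=int(levels.max()),
                          bin_edges={"method": "direct"},
                          n_voxels=int((levels > 0).sum()),
                          voxel_volume=voxel_volume)


def random_droi(rng: np.random.Generator, ng: int = 4, max_shape: int = 5
                ) -> DiscretizedROI:
    """A random small ROI: random levels on a random sub-box, rest background."""
    shape = tuple(rng.integers(2, max_shape + 1, size=3))
    levels = rng.integers(1, ng + 1, size=shape)
    # carve a random background region so the ROI is not a full box
    hole = rng.random(shape) < 0.2
    levels[hole] = 0
    if (levels > 0).sum() < 2:
        levels[0, 0, 0] = 1
        levels[-1, -1, -1] = ng
    d = make_droi(levels)
    return DiscretizedROI(levels=d.levels, Ng=ng, bin_edges=d.bin_edges,
                          n_voxels=d.n_voxels, voxel_volume=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
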