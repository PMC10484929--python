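import math

import numpy as np
import pytest

from brainfrac.synthetic import PhantomSpec3D, PlantedCell, PhantomSpec2D


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast 3D phantom used by module tests."""
    return PhantomSpec3D(
        shape_vx=(32, 48, 48),
        brain_semiaxes_vx=(12.0, 18.0, 18.0),
    )


def make_separated_cells(
    n, rng, radius=4.0, extra_channels=(), shape=(512, 512), margin=30, min_dist=30.0
):
    """Plant n non-overlapping disks at random positions; the first
    len(extra_channels[i]) memberships follow the caller's plan."""
    centers = []
    while len(centers) < n:
        p = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        if all(math.dist(p, q) >= min_dist for q in centers):
            centers.append(p)
    cells = []
    for i, c in enumerate(centers):
        ch = {"ccasp3"}
        for name, count in extra_channels:
            if i < count:
                ch.add(name)
        cells.append(PlantedCell(center_px=c, radius_px=radius, channels=frozenset(ch)))
    return tuple(cells)


@pytest.fixture
def slice_spec():
    rng = np.random.default_rng(42)
    cells = make_separated_cells(12, rng, extra_channels=[("NeuN", 7)])
    return PhantomSpec2D(
        cells=cells, layer_boundaries_px=(0, 60, 200, 320, 512), seed=7
    )
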