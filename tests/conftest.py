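import numpy as np
import pytest

import polarflow as pf
from polarflow.network import Segment, VesselNetwork


def make_tube(r: float = 4.0, length: float = 100.0) -> VesselNetwork:
    """Single straight horizontal vessel from (0,0) to (L,0)."""
    net = VesselNetwork()
    net.nodes[0] = np.array([0.0, 0.0])
    net.nodes[1] = np.array([length, 0.0])
    net.segments[0] = Segment(
        0, 1, np.array([[0.0, 0.0], [length, 0.0]]), np.full(2, r)
    )
    net.inlets, net.outlets = [0], [1]
    return net


def add_segment(net: VesselNetwork, a: int, b: int, r: float,
                sid: int | None = None, **kw) -> int:
    sid = sid if sid is not None else (max(net.segments, default=-1) + 1)
    p0, p1 = net.nodes[a], net.nodes[b]
    n = max(2, int(np.ceil(np.hypot(*(p1 - p0)) / 10.0)) + 1)
    t = np.linspace(0.0, 1.0, n)
    poly = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    net.segments[sid] = Segment(a, b, poly, np.full(n, r), **kw)
    return sid


SMALL_CFG_KW = dict(
    retina_radius=400.0,
    capillary_spacing=50.0,
    n_arteries=3,
    n_veins=3,
    n_cells_target=2000,
    regression_rate=0.06,
    apoptosis_total_mean=25.0,
)

# rendering-friendly plexus for mask → graph roundtrips: sparse mains,
# moderate radii, 1 μm pixels
ROUNDTRIP_CFG_KW = dict(
    retina_radius=280.0,
    capillary_spacing=60.0,
    n_arteries=2,
    n_veins=2,
    radius_artery=6.0,
    radius_vein=7.0,
    radius_capillary=3.0,
    pixel_size=1.0,
    regression_rate=0.0,
    capillary_dropout=0.1,
)


@pytest.fixture(scope="session")
def small_world() -> pf.World:
    """A reduced synthetic retina shared by read-only tests."""
    return pf.simulate_world(pf.GenConfig(seed=11, **SMALL_CFG_KW))


@pytest.fixture(scope="session")
def small_world_analyzed(small_world):
    """Small world with the cell table carried through assignment and
    angle/scalar computation."""
    from polarflow.polarity import (
        angle_and_scalar,
        assign_to_segments,
        cells_from_table,
    )

    cells = cells_from_table(small_world.cells)
    cells = assign_to_segments(cells, small_world.net)
    cells = angle_and_scalar(cells, small_world.net, small_world.flow)
    return small_world, cells
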