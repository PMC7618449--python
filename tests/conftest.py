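"""Shared fixtures: canonical small networks and solver settings.

Oracle fixtures use 8 μm vessels so the finite-difference reference can
resolve the lumen on a 2 μm grid, and an elevated consumption rate
(M0 = 1e-3 cm³O₂·cm⁻³·s⁻¹) so diffusion gradients are O(10 mmHg) and
percentage comparisons are meaningful.
"""

import numpy as np
import pytest
from hypothesis import settings

import plexflow as pf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def seg_axis_distance(net: pf.VesselNetwork, pts: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment chord."""
    dist = np.full(len(pts), np.inf)
    for seg in net.segments.values():
        a = net.nodes[seg.node_a].position
        b = net.nodes[seg.node_b].position
        ab = b - a
        t = np.clip((pts - a) @ ab / (ab @ ab), 0, 1)
        dist = np.minimum(dist, np.linalg.norm(pts - (a + t[:, None] * ab), axis=1))
    return dist


def make_tube(length=60.0, diameter=6.0, p_in=16.0, p_out=15.0, inlet_po2=60.0):
    net = pf.VesselNetwork(provenance="fixture:tube")
    net.nodes[0] = pf.VesselNode(0, [0.0, 0.0, 0.0])
    net.nodes[1] = pf.VesselNode(1, [length, 0.0, 0.0])
    net.segments[0] = pf.VesselSegment(0, 0, 1, diameter, length)
    return pf.assign_boundaries(
        net, pf.BoundaryPolicy(p_in=p_in, p_out=p_out, inlet_po2=inlet_po2)
    )


def make_y(d_stem=8.0, d_branch=7.0, p_in=17.0, p_out=15.0):
    """One inlet feeding two geometrically identical branches."""
    net = pf.VesselNetwork(provenance="fixture:y")
    net.nodes[0] = pf.VesselNode(0, [0.0, 0.0, 0.0])
    net.nodes[1] = pf.VesselNode(1, [50.0, 0.0, 0.0])
    net.nodes[2] = pf.VesselNode(2, [100.0, 30.0, 0.0])
    net.nodes[3] = pf.VesselNode(3, [100.0, -30.0, 0.0])
    blen = float(np.hypot(50.0, 30.0))
    net.segments[0] = pf.VesselSegment(0, 0, 1, d_stem, 50.0)
    net.segments[1] = pf.VesselSegment(1, 1, 2, d_branch, blen)
    net.segments[2] = pf.VesselSegment(2, 1, 3, d_branch, blen)
    return pf.assign_boundaries(net, pf.BoundaryPolicy(p_in=p_in, p_out=p_out, inlet_po2=60.0))


def make_mini_lattice(seed=7):
    """~20-segment pruned mini-plexus with thick, FD-resolvable vessels."""
    spec = pf.PlexusSpec(
        field_size=(90.0, 90.0), lattice_pitch=40.0, jitter_sd=4.0,
        prune_fraction=0.1, n_inlets=2, n_outlets=2, seed=seed,
        mean_diameter=8.0, diameter_cv=0.1,
    )
    return pf.generate_plexus(spec)


def make_grid_lattice(pitch=50.0, field=581.0):
    """Square lattice: interior columns/rows at multiples of pitch, spanning rails.

    Vertical vessels sit at x = pitch, 2·pitch, … strictly inside the field
    (⌊field/pitch⌋ of them); horizontal vessels span the full field width.
    """
    net = pf.VesselNetwork(provenance="fixture:grid")
    n_inner = int(field // pitch)  # 11 for the 50/581 defaults
    xs = [pitch * (i + 1) for i in range(n_inner)]
    ys = [pitch * (j + 1) for j in range(n_inner)]
    nid = 0
    ids = {}
    for x in [0.0] + xs + [field]:
        for y in [0.0] + ys + [field]:
            net.nodes[nid] = pf.VesselNode(nid, [x, y, 0.0])
            ids[(x, y)] = nid
            nid += 1
    sid = 0
    xs_all = [0.0] + xs + [field]
    ys_all = [0.0] + ys + [field]
    for xi in range(len(xs_all) - 1):
        for y in ys:  # horizontal vessels along interior rows only
            a, b = ids[(xs_all[xi], y)], ids[(xs_all[xi + 1], y)]
            net.segments[sid] = pf.VesselSegment(sid, a, b, 6.0, xs_all[xi + 1] - xs_all[xi])
            sid += 1
    for x in xs:  # vertical vessels along interior columns, full span
        for yi in range(len(ys_all) - 1):
            a, b = ids[(x, ys_all[yi])], ids[(x, ys_all[yi + 1])]
            net.segments[sid] = pf.VesselSegment(sid, a, b, 6.0, ys_all[yi + 1] - ys_all[yi])
            sid += 1
    # drop corner nodes never referenced
    used = {s.node_a for s in net.segments.values()} | {s.node_b for s in net.segments.values()}
    net.nodes = {k: v for k, v in net.nodes.items() if k in used}
    return net


@pytest.fixture
def tube():
    return make_tube()


@pytest.fixture
def y_network():
    return make_y()


@pytest.fixture(scope="session")
def constant_hemo():
    return pf.HemoParams(plasma_viscosity=1.0, viscosity_law="constant", p_in=17, p_out=15)


@pytest.fixture(scope="session")
def oracle_oxy_params():
    return pf.OxyParams(m0=1e-3, element_len=10.0, tissue_spacing=4.0, tissue_margin=15.0)


@pytest.fixture(scope="session")
def oracle_solves(constant_hemo, oracle_oxy_params):
    """Green's + FD solutions on the three oracle fixtures (shared, expensive)."""
    from plexflow.fdref import fd_reference_solver

    out = {}
    for name, net0 in (
        ("tube", make_tube(length=100.0, diameter=8.0, p_in=17.0, p_out=15.0)),
        ("y", make_y()),
        ("lattice", make_mini_lattice()),
    ):
        net = pf.resample_segments(net0, oracle_oxy_params.element_len)
        flow = pf.solve_flow(net, constant_hemo)

        def sleeve(pts, n=net):
            return seg_axis_distance(n, pts) <= 20.0

        greens = pf.solve_oxygen(net, flow, oracle_oxy_params, tissue_mask=sleeve)
        fd = fd_reference_solver(net, flow, oracle_oxy_params, grid_spacing=2.0, consume_mask=sleeve)
        out[name] = (net, flow, greens, fd)
    return out
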