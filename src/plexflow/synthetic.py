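"""Seeded generator of deep-plexus-like capillary networks.

The retinal deep vascular plexus is a quasi-planar capillary mesh. The
generator emulates the two statistical features the flow/oxygen analysis
consumes — the diameter distribution and the spatial density of vessels —
as a perturbed planar lattice: grid nodes jittered in-plane, per-edge
log-normal diameters, random edge pruning with connectivity protection, and
short boundary stubs on two opposite faces acting as arteriolar inlets and
venular outlets. A *diabetic* preset narrows every diameter by a scale
factor and prunes more edges, mirroring early capillary vasoconstriction
and sparsification; both knobs are configurable.

Randomness: numpy PCG64 (``numpy.random.default_rng``) with three named
streams derived from the spec seed — jitter, diameters, pruning — so output
is bit-stable across platforms, and the diameter draw of a given grid edge
does not depend on the prune fraction (presets differing only in
``diameter_scale`` produce exactly proportional diameters).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .network import (
    BoundaryPolicy,
    VesselNetwork,
    VesselNode,
    VesselSegment,
    assign_boundaries,
)

logger = logging.getLogger(__name__)


class PlexusSpec(BaseModel):
    """Parameters of one synthetic deep-plexus network.

    Defaults emulate a healthy deep plexus over a 581 × 581 μm confocal
    field of view: ~55 μm inter-capillary pitch, mean diameter 5.5 μm with
    15% coefficient of variation, 10% of edges pruned.
    """

    field_size: tuple[float, float] = (581.0, 581.0)  # μm
    slab_thickness: float = Field(default=10.0, gt=0)  # μm
    lattice_pitch: float = Field(default=55.0, gt=0)  # μm
    jitter_sd: float = Field(default=8.0, ge=0)  # μm
    mean_diameter: float = Field(default=5.5, gt=0)  # μm
    diameter_cv: float = Field(default=0.15, ge=0)
    prune_fraction: float = Field(default=0.10, ge=0, lt=1)
    diameter_scale: float = Field(default=1.0, gt=0)
    n_inlets: int = Field(default=3, ge=1)
    n_outlets: int = Field(default=3, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _jitter_vs_pitch(self) -> "PlexusSpec":
        if not self.lattice_pitch > 2 * self.jitter_sd:
            raise ValueError("lattice_pitch must exceed 2·jitter_sd")
        return self


def healthy_spec(seed: int = 0, **overrides) -> PlexusSpec:
    return PlexusSpec(seed=seed, **overrides)


def diabetic_spec(seed: int = 0, **overrides) -> PlexusSpec:
    """Diabetic preset: subtle capillary narrowing (×0.9) + sparser mesh (25% pruned)."""
    overrides.setdefault("diameter_scale", 0.9)
    overrides.setdefault("prune_fraction", 0.25)
    return PlexusSpec(seed=seed, **overrides)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Moment-matched (μ, σ) of a log-normal with given arithmetic mean and CV."""
    sigma2 = np.log1p(cv**2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def generate_plexus(spec: PlexusSpec, boundary_policy: BoundaryPolicy | None = None) -> VesselNetwork:
    """Generate one seeded plexus; bit-identical for identical spec."""
    pitch = spec.lattice_pitch
    nx_cols = int(np.floor(spec.field_size[0] / pitch)) + 1
    ny_rows = int(np.floor(spec.field_size[1] / pitch)) + 1
    if nx_cols < 2 or ny_rows < 2:
        raise ConfigurationError("field too small for the lattice pitch")
    x0 = (spec.field_size[0] - (nx_cols - 1) * pitch) / 2.0
    y0 = (spec.field_size[1] - (ny_rows - 1) * pitch) / 2.0

    rng_jitter = np.random.default_rng([spec.seed, 0])
    rng_diam = np.random.default_rng([spec.seed, 1])
    rng_prune = np.random.default_rng([spec.seed, 2])

    # jitter clipped so lattice nodes never reach the boundary-stub faces
    clip = min(3.0 * spec.jitter_sd, pitch / 2.0 - 2.0) if spec.jitter_sd > 0 else 0.0
    z_mid = spec.slab_thickness / 2.0

    net = VesselNetwork(provenance=f"synthetic:{spec.model_dump_json()}")
    node_id = {}
    nid = 0
    for i in range(nx_cols):
        for j in range(ny_rows):
            if spec.jitter_sd > 0:
                jx, jy = np.clip(rng_jitter.normal(0.0, spec.jitter_sd, size=2), -clip, clip)
                jz = float(np.clip(rng_jitter.normal(0.0, spec.slab_thickness / 8.0),
                                   -0.45 * spec.slab_thickness, 0.45 * spec.slab_thickness))
            else:
                jx = jy = jz = 0.0
            pos = np.array([x0 + i * pitch + jx, y0 + j * pitch + jy, z_mid + jz])
            net.nodes[nid] = VesselNode(nid, pos)
            node_id[(i, j)] = nid
            nid += 1

    # fixed edge enumeration: all horizontal, then all vertical
    grid_edges: list[tuple[int, int]] = []
    for i in range(nx_cols - 1):
        for j in range(ny_rows):
            grid_edges.append((node_id[(i, j)], node_id[(i + 1, j)]))
    for i in range(nx_cols):
        for j in range(ny_rows - 1):
            grid_edges.append((node_id[(i, j)], node_id[(i, j + 1)]))

    mu, sigma = _lognormal_params(spec.mean_diameter, spec.diameter_cv)
    diam = np.exp(mu + sigma * rng_diam.standard_normal(len(grid_edges)))
    diam *= spec.diameter_scale

    # boundary stubs: evenly spaced rows on the two x faces
    def _stub_rows(count: int) -> list[int]:
        return sorted({int(round(r)) for r in np.linspace(0, ny_rows - 1, count)})

    stub_edges: list[tuple[int, int]] = []
    stub_count = len(_stub_rows(spec.n_inlets)) + len(_stub_rows(spec.n_outlets))
    stub_diam = np.exp(mu + sigma * rng_diam.standard_normal(stub_count)) * spec.diameter_scale
    k = 0
    for j in _stub_rows(spec.n_inlets):
        anchor = node_id[(0, j)]
        pos = net.nodes[anchor].position.copy()
        tip = np.array([x0 - pitch / 2.0, pos[1], pos[2]])
        net.nodes[nid] = VesselNode(nid, tip)
        stub_edges.append((nid, anchor))
        nid += 1
        k += 1
    for j in _stub_rows(spec.n_outlets):
        anchor = node_id[(nx_cols - 1, j)]
        pos = net.nodes[anchor].position.copy()
        tip = np.array([x0 + (nx_cols - 1) * pitch + pitch / 2.0, pos[1], pos[2]])
        net.nodes[nid] = VesselNode(nid, tip)
        stub_edges.append((nid, anchor))
        nid += 1

    # prune grid edges, protecting inlet–outlet connectivity
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for a, b in grid_edges:
        g.add_edge(a, b)
    for a, b in stub_edges:
        g.add_edge(a, b)
    source, sink = -1, -2
    g.add_edge(source, stub_edges[0][0])
    for idx, (tip, _) in enumerate(stub_edges):
        if idx < len(_stub_rows(spec.n_inlets)):
            g.add_edge(source, tip)
        else:
            g.add_edge(sink, tip)
    target = int(round(spec.prune_fraction * len(grid_edges)))
    removed: set[int] = set()
    for edge_idx in rng_prune.permutation(len(grid_edges)):
        if len(removed) >= target:
            break
        a, b = grid_edges[edge_idx]
        g.remove_edge(a, b)
        if nx.has_path(g, source, sink):
            removed.add(int(edge_idx))
        else:
            g.add_edge(a, b)
    if len(removed) < target:
        logger.warning(
            "pruning stopped at %d/%d edges to preserve inlet–outlet connectivity",
            len(removed), target,
        )

    sid = 0
    for idx, (a, b) in enumerate(grid_edges):
        if idx in removed:
            continue
        pa, pb = net.nodes[a].position, net.nodes[b].position
        net.segments[sid] = VesselSegment(sid, a, b, float(diam[idx]),
                                          float(np.linalg.norm(pb - pa)))
        sid += 1
    for idx, (a, b) in enumerate(stub_edges):
        pa, pb = net.nodes[a].position, net.nodes[b].position
        net.segments[sid] = VesselSegment(sid, a, b, float(stub_diam[idx]),
                                          float(np.linalg.norm(pb - pa)))
        sid += 1

    # drop nodes isolated by pruning
    used = {seg.node_a for seg in net.segments.values()} | {
        seg.node_b for seg in net.segments.values()
    }
    net.nodes = {n: v for n, v in net.nodes.items() if n in used}

    net = assign_boundaries(net, boundary_policy)
    net.validate(require_boundaries=True)
    return net


class GroupDesign(BaseModel):
    """Labelled groups of plexus specs with per-network seeds.

    ``paired=False`` (default): seeds run consecutively across groups,
    seed_i = base_seed + i. ``paired=True``: every group reuses seeds
    base_seed … base_seed+n−1, so groups differing only in their spec are
    compared on common random numbers (and identical specs give identical
    groups).
    """

    groups: list[tuple[str, PlexusSpec, int]]
    base_seed: int = 0
    paired: bool = False

    @model_validator(mode="after")
    def _check(self) -> "GroupDesign":
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if any(g[2] < 1 for g in self.groups):
            raise ValueError("n_networks must be >= 1 in every group")
        return self

    def network_seeds(self) -> list[tuple[str, PlexusSpec, int]]:
        """(label, spec-with-seed, seed) per network, in design order."""
        out = []
        i = 0
        for label, spec, n in self.groups:
            if self.paired:
                i = 0
            for _ in range(n):
                seed = self.base_seed + i
                out.append((label, spec.model_copy(update={"seed": seed}), seed))
                i += 1
        return out


def make_group_design(
    healthy: PlexusSpec | None = None,
    diabetic: PlexusSpec | None = None,
    n_per_group: int = 6,
    base_seed: int = 0,
) -> GroupDesign:
    """Two-group design: healthy seeds first, then diabetic, consecutively."""
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    return GroupDesign(
        groups=[
            ("healthy", healthy or healthy_spec(), n_per_group),
            ("diabetic", diabetic or diabetic_spec(), n_per_group),
        ],
        base_seed=base_seed,
    )


def generate_design(design: GroupDesign) -> list[tuple[str, VesselNetwork]]:
    """Materialize every network of a design, in design order."""
    return [(label, generate_plexus(spec)) for label, spec, _ in design.network_seeds()]
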