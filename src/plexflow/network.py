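"""Vascular skeleton data model.

A capillary network is a geometric graph: nodes are 3-D points (μm) and
segments are tubes with a diameter and an arc length, optionally carrying a
polyline centerline. Boundary conditions (inlet/outlet pressures, inlet PO₂)
are annotations on degree-1 nodes.

Units: lengths and coordinates in μm, pressures and PO₂ in mmHg.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, GeometryError, ReferentialIntegrityError

logger = logging.getLogger(__name__)

#: Euclidean node-merge tolerance, μm. Below the in-plane voxel size of the
#: confocal stacks this model ingests (0.568 μm), so merged points are
#: sub-resolution.
MERGE_TOLERANCE = 0.5

#: Relative slack allowed on the L >= euclidean-distance invariant.
_LENGTH_RTOL = 1e-6


class BoundaryKind(str, Enum):
    INTERIOR = "interior"
    INLET = "inlet"
    OUTLET = "outlet"


@dataclass
class VesselNode:
    node_id: int
    position: np.ndarray  # shape (3,), μm
    boundary_kind: BoundaryKind = BoundaryKind.INTERIOR
    boundary_pressure: float | None = None  # mmHg, present iff not interior
    boundary_po2: float | None = None  # mmHg, inlets only

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise GeometryError(f"node {self.node_id}: non-finite position")


@dataclass
class VesselSegment:
    segment_id: int
    node_a: int
    node_b: int
    diameter: float  # μm
    length: float  # μm (arc length; >= chord length)
    polyline: np.ndarray | None = None  # (k, 3) centerline detail, μm

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise GeometryError(
                f"segment {self.segment_id}: self-loop on node {self.node_a}"
            )
        if not self.diameter > 0:
            raise GeometryError(
                f"segment {self.segment_id}: diameter must be > 0, got {self.diameter}"
            )
        if not self.length > 0:
            raise GeometryError(
                f"segment {self.segment_id}: length must be > 0, got {self.length}"
            )
        if self.polyline is not None:
            self.polyline = np.asarray(self.polyline, dtype=float)

    @property
    def volume(self) -> float:
        """Luminal volume π d² L / 4 in μm³."""
        return np.pi * self.diameter**2 * self.length / 4.0


@dataclass
class VesselNetwork:
    nodes: dict[int, VesselNode] = field(default_factory=dict)
    segments: dict[int, VesselSegment] = field(default_factory=dict)
    provenance: str = ""

    # ------------------------------------------------------------------ basics
    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pos = self.node_positions()
        return pos.min(axis=0), pos.max(axis=0)

    def node_positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nodes.values()])

    def node_ids(self) -> list[int]:
        return list(self.nodes)

    def degrees(self) -> dict[int, int]:
        deg = {nid: 0 for nid in self.nodes}
        for seg in self.segments.values():
            deg[seg.node_a] += 1
            deg[seg.node_b] += 1
        return deg

    def boundary_nodes(self, kind: BoundaryKind) -> list[int]:
        return [n.node_id for n in self.nodes.values() if n.boundary_kind == kind]

    @property
    def total_length(self) -> float:
        return sum(s.length for s in self.segments.values())

    @property
    def total_volume(self) -> float:
        return sum(s.volume for s in self.segments.values())

    def to_graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for seg in self.segments.values():
            g.add_edge(seg.node_a, seg.node_b, key=seg.segment_id)
        return g

    def copy(self) -> "VesselNetwork":
        return _copy.deepcopy(self)

    # -------------------------------------------------------------- validation
    def validate(self, require_boundaries: bool = False) -> None:
        """Check structural invariants; raise on violation.

        With ``require_boundaries`` the network must carry at least one inlet
        and one outlet (precondition of the flow solver).
        """
        if not self.nodes:
            raise ReferentialIntegrityError("network has no nodes")
        for seg in self.segments.values():
            for end in (seg.node_a, seg.node_b):
                if end not in self.nodes:
                    raise ReferentialIntegrityError(
                        f"segment {seg.segment_id} references missing node {end}"
                    )
            chord = float(
                np.linalg.norm(
                    self.nodes[seg.node_a].position - self.nodes[seg.node_b].position
                )
            )
            if seg.length < chord * (1.0 - _LENGTH_RTOL):
                raise GeometryError(
                    f"segment {seg.segment_id}: length {seg.length} < chord {chord}"
                )
        for node in self.nodes.values():
            interior = node.boundary_kind == BoundaryKind.INTERIOR
            if interior and node.boundary_pressure is not None:
                raise ConfigurationError(
                    f"interior node {node.node_id} carries a boundary pressure"
                )
            if not interior and node.boundary_pressure is None:
                raise ConfigurationError(
                    f"{node.boundary_kind.value} node {node.node_id} lacks a pressure"
                )
            if node.boundary_po2 is not None and node.boundary_kind != BoundaryKind.INLET:
                raise ConfigurationError(
                    f"node {node.node_id}: boundary_po2 allowed on inlets only"
                )
        if len(self.nodes) > 1:
            tree = cKDTree(self.node_positions())
            pairs = tree.query_pairs(MERGE_TOLERANCE)
            if pairs:
                ids = self.node_ids()
                i, j = next(iter(pairs))
                raise GeometryError(
                    f"nodes {ids[i]} and {ids[j]} coincide within the merge "
                    f"tolerance ({MERGE_TOLERANCE} μm) but were not merged"
                )
        if require_boundaries:
            if not self.boundary_nodes(BoundaryKind.INLET):
                raise ConfigurationError("network has no inlet")
            if not self.boundary_nodes(BoundaryKind.OUTLET):
                raise ConfigurationError("network has no outlet")


# ---------------------------------------------------------------------------
# Boundary assignment
# ---------------------------------------------------------------------------


@dataclass
class BoundaryPolicy:
    """Geometric inlet/outlet assignment with per-node overrides.

    Degree-1 nodes lying within ``face_tol`` of the bounding-box face at the
    low end of ``axis`` become inlets at ``p_in``; the opposite face becomes
    outlets at ``p_out``. The retina papers this model serves do not state
    their boundary conditions, so this is an explicit modelling choice and is
    echoed into every report.
    """

    axis: int = 0  # 0=x, 1=y, 2=z
    p_in: float = 45.0  # mmHg
    p_out: float = 15.0  # mmHg
    inlet_po2: float = 60.0  # mmHg
    face_tol: float = 1.0  # μm
    #: node_id -> (kind, pressure, po2-or-None); applied after the geometric rule
    overrides: Mapping[int, tuple[BoundaryKind, float, float | None]] = field(
        default_factory=dict
    )


def assign_boundaries(net: VesselNetwork, policy: BoundaryPolicy | None = None) -> VesselNetwork:
    """Return a copy of ``net`` with inlet/outlet annotations per ``policy``."""
    policy = policy or BoundaryPolicy()
    out = net.copy()
    deg = out.degrees()
    if not any(d == 1 for d in deg.values()) and not policy.overrides:
        raise ConfigurationError("network has no degree-1 node to act as boundary")
    lo, hi = out.bounding_box
    for node in out.nodes.values():
        node.boundary_kind = BoundaryKind.INTERIOR
        node.boundary_pressure = None
        node.boundary_po2 = None
        if deg[node.node_id] != 1:
            continue
        c = node.position[policy.axis]
        if c <= lo[policy.axis] + policy.face_tol:
            node.boundary_kind = BoundaryKind.INLET
            node.boundary_pressure = policy.p_in
            node.boundary_po2 = policy.inlet_po2
        elif c >= hi[policy.axis] - policy.face_tol:
            node.boundary_kind = BoundaryKind.OUTLET
            node.boundary_pressure = policy.p_out
    for nid, (kind, pressure, po2) in policy.overrides.items():
        if nid not in out.nodes:
            raise ReferentialIntegrityError(f"override references missing node {nid}")
        node = out.nodes[nid]
        node.boundary_kind = BoundaryKind(kind)
        node.boundary_pressure = pressure if node.boundary_kind != BoundaryKind.INTERIOR else None
        node.boundary_po2 = po2 if node.boundary_kind == BoundaryKind.INLET else None
    if not out.boundary_nodes(BoundaryKind.INLET):
        raise ConfigurationError("boundary policy produced no inlets")
    if not out.boundary_nodes(BoundaryKind.OUTLET):
        raise ConfigurationError("boundary policy produced no outlets")
    return out


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length of a polyline, starting at 0."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate(([0.0], np.cumsum(steps)))


def _cut_polyline(points: np.ndarray, n_pieces: int) -> list[np.ndarray]:
    """Split a polyline into n_pieces of equal arc length, inserting cut points."""
    arc = _polyline_arclength(points)
    total = arc[-1]
    pieces: list[np.ndarray] = []
    start_pt = points[0]
    start_arc = 0.0
    idx = 0  # index of last original vertex at or before the cursor
    for k in range(1, n_pieces + 1):
        target = total * k / n_pieces
        piece = [start_pt]
        while idx + 1 < len(points) and arc[idx + 1] < target - 1e-12 * max(total, 1.0):
            idx += 1
            piece.append(points[idx])
        if k == n_pieces:
            end_pt = points[-1]
            if not np.allclose(piece[-1], end_pt):
                piece.append(end_pt)
        else:
            span = arc[idx + 1] - arc[idx]
            frac = 0.0 if span == 0 else (target - arc[idx]) / span
            end_pt = points[idx] + frac * (points[idx + 1] - points[idx])
            piece.append(end_pt)
        pieces.append(np.array(piece))
        start_pt = end_pt
        start_arc = target
    return pieces


def resample_segments(net: VesselNetwork, max_element_len: float) -> VesselNetwork:
    """Subdivide segments in series so every segment has length <= max_element_len.

    Total length and luminal volume are conserved (each segment is cut into
    equal-arc-length pieces inheriting its diameter); flow topology is
    unchanged. Needed to discretize vessels for the oxygen solver.
    """
    if not max_element_len > 0:
        raise ConfigurationError("max_element_len must be > 0")
    out = VesselNetwork(provenance=net.provenance)
    out.nodes = {nid: _copy.deepcopy(n) for nid, n in net.nodes.items()}
    next_node = max(net.nodes) + 1 if net.nodes else 0
    next_seg = 0
    for seg in sorted(net.segments.values(), key=lambda s: s.segment_id):
        n_pieces = max(1, int(np.ceil(seg.length / max_element_len - 1e-12)))
        if n_pieces == 1:
            out.segments[next_seg] = VesselSegment(
                next_seg, seg.node_a, seg.node_b, seg.diameter, seg.length,
                None if seg.polyline is None else seg.polyline.copy(),
            )
            next_seg += 1
            continue
        if seg.polyline is not None:
            pieces = _cut_polyline(seg.polyline, n_pieces)
        else:
            a = net.nodes[seg.node_a].position
            b = net.nodes[seg.node_b].position
            ts = np.linspace(0.0, 1.0, n_pieces + 1)
            pts = a[None, :] + ts[:, None] * (b - a)[None, :]
            pieces = [pts[i : i + 2] for i in range(n_pieces)]
        chain = [seg.node_a]
        for pc in pieces[:-1]:
            out.nodes[next_node] = VesselNode(next_node, pc[-1])
            chain.append(next_node)
            next_node += 1
        chain.append(seg.node_b)
        piece_len = seg.length / n_pieces
        for i, pc in enumerate(pieces):
            out.segments[next_seg] = VesselSegment(
                next_seg, chain[i], chain[i + 1], seg.diameter, piece_len, pc
            )
            next_seg += 1
    return out
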