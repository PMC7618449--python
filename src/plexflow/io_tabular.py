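"""Plain tabular (CSV) network format.

Two files describe a network:

``nodes.csv``
    columns ``node_id,x,y,z,boundary_kind,boundary_pressure,boundary_po2``
``segments.csv``
    columns ``segment_id,node_a,node_b,diameter,length``

Boundary fields are empty for interior nodes. The documented columns
round-trip bit-exactly through :func:`write_tabular` / :func:`read_tabular`
(polyline centerline detail is not part of the tabular format and is dropped).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ReferentialIntegrityError
from .network import BoundaryKind, VesselNetwork, VesselNode, VesselSegment

NODE_COLUMNS = ["node_id", "x", "y", "z", "boundary_kind", "boundary_pressure", "boundary_po2"]
SEGMENT_COLUMNS = ["segment_id", "node_a", "node_b", "diameter", "length"]


def network_to_frames(net: VesselNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        [
            {
                "node_id": n.node_id,
                "x": n.position[0],
                "y": n.position[1],
                "z": n.position[2],
                "boundary_kind": n.boundary_kind.value,
                "boundary_pressure": n.boundary_pressure,
                "boundary_po2": n.boundary_po2,
            }
            for n in sorted(net.nodes.values(), key=lambda n: n.node_id)
        ],
        columns=NODE_COLUMNS,
    )
    segments = pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "node_a": s.node_a,
                "node_b": s.node_b,
                "diameter": s.diameter,
                "length": s.length,
            }
            for s in sorted(net.segments.values(), key=lambda s: s.segment_id)
        ],
        columns=SEGMENT_COLUMNS,
    )
    return nodes, segments


def write_tabular(net: VesselNetwork, nodes_path: str | Path, segments_path: str | Path) -> None:
    nodes, segments = network_to_frames(net)
    nodes.to_csv(nodes_path, index=False)
    segments.to_csv(segments_path, index=False)


def read_tabular(nodes_path: str | Path, segments_path: str | Path) -> VesselNetwork:
    """Load a network from the documented CSV pair.

    Raises :class:`FormatError` on missing columns and
    :class:`ReferentialIntegrityError` when a segment references an absent
    node.
    """
    nodes_df = pd.read_csv(nodes_path, float_precision="round_trip")
    segs_df = pd.read_csv(segments_path, float_precision="round_trip")
    for df, cols, path in ((nodes_df, NODE_COLUMNS, nodes_path), (segs_df, SEGMENT_COLUMNS, segments_path)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
    net = VesselNetwork(provenance=f"tabular:{Path(nodes_path).name}")
    for row in nodes_df.itertuples(index=False):
        net.nodes[int(row.node_id)] = VesselNode(
            int(row.node_id),
            np.array([row.x, row.y, row.z], dtype=float),
            BoundaryKind(row.boundary_kind),
            None if pd.isna(row.boundary_pressure) else float(row.boundary_pressure),
            None if pd.isna(row.boundary_po2) else float(row.boundary_po2),
        )
    for row in segs_df.itertuples(index=False):
        na, nb = int(row.node_a), int(row.node_b)
        for end in (na, nb):
            if end not in net.nodes:
                raise ReferentialIntegrityError(
                    f"segment {int(row.segment_id)} references missing node {end}"
                )
        net.segments[int(row.segment_id)] = VesselSegment(
            int(row.segment_id), na, nb, float(row.diameter), float(row.length)
        )
    return net
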