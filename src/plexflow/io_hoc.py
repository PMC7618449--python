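"""Reader for NEURON-style ``.hoc`` vascular skeletons.

Imaris filament exports describe each vessel branch as a hoc *section*: a
``create`` declaration, a ``{ ... }`` block of ``pt3dadd(x, y, z, d)`` points,
and optional ``connect child(end), parent(end)`` statements. Only this
dialect is supported; unknown statements are ignored with a logged warning,
since exports vary between Imaris versions and being permissive (while
surfacing drift in the log) maximizes ingest success.

Sections become :class:`~plexflow.network.VesselSegment` objects with

* ``length`` = summed polyline chord length,
* ``diameter`` = length-weighted mean of the per-point diameters (robust to
  endpoint taper artifacts),

and section endpoints are fused into shared nodes via ``connect`` statements
plus coincidence within the 0.5 μm merge tolerance.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, FormatError, GeometryError
from .network import MERGE_TOLERANCE, VesselNetwork, VesselNode, VesselSegment

logger = logging.getLogger(__name__)

_CREATE_RE = re.compile(r"^\s*create\s+(.+?)\s*$")
_CONNECT_RE = re.compile(
    r"^\s*connect\s+([\w\[\]]+)\s*\(\s*([01])\s*\)\s*,\s*([\w\[\]]+)\s*\(\s*([01])\s*\)\s*$"
)
_BLOCK_OPEN_RE = re.compile(r"^\s*([\w\[\]]+)\s*\{(.*)$")
_CALL_RE = re.compile(r"([A-Za-z_]\w*)\s*\(([^)]*)\)")


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _parse_block_content(
    content: str,
    lineno: int,
    section: str,
    points: list[tuple[float, float, float, float]],
) -> None:
    """Parse statements inside a section block (a single line's worth)."""
    consumed = np.zeros(len(content), dtype=bool)
    for m in _CALL_RE.finditer(content):
        consumed[m.start() : m.end()] = True
        name, args = m.group(1), m.group(2)
        if name == "pt3dadd":
            parts = [a.strip() for a in args.split(",")] if args.strip() else []
            if len(parts) != 4:
                raise FormatError(
                    f"pt3dadd expects 4 arguments (x, y, z, d), got {len(parts)}",
                    line=lineno,
                )
            try:
                x, y, z, d = (float(p) for p in parts)
            except ValueError as exc:
                raise FormatError(f"non-numeric pt3dadd argument: {exc}", line=lineno)
            points.append((x, y, z, d))
        else:
            logger.warning(
                "hoc line %d: ignoring unsupported statement %r in section %s",
                lineno, f"{name}({args})", section,
            )
    leftover = "".join(
        ch for i, ch in enumerate(content) if not consumed[i]
    ).strip()
    if leftover:
        logger.warning(
            "hoc line %d: ignoring unrecognized text %r in section %s",
            lineno, leftover, section,
        )


def read_hoc(path: str | Path) -> VesselNetwork:
    """Parse a ``.hoc`` skeleton into a :class:`VesselNetwork`.

    Raises :class:`FormatError` (with the offending line number) on malformed
    statements, :class:`GeometryError` for sections with fewer than two
    points, and :class:`EmptyInputError` when the file declares no usable
    section. All nodes start as *interior*; call
    :func:`plexflow.network.assign_boundaries` before flow solving.
    """
    path = Path(path)
    text = path.read_text()
    declared: list[str] = []
    points: dict[str, list[tuple[float, float, float, float]]] = {}
    connects: list[tuple[str, int, str, int]] = []
    in_block: str | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//")[0]
        while line.strip():
            if in_block is not None:
                brace = line.find("}")
                content = line if brace < 0 else line[:brace]
                _parse_block_content(content, lineno, in_block, points[in_block])
                if brace < 0:
                    line = ""
                else:
                    in_block = None
                    line = line[brace + 1 :]
                continue
            m = _CREATE_RE.match(line)
            if m:
                for name in (n.strip() for n in m.group(1).split(",")):
                    if name:
                        declared.append(name)
                        points.setdefault(name, [])
                line = ""
                continue
            m = _CONNECT_RE.match(line)
            if m:
                child, c_end, parent, p_end = (
                    m.group(1), int(m.group(2)), m.group(3), int(m.group(4)),
                )
                connects.append((child, c_end, parent, p_end))
                line = ""
                continue
            m = _BLOCK_OPEN_RE.match(line)
            if m:
                name = m.group(1)
                if name not in points:
                    logger.warning(
                        "hoc line %d: section %s was not declared with create",
                        lineno, name,
                    )
                    declared.append(name)
                    points.setdefault(name, [])
                in_block = name
                line = m.group(2)
                continue
            logger.warning("hoc line %d: ignoring unrecognized line %r", lineno, line.strip())
            line = ""

    if in_block is not None:
        raise FormatError(f"unterminated block for section {in_block}")

    sections = []
    for name in declared:
        pts = points.get(name, [])
        if not pts:
            logger.warning("hoc: section %s has no pt3dadd points; skipped", name)
            continue
        if len(pts) < 2:
            raise GeometryError(f"section {name} has fewer than 2 points")
        sections.append(name)
    if not sections:
        raise EmptyInputError(f"{path}: no sections with geometry found")

    # --- fuse section endpoints into nodes -------------------------------
    uf = _UnionFind()
    known = set(sections)
    for child, c_end, parent, p_end in connects:
        if child in known and parent in known:
            uf.union((parent, p_end), (child, c_end))
        else:
            logger.warning(
                "hoc: connect references unknown section (%s or %s); ignored",
                child, parent,
            )
    end_keys = [(s, e) for s in sections for e in (0, 1)]
    end_pos = np.array(
        [points[s][0 if e == 0 else -1][:3] for s, e in end_keys]
    )
    tree = cKDTree(end_pos)
    for i, j in sorted(tree.query_pairs(MERGE_TOLERANCE)):
        uf.union(end_keys[i], end_keys[j])

    clusters: dict = {}
    for key in end_keys:
        clusters.setdefault(uf.find(key), []).append(key)
    node_of_end: dict[tuple[str, int], int] = {}
    net = VesselNetwork(provenance=f"hoc:{path.name}")
    for nid, (_, members) in enumerate(sorted(
        clusters.items(), key=lambda kv: min(sections.index(s) * 2 + e for s, e in kv[1])
    )):
        pos = np.mean(
            [points[s][0 if e == 0 else -1][:3] for s, e in members], axis=0
        )
        net.nodes[nid] = VesselNode(nid, pos)
        for key in members:
            node_of_end[key] = nid

    for sid, name in enumerate(sections):
        pts = np.array(points[name], dtype=float)
        xyz, dia = pts[:, :3], pts[:, 3]
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        length = float(steps.sum())
        if length <= 0:
            raise GeometryError(f"section {name} has zero length")
        # length-weighted (trapezoidal) mean of per-point diameters
        diameter = float(np.sum(steps * (dia[:-1] + dia[1:]) / 2.0) / length)
        na, nb = node_of_end[(name, 0)], node_of_end[(name, 1)]
        if na == nb:
            raise GeometryError(
                f"section {name}: endpoints merged into the same node (loop)"
            )
        # merged-node averaging can move endpoints sub-resolution; keep the
        # arc-length >= chord invariant intact
        chord = float(np.linalg.norm(net.nodes[na].position - net.nodes[nb].position))
        net.segments[sid] = VesselSegment(sid, na, nb, diameter, max(length, chord), xyz)
    return net
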