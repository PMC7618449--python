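"""Network data model, hoc ingestion, tabular round trips, resampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import plexflow as pf
from plexflow.errors import (
    ConfigurationError,
    EmptyInputError,
    FormatError,
    GeometryError,
    ReferentialIntegrityError,
)

SINGLE_TUBE_HOC = """\
create seg_1
seg_1 { pt3dadd(0,0,0,6) pt3dadd(60,0,0,6) }
"""

TWO_SECTION_HOC = """\
create seg_1, seg_2
seg_1 { pt3dadd(0,0,0,6) pt3dadd(60,0,0,6) }
seg_2 { pt3dadd(60.0,0.2,0,4) pt3dadd(60,50,0,4) }
"""


class TestReadHoc:
    def test_single_section(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text(SINGLE_TUBE_HOC)
        net = pf.read_hoc(p)
        assert len(net.nodes) == 2
        assert len(net.segments) == 1
        seg = net.segments[0]
        assert seg.diameter == pytest.approx(6.0)
        assert seg.length == pytest.approx(60.0)
        assert all(
            n.boundary_kind == pf.BoundaryKind.INTERIOR for n in net.nodes.values()
        )

    def test_touching_endpoints_merge_into_shared_node(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text(TWO_SECTION_HOC)
        net = pf.read_hoc(p)
        assert len(net.nodes) == 3  # 0.2 μm offset is below the 0.5 μm merge tolerance
        assert len(net.segments) == 2
        shared = set(
            (net.segments[0].node_a, net.segments[0].node_b)
        ) & set((net.segments[1].node_a, net.segments[1].node_b))
        assert len(shared) == 1

    def test_connect_statement_joins_sections(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text(
            "create a\ncreate b\n"
            "a { pt3dadd(0,0,0,6) pt3dadd(60,0,0,6) }\n"
            "b { pt3dadd(65,0,0,4) pt3dadd(65,50,0,4) }\n"  # 5 μm gap: only connect joins
            "connect b(0), a(1)\n"
        )
        net = pf.read_hoc(p)
        assert len(net.nodes) == 3

    def test_wrong_pt3dadd_arity_reports_line(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text("create s\ns { pt3dadd(0,0,0) }\n")
        with pytest.raises(FormatError, match="line 2"):
            pf.read_hoc(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text("\n// nothing here\n")
        with pytest.raises(EmptyInputError):
            pf.read_hoc(p)

    def test_single_point_section_is_invalid_geometry(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text("create s\ns { pt3dadd(0,0,0,6) }\n")
        with pytest.raises(GeometryError):
            pf.read_hoc(p)

    def test_unknown_statements_are_ignored_with_warning(self, tmp_path, caplog):
        p = tmp_path / "net.hoc"
        p.write_text("create s\ns { pt3dclear() pt3dadd(0,0,0,6) pt3dadd(60,0,0,6) }\n")
        with caplog.at_level("WARNING", logger="plexflow.io_hoc"):
            net = pf.read_hoc(p)
        assert len(net.segments) == 1
        assert any("pt3dclear" in r.message for r in caplog.records)

    def test_section_order_permutation_gives_isomorphic_graph(self, tmp_path):
        lines = [
            "a { pt3dadd(0,0,0,6) pt3dadd(60,0,0,6) }",
            "b { pt3dadd(60,0,0,5) pt3dadd(60,60,0,5) }",
            "c { pt3dadd(60,60,0,4) pt3dadd(0,60,0,4) }",
        ]
        header = "create a, b, c\n"
        p1, p2 = tmp_path / "n1.hoc", tmp_path / "n2.hoc"
        p1.write_text(header + "\n".join(lines))
        p2.write_text(header + "\n".join(reversed(lines)))
        n1, n2 = pf.read_hoc(p1), pf.read_hoc(p2)
        assert len(n1.nodes) == len(n2.nodes)
        assert len(n1.segments) == len(n2.segments)
        assert sorted(n1.degrees().values()) == sorted(n2.degrees().values())
        assert n1.total_length == pytest.approx(n2.total_length, rel=1e-12)

    def test_taper_gives_length_weighted_diameter(self, tmp_path):
        p = tmp_path / "net.hoc"
        # 30 μm at d spanning 6->6, then 90 μm at 6->2: trapezoid weighting
        p.write_text(
            "create s\ns { pt3dadd(0,0,0,6) pt3dadd(30,0,0,6) pt3dadd(120,0,0,2) }\n"
        )
        net = pf.read_hoc(p)
        expected = (30 * 6.0 + 90 * 4.0) / 120.0
        assert net.segments[0].diameter == pytest.approx(expected)


class TestTabular:
    def test_hoc_and_tabular_agree_on_single_tube(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text(SINGLE_TUBE_HOC)
        net = pf.read_hoc(p)
        pf.write_tabular(net, tmp_path / "n.nodes.csv", tmp_path / "n.segments.csv")
        back = pf.read_tabular(tmp_path / "n.nodes.csv", tmp_path / "n.segments.csv")
        assert len(back.nodes) == 2 and len(back.segments) == 1
        assert back.segments[0].diameter == pytest.approx(6.0)

    def test_round_trip_is_byte_identical(self, tmp_path):
        net = pf.generate_plexus(pf.healthy_spec(seed=3))
        a_n, a_s = tmp_path / "a.nodes.csv", tmp_path / "a.segments.csv"
        b_n, b_s = tmp_path / "b.nodes.csv", tmp_path / "b.segments.csv"
        pf.write_tabular(net, a_n, a_s)
        pf.write_tabular(pf.read_tabular(a_n, a_s), b_n, b_s)
        assert a_n.read_bytes() == b_n.read_bytes()
        assert a_s.read_bytes() == b_s.read_bytes()

    def test_missing_column_is_format_error(self, tmp_path):
        (tmp_path / "n.csv").write_text("node_id,x,y\n0,0,0\n")
        (tmp_path / "s.csv").write_text("segment_id,node_a,node_b,diameter,length\n")
        with pytest.raises(FormatError, match="missing column"):
            pf.read_tabular(tmp_path / "n.csv", tmp_path / "s.csv")

    def test_dangling_endpoint_is_referential_error(self, tmp_path):
        (tmp_path / "n.csv").write_text(
            "node_id,x,y,z,boundary_kind,boundary_pressure,boundary_po2\n"
            "0,0,0,0,interior,,\n1,60,0,0,interior,,\n"
        )
        (tmp_path / "s.csv").write_text(
            "segment_id,node_a,node_b,diameter,length\n0,0,99,6,60\n"
        )
        with pytest.raises(ReferentialIntegrityError, match="99"):
            pf.read_tabular(tmp_path / "n.csv", tmp_path / "s.csv")


class TestBoundaries:
    def test_geometric_x_face_policy(self, tube):
        inlets = tube.boundary_nodes(pf.BoundaryKind.INLET)
        outlets = tube.boundary_nodes(pf.BoundaryKind.OUTLET)
        assert inlets == [0] and outlets == [1]
        assert tube.nodes[0].boundary_po2 is not None
        tube.validate(require_boundaries=True)

    def test_explicit_override(self):
        net = pf.VesselNetwork()
        net.nodes[4] = pf.VesselNode(4, [0, 0, 0])
        net.nodes[5] = pf.VesselNode(5, [60, 0, 0])
        net.segments[0] = pf.VesselSegment(0, 4, 5, 6.0, 60.0)
        policy = pf.BoundaryPolicy(
            overrides={
                5: (pf.BoundaryKind.INLET, 45.0, 60.0),
                4: (pf.BoundaryKind.OUTLET, 15.0, None),
            }
        )
        out = pf.assign_boundaries(net, policy)
        assert out.nodes[5].boundary_kind == pf.BoundaryKind.INLET
        assert out.nodes[5].boundary_pressure == 45.0

    def test_all_tips_on_one_face_is_configuration_error(self):
        # comb: all degree-1 tips stick out of the low-x face
        net = pf.VesselNetwork()
        nid = 0
        for j in range(3):
            net.nodes[nid] = pf.VesselNode(nid, [0.0, 50.0 * j, 0.0])
            net.nodes[nid + 1] = pf.VesselNode(nid + 1, [60.0, 50.0 * j, 0.0])
            nid += 2
        for j in range(3):
            net.segments[j] = pf.VesselSegment(j, 2 * j, 2 * j + 1, 6.0, 60.0)
        net.segments[3] = pf.VesselSegment(3, 1, 3, 6.0, 50.0)
        net.segments[4] = pf.VesselSegment(4, 3, 5, 6.0, 50.0)
        with pytest.raises(ConfigurationError):
            pf.assign_boundaries(net)


class TestResample:
    def test_equal_subdivision(self, tube):
        out = pf.resample_segments(tube, 25.0)
        assert len(out.segments) == 3
        assert all(s.length == pytest.approx(20.0) for s in out.segments.values())

    def test_identity_when_short_enough(self, tube):
        out = pf.resample_segments(tube, 100.0)
        assert len(out.segments) == 1
        assert out.segments[0].length == pytest.approx(60.0)

    @given(
        lengths=st.lists(st.floats(1.0, 300.0), min_size=1, max_size=6),
        max_len=st.floats(5.0, 80.0),
    )
    def test_length_and_volume_conserved(self, lengths, max_len):
        net = pf.VesselNetwork()
        x = 0.0
        net.nodes[0] = pf.VesselNode(0, [0.0, 0.0, 0.0])
        for i, ln in enumerate(lengths):
            x += ln
            net.nodes[i + 1] = pf.VesselNode(i + 1, [x, 0.0, 0.0])
            net.segments[i] = pf.VesselSegment(i, i, i + 1, 4.0 + i, ln)
        out = pf.resample_segments(net, max_len)
        assert out.total_length == pytest.approx(net.total_length, rel=1e-9)
        assert out.total_volume == pytest.approx(net.total_volume, rel=1e-9)
        assert max(s.length for s in out.segments.values()) <= max_len * (1 + 1e-12)

    def test_polyline_midpoints_follow_centerline(self, tmp_path):
        p = tmp_path / "net.hoc"
        p.write_text(
            "create s\ns { pt3dadd(0,0,0,6) pt3dadd(30,40,0,6) pt3dadd(60,0,0,6) }\n"
        )
        net = pf.read_hoc(p)
        out = pf.resample_segments(net, 30.0)
        assert out.total_length == pytest.approx(100.0, rel=1e-9)
        # subdivision nodes must lie on the original polyline
        for nid, node in out.nodes.items():
            if nid not in net.nodes:
                assert abs(node.position[1] - (node.position[0] * 4 / 3)) < 1e-6 or abs(
                    node.position[1] - ((60 - node.position[0]) * 4 / 3)
                ) < 1e-6


class TestValidate:
    def test_detects_unmerged_coincident_nodes(self):
        net = pf.VesselNetwork()
        net.nodes[0] = pf.VesselNode(0, [0, 0, 0])
        net.nodes[1] = pf.VesselNode(1, [0.1, 0, 0])
        net.nodes[2] = pf.VesselNode(2, [60, 0, 0])
        net.segments[0] = pf.VesselSegment(0, 0, 2, 6.0, 60.0)
        net.segments[1] = pf.VesselSegment(1, 1, 2, 6.0, 60.0)
        with pytest.raises(GeometryError, match="merge"):
            net.validate()

    def test_rejects_length_below_chord(self):
        net = pf.VesselNetwork()
        net.nodes[0] = pf.VesselNode(0, [0, 0, 0])
        net.nodes[1] = pf.VesselNode(1, [60, 0, 0])
        net.segments[0] = pf.VesselSegment(0, 0, 1, 6.0, 50.0)
        with pytest.raises(GeometryError, match="chord"):
            net.validate()
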