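import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortimorph import skeleton_io as sio


def make_tree(tree_id="OHC1_001", positions=((0, 0, 0), (0, 0, 4000)), cls="OHC", row=1):
    t = sio.SkeletonTree(tree_id=tree_id, cell_class=cls, row=row)
    for i, p in enumerate(positions, start=1):
        t.add_node(i, np.array(p, dtype=float))
        if i > 1:
            t.add_edge(i - 1, i)
    return t


class TestNaming:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("OHC2_017", ("OHC", 2, "OHC2_017")),
            ("DC3_012", ("DC", 3, "DC3_012")),
            ("MOC_007", ("MOC", None, "MOC_007")),
            ("T2SGN_040", ("T2SGN", None, "T2SGN_040")),
            ("blob", (None, None, "blob")),
        ],
    )
    def test_grammar(self, name, expected):
        assert sio.parse_tree_name(name) == expected


class TestNml:
    def nml_text(self, edges='<edge source="1" target="2"/>', extra_node=""):
        return f"""<things>
          <parameters><scale x="11" y="11" z="40"/></parameters>
          <thing id="1" name="OHC2_017">
            <nodes><node id="1" x="0" y="0" z="0"/><node id="2" x="0" y="0" z="100"/>{extra_node}</nodes>
            <edges>{edges}</edges>
          </thing>
          <comments><comment node="1" content="landmark:basal_pole"/></comments>
        </things>"""

    def test_read_scales_by_pitch(self, tmp_path):
        p = tmp_path / "a.nml"
        p.write_text(self.nml_text())
        aset = sio.read_nml(p)
        tree = aset.trees["OHC2_017"]
        assert tree.cell_class == "OHC" and tree.row == 2
        # 100 z-voxels at 40 nm pitch = 4000 nm edge
        d = np.linalg.norm(tree.nodes[2].position - tree.nodes[1].position)
        assert d == pytest.approx(4000.0)
        assert tree.landmarks == {"basal_pole": 1}

    def test_dangling_edge_names_node(self, tmp_path):
        p = tmp_path / "a.nml"
        p.write_text(self.nml_text(edges='<edge source="1" target="99"/>'))
        with pytest.raises(sio.ValidationError, match="99"):
            sio.read_nml(p)

    def test_duplicate_node_id(self, tmp_path):
        p = tmp_path / "a.nml"
        p.write_text(self.nml_text(extra_node='<node id="2" x="1" y="1" z="1"/>'))
        with pytest.raises(sio.ValidationError, match="duplicate"):
            sio.read_nml(p)

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "a.nml"
        p.write_text("<things><thing></things>")
        with pytest.raises(sio.ParseError):
            sio.read_nml(p)

    def test_unknown_tree_name_retained(self, tmp_path):
        p = tmp_path / "a.nml"
        p.write_text(self.nml_text().replace("OHC2_017", "mystery"))
        aset = sio.read_nml(p)
        assert aset.trees["mystery"].cell_class is None

    def test_roundtrip_positions_within_half_voxel(self, tmp_path, rng):
        pitch = sio.VoxelPitch(11, 11, 40)
        aset = sio.AnnotationSet(pitch=pitch)
        pos = rng.uniform(0, 50000, size=(100, 3))
        tree = sio.SkeletonTree("T2SGN_000", "T2SGN", None)
        for i, p in enumerate(pos, start=1):
            tree.add_node(i, p)
            if i > 1:
                tree.add_edge(i - 1, i)
        tree.landmarks["turn"] = 5
        aset.add_tree(tree)
        sio.write_annotation(aset, tmp_path / "x.nml", "nml")
        back = sio.read_nml(tmp_path / "x.nml")
        t2 = back.trees["T2SGN_000"]
        assert t2.edges == tree.edges and t2.landmarks == tree.landmarks
        for i in tree.nodes:
            err = np.abs(t2.nodes[i].position - tree.nodes[i].position)
            assert np.all(err <= pitch.as_array() / 2 + 1e-9)


class TestSwc:
    def test_unbranched_three_nodes(self, tmp_path):
        f = tmp_path / "DC1_000.swc"
        f.write_text("# test\n1 0 0 0 0 1.0 -1\n2 0 0 0 5 1.0 1\n3 0 0 0 9 1.0 2\n")
        aset = sio.read_swc([f], sio.VoxelPitch(1, 1, 1), {"DC1_000": ("DC", 1)})
        tree = aset.trees["DC1_000"]
        assert len(tree.edges) == 2
        assert tree.landmarks["swc_root"] == 1

    def test_cyclic_parent_chain(self, tmp_path):
        f = tmp_path / "X.swc"
        f.write_text("1 0 0 0 0 1.0 2\n2 0 0 0 5 1.0 1\n")
        with pytest.raises(sio.ValidationError, match="cyclic"):
            sio.read_swc([f], sio.VoxelPitch(1, 1, 1))

    def test_shared_internal_ids_distinct_trees(self, tmp_path):
        for stem in ("OHC1_000", "OHC1_001"):
            (tmp_path / f"{stem}.swc").write_text("1 0 0 0 0 1.0 -1\n2 0 1 0 0 1.0 1\n")
        aset = sio.read_swc(
            sorted(tmp_path.glob("*.swc")),
            sio.VoxelPitch(1, 1, 1),
            {"OHC1_000": ("OHC", 1), "OHC1_001": ("OHC", 1)},
        )
        assert set(aset.trees) == {"OHC1_000", "OHC1_001"}

    def test_swc_roundtrip(self, tmp_path, cba1_volume):
        aset, _ = cba1_volume
        sub = sio.AnnotationSet(pitch=aset.pitch)
        sub.add_tree(aset.trees["DC1_005"])
        sio.write_annotation(sub, tmp_path / "out", "swc")
        labels = {"DC1_005": ("DC", 1)}
        back = sio.read_swc([tmp_path / "out" / "DC1_005.swc"], aset.pitch, labels)
        t0, t1 = aset.trees["DC1_005"], back.trees["DC1_005"]
        assert t1.edges == t0.edges
        for k, v in t0.landmarks.items():
            assert t1.landmarks[k] == v


class TestContacts:
    def test_roundtrip_and_validation(self, tmp_path, cba1_volume):
        aset, _ = cba1_volume
        sio.write_annotation(aset, tmp_path / "c.csv", "contacts-csv")
        n = len(aset.contacts)
        aset.contacts = []
        sio.read_contacts(tmp_path / "c.csv", aset)
        assert len(aset.contacts) == n

    def test_efferent_class_on_t2sgn_rejected(self, tmp_path, cba1_volume):
        aset, _ = cba1_volume
        fid = next(t.tree_id for t in aset.trees_of_class("T2SGN"))
        oid = next(t.tree_id for t in aset.trees_of_class("OHC"))
        (tmp_path / "bad.csv").write_text(
            "fiber_id,target_id,bouton_class,x,y,z,node_id\n"
            f"{fid},{oid},efferent,0,0,0,1\n"
        )
        with pytest.raises(sio.ValidationError, match="efferent"):
            sio.read_contacts(tmp_path / "bad.csv", aset)

    def test_empty_table_is_noop(self, tmp_path, caplog):
        aset = sio.AnnotationSet(pitch=sio.VoxelPitch(1, 1, 1))
        (tmp_path / "e.csv").write_text("fiber_id,target_id,bouton_class,x,y,z,node_id\n")
        out = sio.read_contacts(tmp_path / "e.csv", aset)
        assert out.contacts == []

    def test_unsupported_format(self, tmp_path):
        aset = sio.AnnotationSet(pitch=sio.VoxelPitch(1, 1, 1))
        with pytest.raises(sio.AnnotationError, match="foo"):
            sio.write_annotation(aset, tmp_path / "x", "foo")


class TestValidation:
    def test_cycle_rejected(self):
        t = make_tree(positions=[(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        t.add_edge(3, 1)
        with pytest.raises(sio.ValidationError, match="cycle"):
            t.validate()

    def test_disconnection_rejected(self):
        t = make_tree(positions=[(0, 0, 0), (1, 0, 0)])
        t.add_node(7, np.array([5.0, 5.0, 5.0]))
        with pytest.raises(sio.ValidationError, match="disconnected"):
            t.validate()

    def test_rowed_class_needs_row(self):
        t = make_tree(cls="DC", row=None, tree_id="DCx")
        with pytest.raises(sio.ValidationError, match="row"):
            t.validate()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=1, max_value=1000))
    def test_pitch_linearity(self, k):
        """Scaling the pitch by k scales all inter-node distances by k."""
        base = sio.VoxelPitch(11, 11, 40)
        scaled = sio.VoxelPitch(11 * k, 11 * k, 40 * k)
        voxels = np.array([[0, 0, 0], [3, 4, 5], [10, 2, 7]], dtype=float)
        d = [
            np.linalg.norm(np.diff(voxels * p.as_array(), axis=0), axis=1)
            for p in (base, scaled)
        ]
        assert np.allclose(d[1], k * d[0])
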