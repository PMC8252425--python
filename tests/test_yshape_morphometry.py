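import math

import numpy as np
import pytest

from cortimorph import yshape_morphometry as ym
from cortimorph.skeleton_io import SkeletonTree, ValidationError


def chain_tree(points, landmarks, cls="OHC", row=1, tree_id="OHC1_000"):
    t = SkeletonTree(tree_id=tree_id, cell_class=cls, row=row)
    for i, p in enumerate(points, start=1):
        t.add_node(i, np.array(p, dtype=float))
        if i > 1:
            t.add_edge(i - 1, i)
    t.landmarks.update(landmarks)
    return t


class TestPathLength:
    def test_l_shaped_chain(self):
        t = chain_tree(
            [(0, 0, 0), (0, 0, 10000), (0, 10000, 10000)],
            {"a": 1, "b": 3},
        )
        assert ym.path_length(t, "a", "b") == pytest.approx(20.0)

    def test_identity_landmarks(self):
        t = chain_tree([(0, 0, 0), (0, 0, 1000)], {"a": 1})
        assert ym.path_length(t, "a", "a") == 0.0

    def test_missing_landmark_named(self):
        t = chain_tree([(0, 0, 0), (0, 0, 1000)], {"a": 1})
        with pytest.raises(ValidationError, match="nope"):
            ym.path_length(t, "a", "nope")

    def test_at_least_chord_length(self, cba1_volume):
        """Path length >= straight-line distance between its endpoints."""
        aset, _ = cba1_volume
        for dc in aset.trees_of_class("DC")[:20]:
            L = ym.path_length(dc, "DC_root", "PhP_branch_point")
            chord = np.linalg.norm(
                dc.landmark_position("PhP_branch_point")
                - dc.landmark_position("DC_root")
            ) / 1000.0
            assert L >= chord - 1e-9

    def test_generator_length_recovered(self, cba1_volume):
        """Smooth-bow jitter must not inflate path lengths materially."""
        aset, ledger = cba1_volume
        errs = [
            ym.path_length(aset.trees[f"OHC{v['row']}_{v['col']:03d}"],
                           "basal_pole", "cuticular_plate") - v["L_OHC"]
            for v in ledger.complexes.values()
        ]
        assert abs(float(np.mean(errs))) < 0.05
        assert float(np.max(np.abs(errs))) < 0.2


class TestPrincipalAxis:
    def test_collinear_orientation(self):
        t = chain_tree(
            [(0, 0, 0), (0, 0, 1000), (0, 0, 2000)], {"base": 1, "apex": 3}
        )
        assert np.allclose(ym.principal_axis(t, "base", "apex"), [0, 0, 1])
        assert np.allclose(ym.principal_axis(t, "apex", "base"), [0, 0, -1])

    def test_noisy_axis_within_one_degree(self, cba1_volume):
        aset, ledger = cba1_volume
        for v in list(ledger.complexes.values())[:40]:
            if not v["complete"]:
                continue
            dc = aset.trees[f"DC{v['row']}_{v['col']:03d}"]
            axis = ym.principal_axis(dc, "PhP_branch_point", "PhP_apical_insertion")
            true = np.array(v["php_dir"])
            ang = math.degrees(math.acos(float(np.clip(axis @ true, -1, 1))))
            assert ang < 1.0


class TestIntersectionAngle:
    @pytest.mark.parametrize(
        "b,expected",
        [
            ((0.0, math.sin(math.radians(30)), math.cos(math.radians(30))), 30.0),
            ((0.0, 0.0, 1.0), 0.0),
            ((0.0, 1.0, 0.0), 90.0),
        ],
    )
    def test_analytic_pairs(self, b, expected):
        assert ym.intersection_angle((0, 0, 1), b) == pytest.approx(expected, abs=1e-9)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            ym.intersection_angle((0, 0, 2), (0, 0, 1))


class TestLongitudinalAngle:
    def test_parallel_and_perpendicular(self, cba1_frame):
        u = cba1_frame.rows[2].direction
        b3, bp = ym.longitudinal_angle(u, cba1_frame, 2)
        assert b3 == pytest.approx(0.0, abs=1e-9)
        b3, bp = ym.longitudinal_angle(cba1_frame.bm.normal, cba1_frame, 2)
        assert b3 == pytest.approx(90.0, abs=0.1)

    def test_absent_row(self, cba1_frame):
        with pytest.raises(KeyError):
            ym.longitudinal_angle((1, 0, 0), cba1_frame, 4)


class TestMosaicSpan:
    def test_row_rule_on_default_lattice(self, cba1_yshapes):
        _, table, _, _ = cba1_yshapes
        spans = {r: set(g["span"]) for r, g in table.groupby("row")}
        assert spans == {1: {4}, 2: {3}, 3: {2}}

    def test_own_column_insertion_is_span_one(self, cba1_volume, cba1_frame):
        aset, _ = cba1_volume
        lattice = ym.RLLattice(aset, cba1_frame)
        dc = aset.trees["DC1_005"]
        # move the insertion landmark onto the fiber's own apex column
        own_apex = aset.trees["OHC1_005"].landmark_position("cuticular_plate")
        tip_node = dc.landmarks["PhP_apical_insertion"]
        saved = dc.nodes[tip_node].position.copy()
        dc.nodes[tip_node].position = own_apex + np.array([0.0, 500.0, 0.0])
        try:
            span, partners, tied = ym.mosaic_span(dc, lattice, "OHC1_005")
            assert span == 1
            assert "OHC1_005" in partners
        finally:
            dc.nodes[tip_node].position = saved

    def test_row1_partners_are_neighbouring_rows(self, cba1_volume, cba1_frame):
        """A row-1 PhP tip lands in the mosaic amid row-2 OHC apices."""
        aset, _ = cba1_volume
        lattice = ym.RLLattice(aset, cba1_frame)
        dc = aset.trees["DC1_004"]
        span, partners, _ = ym.mosaic_span(dc, lattice, "OHC1_004")
        assert span == 4
        assert partners and all(p.startswith("OHC2") for p in partners)

    def test_missing_insertion_landmark(self, cba1_volume, cba1_frame):
        aset, _ = cba1_volume
        lattice = ym.RLLattice(aset, cba1_frame)
        incomplete = next(
            t for t in aset.trees_of_class("DC")
            if "PhP_apical_insertion" not in t.landmarks
        )
        own = "OHC" + incomplete.tree_id[2:]
        with pytest.raises(ValidationError):
            ym.mosaic_span(incomplete, lattice, own)


class TestMeasureAll:
    def test_census_and_exclusions(self, cba1_yshapes):
        _, table, summary, n_excluded = cba1_yshapes
        assert table.groupby("row").size().tolist() == [29, 30, 29]
        assert n_excluded == 8

    def test_summary_has_per_row_stats(self, cba1_yshapes):
        _, _, summary, _ = cba1_yshapes
        assert ("alpha", "mean") in summary.columns
        assert summary.loc[1, ("alpha", "n")] == 29

    def test_missing_basal_pole_excludes_complex(self, cba1, cba1_frame, cba1_volume):
        from cortimorph import generate_annotation, measure_all_yshapes

        aset, _ = generate_annotation(cba1, 3)
        ohc = aset.trees["OHC1_010"]
        del ohc.landmarks["basal_pole"]
        from cortimorph import build_reference_frame

        frame = build_reference_frame(aset, cba1.basal_hint)
        _, table, _, n_exc = measure_all_yshapes(aset, frame)
        assert n_exc == 9
        assert "Y1_010" not in set(table["complex_id"])

    def test_empty_annotation(self, cba1, cba1_frame):
        from cortimorph.skeleton_io import AnnotationSet, VoxelPitch

        empty = AnnotationSet(pitch=VoxelPitch(11, 11, 40))
        measures, table, summary, n = ym.measure_all_yshapes(empty, cba1_frame)
        assert measures == [] and len(table) == 0 and n == 0

    def test_alpha_beta_consistency_projected(self, cba1_yshapes):
        """In the longitudinal projection, beta_OHC - beta_PhP equals alpha_proj."""
        _, table, _, _ = cba1_yshapes
        gap = np.abs(
            (table["beta_OHC_proj"] - table["beta_PhP_proj"]).abs()
            - table["alpha_proj"]
        )
        assert float(gap.max()) < 1e-6
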