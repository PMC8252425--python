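import numpy as np
import pytest

from cortimorph import fiber_analysis as fa
from cortimorph.skeleton_io import AnnotationSet, SkeletonTree, VoxelPitch


def chain(points, tree_id="T2SGN_000", cls="T2SGN", row=None, start_id=1):
    t = SkeletonTree(tree_id=tree_id, cell_class=cls, row=row)
    for k, p in enumerate(points):
        t.add_node(start_id + k, np.array(p, dtype=float) * 1000.0)  # um -> nm
        if k > 0:
            t.add_edge(start_id + k - 1, start_id + k)
    return t


@pytest.fixture(scope="module")
def profiles(cba1_volume, cba1_frame, cba1_support):
    aset, _ = cba1_volume
    return [
        fa.build_profile(f, aset.contacts, cba1_frame, cba1_support)
        for f in sorted(aset.trees_of_class("T2SGN"), key=lambda t: t.tree_id)
    ]


class TestLocateTurn:
    def test_right_angle_bend_found(self, cba1_frame):
        pts = [(0, -20 + i, 10) for i in range(15)] + [
            (1 + i, -5, 10) for i in range(15)
        ]
        fiber = chain(pts)
        node = fa.locate_turn(fiber, cba1_frame)
        bend = fiber.nodes[node].position / 1000.0
        assert abs(bend[1] - (-5)) <= 2.0  # within the bend neighbourhood

    def test_straight_fiber_not_found(self, cba1_frame):
        fiber = chain([(i, 0, 10) for i in range(20)])
        with pytest.raises(fa.TurnNotFoundError):
            fa.locate_turn(fiber, cba1_frame)

    def test_annotated_landmark_returned_unchanged(self, cba1_volume, cba1_frame):
        aset, ledger = cba1_volume
        for fid, entry in list(ledger.fibers.items())[:5]:
            fiber = aset.trees[fid]
            assert fa.locate_turn(fiber, cba1_frame) == fiber.landmarks["turn"]

    def test_detector_matches_annotated_turn(self, cba1_volume, cba1_frame):
        """Without the landmark, the detector lands within the window."""
        aset, ledger = cba1_volume
        hits = 0
        fids = [f for f, e in ledger.fibers.items() if e["complete"]][:8]
        for fid in fids:
            fiber = aset.trees[fid]
            marked = fiber.landmarks.pop("turn")
            try:
                found = fa.locate_turn(fiber, cba1_frame)
            finally:
                fiber.landmarks["turn"] = marked
            d = np.linalg.norm(
                fiber.nodes[found].position - fiber.nodes[marked].position
            ) / 1000.0
            if d <= 5.0:
                hits += 1
        assert hits >= 7


class TestProfileAndFit:
    def test_constant_height_single_dc(self, cba1_frame):
        """A fiber hugging one DC trunk: all samples at its height, one id."""
        dc = chain(
            [(50, 0, z) for z in range(0, 30)], tree_id="DC1_999", cls="DC", row=1
        )
        dc.landmarks.update({"DC_root": 1, "PhP_branch_point": 30})
        fiber = chain(
            [(50, -20 + i, 12) for i in range(18)]
            + [(50.5 + i, -1.2, 12) for i in range(3)],
            start_id=100,
        )
        fiber.landmarks["turn"] = 117
        fiber.landmarks["fiber_end"] = 120
        profile = fa.build_profile(fiber, [], cba1_frame, [dc])
        attached = profile.samples["attached_id"].dropna().unique().tolist()
        assert attached == ["DC1_999"]
        np.testing.assert_allclose(profile.samples["height_um"], 12.0, atol=0.5)

    def test_attachment_radius_rule(self, cba1_frame):
        dc = chain([(50, 0, z) for z in range(0, 30)], tree_id="DC1_999", cls="DC", row=1)
        dc.landmarks.update({"DC_root": 1, "PhP_branch_point": 30})
        fiber = chain(
            [(50, -20 + i, 12) for i in range(17)] + [(51, -3, 12), (52, -3, 12)],
            start_id=100,
        )
        fiber.landmarks["turn"] = 117
        fiber.landmarks["fiber_end"] = 118
        profile = fa.build_profile(fiber, [], cba1_frame, [dc])
        assert profile.samples["attached_id"].isna().all()  # 3 um away > 2 um

    def test_biphasic_exact_on_noiseless_input(self):
        """OLS recovers a noiseless piecewise-linear profile exactly."""
        x = np.arange(0.0, 40.0)
        h = np.where(x < 20, 10 + 0.25 * x, 10 + 0.25 * 20 + 0.0 * (x - 20))
        samples = __import__("pandas").DataFrame(
            {
                "node_id": np.arange(len(x)),
                "arc_um": x,
                "longitudinal_um": x,
                "height_um": h,
                "attached_id": None,
                "attached_class": None,
            }
        )
        profile = fa.FiberProfile("f", samples, {20: ["OHC1_000"]}, 0, 20.0)
        fit = fa.fit_biphasic(profile, dc_pitch_um=6.8)
        assert fit.climbing_slope == pytest.approx(0.25, abs=1e-9)
        assert fit.contact_slope == pytest.approx(0.0, abs=1e-9)
        assert fit.climbing_slope_per_dc == pytest.approx(0.25 * 6.8)

    def test_contactless_fiber_still_reports_climb(self, profiles):
        passing = [p for p in profiles if p.breakpoint_arc is None]
        assert passing  # truncated segments exist in the CBA1 census
        fit = fa.fit_biphasic(passing[0])
        assert fit.contact_slope is None and np.isfinite(fit.climbing_slope)

    def test_fitted_slopes_match_ledger(self, cba1_volume, profiles):
        """Per-fiber fits track the sampled slopes; cohort means tighter.

        The contact region is short (~20-40 um), so its OLS slope
        carries a few-thousandths of noise per fiber from the smooth
        perpendicular jitter; errors are zero-mean and shrink in the
        cohort mean.
        """
        _, ledger = cba1_volume
        climb_err, contact_err = [], []
        for p in profiles:
            entry = ledger.fibers[p.fiber_id]
            if not entry["complete"]:
                continue
            fit = fa.fit_biphasic(p)
            climb_err.append(fit.climbing_slope - entry["climbing_slope"])
            contact_err.append(fit.contact_slope - entry["contact_slope"])
            assert fit.climbing_slope == pytest.approx(
                entry["climbing_slope"], abs=0.02
            )
            assert fit.contact_slope == pytest.approx(
                entry["contact_slope"], abs=0.04
            )
        assert abs(float(np.mean(climb_err))) < 0.005
        assert abs(float(np.mean(contact_err))) < 0.005

    def test_climbing_exceeds_contact_when_separated(self, cba1_volume, profiles):
        """Fitted ordering follows the sampled slopes when well separated."""
        _, ledger = cba1_volume
        for p in profiles:
            entry = ledger.fibers[p.fiber_id]
            if not entry["complete"]:
                continue
            if entry["climbing_slope"] - entry["contact_slope"] >= 0.05:
                fit = fa.fit_biphasic(p)
                assert fit.climbing_slope > fit.contact_slope


class TestHeightsAndCounts:
    def test_height_groups_reported_with_n(self, profiles):
        stats = fa.contact_height_stats(profiles)
        byc = stats.set_index(["region", "support_class"])
        for cls in ("DC1", "DC2", "DC3"):
            assert byc.loc[("climbing", cls), "n"] > 0
        assert byc.loc[("contact", "any"), "n"] > 0
        # contact region sits well above the climbing region
        assert (
            byc.loc[("contact", "any"), "mean"]
            > byc.loc[("climbing", "DC1"), "mean"]
        )

    def test_empty_profiles_give_zero_n(self):
        stats = fa.contact_height_stats([])
        assert (stats["n"] == 0).all()

    def test_afferent_counts_and_ribbon_fraction(self):
        aset = AnnotationSet(pitch=VoxelPitch(1, 1, 1))
        ohc = chain([(0, 0, 0), (0, 0, 1)], tree_id="OHC1_000", cls="OHC", row=1)
        fib = chain([(0, 0, 0), (1, 0, 0)], tree_id="T2SGN_000")
        aset.add_tree(ohc)
        aset.add_tree(fib)
        from cortimorph.skeleton_io import ContactRecord

        for cls in ("afferent_ribbon", "afferent_ribbon", "afferent_ribbonless"):
            aset.contacts.append(
                ContactRecord("T2SGN_000", "OHC1_000", cls, np.zeros(3), 2)
            )
        m = fa.InnervationMatrix.from_annotation(aset, "afferent")
        per_ohc, per_row, ribbon = fa.afferent_counts(m)
        assert per_ohc.loc["OHC1_000", "n_contacts"] == 3
        assert ribbon[1] == pytest.approx(2 / 3)

    def test_marginal_conservation(self, cba1_volume):
        """Matrix marginals equal the contact-record counts, always."""
        aset, _ = cba1_volume
        for kind, classes in (
            ("afferent", ("afferent_ribbon", "afferent_ribbonless")),
            ("efferent", ("efferent",)),
        ):
            m = fa.InnervationMatrix.from_annotation(aset, kind)
            n_records = sum(c.bouton_class in classes for c in aset.contacts)
            assert m.n_contacts == n_records
            assert int(m.counts.sum(axis=1).sum()) == n_records


class TestRowSpecificity:
    def test_exclusive_and_modal_fraction(self):
        aset = AnnotationSet(pitch=VoxelPitch(1, 1, 1))
        for r, cid in ((1, "OHC1_000"), (2, "OHC2_000")):
            aset.add_tree(chain([(0, 0, 0), (0, 0, 1)], tree_id=cid, cls="OHC", row=r))
        aset.add_tree(chain([(0, 0, 0), (1, 0, 0)], tree_id="T2SGN_000"))
        aset.add_tree(chain([(0, 0, 0), (1, 0, 0)], tree_id="T2SGN_001"))
        aset.add_tree(chain([(0, 0, 0), (1, 0, 0)], tree_id="T2SGN_002"))
        from cortimorph.skeleton_io import ContactRecord

        for t in ("OHC2_000",) * 3:
            aset.contacts.append(
                ContactRecord("T2SGN_000", t, "afferent_ribbon", np.zeros(3), 2)
            )
        for t in ("OHC1_000", "OHC2_000"):
            aset.contacts.append(
                ContactRecord("T2SGN_001", t, "afferent_ribbonless", np.zeros(3), 2)
            )
        m = fa.InnervationMatrix.from_annotation(aset, "afferent")
        table, summary = fa.row_specificity(m)
        t0 = table.set_index("fiber_id")
        assert t0.loc["T2SGN_000", "exclusive"] and t0.loc["T2SGN_000", "modal_fraction"] == 1.0
        assert not t0.loc["T2SGN_001", "exclusive"]
        assert t0.loc["T2SGN_001", "modal_fraction"] == 0.5
        assert summary["n_zero_contact"] == 1
        assert summary["exclusive_fraction"] == 0.5


def moc_fiber(branch_before_slab, tree_id="MOC_000"):
    """Radial fiber crossing y in [-22, -14]; optional pre-slab fork."""
    stem = [(50, -34 + i, 30) for i in range(9)]  # up to y = -26
    t = chain(stem, tree_id=tree_id, cls="MOC")
    fork = len(stem)
    if branch_before_slab:
        for j, dx in enumerate((-5, 5)):
            arm = [(50 + dx, -26 + i, 30) for i in range(1, 27)]
            sub = chain(arm, start_id=100 * (j + 1) + 1)
            for nid, node in sub.nodes.items():
                t.add_node(nid, node.position)
            t.edges |= sub.edges
            t.add_edge(fork, 100 * (j + 1) + 1)
    else:
        arm = [(50, -26 + i, 30) for i in range(1, 27)]
        sub = chain(arm, start_id=101)
        for nid, node in sub.nodes.items():
            t.add_node(nid, node.position)
        t.edges |= sub.edges
        t.add_edge(fork, 101)
    return t


@pytest.fixture
def zone():
    return fa.TunnelZone(point=np.zeros(3), axis=np.array([0, 1.0, 0]),
                         lo_um=-22.0, hi_um=-14.0)


class TestMocClassification:
    def test_single_crossing_unbranched(self, zone):
        c = fa.classify_moc(moc_fiber(False), zone)
        assert c.subtype == "unbranched" and c.n_tunnel_crossings == 1

    def test_pre_slab_fork_branched(self, zone):
        c = fa.classify_moc(moc_fiber(True), zone)
        assert c.subtype == "branched" and c.n_tunnel_crossings == 2

    def test_post_slab_fork_stays_unbranched(self, cba1_volume, cba1_frame, cba1):
        aset, ledger = cba1_volume
        z = fa.TunnelZone.from_frame(cba1_frame, *cba1.tc_zone_um)
        for fid, entry in ledger.mocs.items():
            c = fa.classify_moc(aset.trees[fid], z)
            assert c.subtype == entry["subtype"]
            assert c.n_tunnel_crossings == entry["n_crossings"]

    def test_resampling_invariance(self, zone):
        """Subdividing edges never changes the crossing count."""
        fiber = moc_fiber(True)
        base = fa.classify_moc(fiber, zone).n_tunnel_crossings
        dense = SkeletonTree(tree_id="MOC_dense", cell_class="MOC", row=None)
        nid = 10000
        for n, node in fiber.nodes.items():
            dense.add_node(n, node.position)
        for a, b in fiber.edges:
            mid = (fiber.nodes[a].position + fiber.nodes[b].position) / 2
            dense.add_node(nid, mid)
            dense.add_edge(a, nid)
            dense.add_edge(nid, b)
            nid += 1
        assert fa.classify_moc(dense, zone).n_tunnel_crossings == base

    def test_never_entering_slab_flagged(self, zone):
        stub = chain([(0, -40 + i, 30) for i in range(10)], tree_id="MOC_x", cls="MOC")
        with pytest.raises(fa.MocClassificationError):
            fa.classify_moc(stub, zone)

    def test_efferent_counts_summaries(self, cba1_volume, cba1_frame, cba1):
        aset, ledger = cba1_volume
        z = fa.TunnelZone.from_frame(cba1_frame, *cba1.tc_zone_um)
        classes, flagged = fa.classify_all_moc(aset, z)
        assert flagged == []
        m = fa.InnervationMatrix.from_annotation(aset, "efferent")
        per_ohc, per_row, subtype_stats, row_dist = fa.efferent_counts(m, classes)
        st = subtype_stats.set_index("subtype")
        assert st.loc["branched", "n_fibers"] == 17
        assert st.loc["unbranched", "n_fibers"] == 53
        assert 3 <= st.loc["branched", "min_synapses"]
        assert st.loc["branched", "max_synapses"] <= 11
        assert st.loc["unbranched", "max_synapses"] <= 4
        for sub in ("branched", "unbranched"):
            pct = row_dist[row_dist["subtype"] == sub]["percent"].sum()
            assert pct == pytest.approx(100.0)
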