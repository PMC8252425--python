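"""Type-2 spiral-ganglion-neuron and medial-olivocochlear fiber analysis.

Type-2 afferents cross the tunnel-of-Corti floor, turn ~90 deg toward the
cochlear base after bypassing the outer pillar cells, then travel along
the Deiters-cell rows.  Based on the presence of OHC-innervating
collaterals each fiber splits into two functional compartments: a
collateral-free *climbing* region with a steep height-vs-longitudinal
slope and an *OHC-contact* region that plateaus.  This module locates the
turn, builds per-fiber height profiles, fits the biphasic trajectory
(ordinary least squares on each side of the first collateral), summarises
contact heights per supporting cell, and quantifies per-OHC afferent
counts, ribbon-associated fractions and row specificity.

Medial olivocochlear (MOC) efferents are classified branched vs
unbranched by the number of distinct branches traversing the tunnel
slab between the pillar-cell rows (>= 2 crossings = branched).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from cortimorph.reference_geometry import NM_PER_UM, ReferenceFrame, height_above_bm
from cortimorph.skeleton_io import (
    AFFERENT_CLASSES,
    AnnotationSet,
    SkeletonTree,
    ValidationError,
)

logger = logging.getLogger(__name__)

TURN_LANDMARK = "turn"
END_LANDMARK = "fiber_end"


class TurnNotFoundError(ValueError):
    """No candidate node shows a sharp enough direction change."""


class MocClassificationError(ValueError):
    """Fiber never traverses the tunnel slab; not an MOC by anatomy."""


@dataclass
class FiberProfile:
    fiber_id: str
    #: one row per trunk node past the turn:
    #: arc_um, longitudinal_um, height_um, attached_id, attached_class, node_id
    samples: pd.DataFrame
    #: trunk node id -> sorted list of target OHC ids
    collateral_origins: dict[int, list[str]]
    turn_node: int
    #: arc length (um) of the first collateral origin; None when contact-free
    breakpoint_arc: float | None


@dataclass
class CompartmentFit:
    fiber_id: str
    breakpoint_index: int | None
    climbing_slope: float  # um height per um longitudinal distance
    contact_slope: float | None
    climbing_slope_per_dc: float  # um per Deiters cell
    contact_slope_per_dc: float | None
    climbing_residual: float
    contact_residual: float | None


@dataclass(frozen=True)
class TunnelZone:
    """Radial slab between the pillar-cell rows where crossings are counted."""

    point: np.ndarray  # (3,) nm, a point on the slab mid-plane
    axis: np.ndarray  # unit radial direction
    lo_um: float
    hi_um: float

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float))
        axis = np.asarray(self.axis, float)
        object.__setattr__(self, "axis", axis / np.linalg.norm(axis))
        if not self.lo_um < self.hi_um:
            raise ValueError("tunnel zone requires lo < hi")

    def coordinate(self, pos: np.ndarray) -> float:
        return float((pos - self.point) @ self.axis) / NM_PER_UM

    @classmethod
    def from_frame(cls, frame: ReferenceFrame, lo_um: float, hi_um: float) -> "TunnelZone":
        """Slab bounded by two longitudinal planes at radial offsets
        ``lo_um``/``hi_um`` from the row-1 line (modiolar side negative)."""
        return cls(
            point=frame.rows[1].point,
            axis=frame.radial_direction(),
            lo_um=lo_um,
            hi_um=hi_um,
        )


@dataclass
class MocClass:
    fiber_id: str
    n_tunnel_crossings: int
    subtype: str  # branched | unbranched
    n_synapses: int

    def __post_init__(self):
        expected = "branched" if self.n_tunnel_crossings >= 2 else "unbranched"
        if self.subtype != expected:
            raise ValueError("subtype must follow the tunnel-crossing rule")


# ---------------------------------------------------------------------------
# trunk extraction and turn location
# ---------------------------------------------------------------------------

def _weighted_graph(tree: SkeletonTree) -> nx.Graph:
    g = nx.Graph()
    for nid in tree.nodes:
        g.add_node(nid)
    for a, b in tree.edges:
        w = float(np.linalg.norm(tree.nodes[a].position - tree.nodes[b].position))
        g.add_edge(a, b, weight=w)
    return g


def _farthest_node(g: nx.Graph, source: int) -> int:
    dist = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    return max(dist, key=dist.get)


def trunk_path(tree: SkeletonTree, turn_node: int) -> list[int]:
    """Main-trunk node ids from the turn to the distal fiber end.

    The end is the ``fiber_end`` landmark when annotated, else the node
    at greatest path distance from the turn.
    """
    g = _weighted_graph(tree)
    end = tree.landmarks.get(END_LANDMARK, _farthest_node(g, turn_node))
    return nx.shortest_path(g, turn_node, end, weight="weight")


def locate_turn(
    fiber: SkeletonTree,
    frame: ReferenceFrame | None = None,
    window_um: float = 5.0,
    min_angle_deg: float = 45.0,
    opc_zone_um: tuple[float, float] = (-12.0, -2.0),
) -> int:
    """Node of the sharp ~90 deg basal turn of a type-2 fiber.

    Returns the annotated ``turn`` landmark unchanged when present.
    Otherwise the node maximizing the angle between mean incoming and
    outgoing tangents over a ``window_um`` window along the fiber's
    longest path is returned.  When a reference frame is given,
    candidates are restricted to the outer-pillar radial zone
    (``opc_zone_um``, relative to the row-1 line): the turn happens
    right after the fiber bypasses the pillar cells, and the
    restriction keeps collateral junctions out of contention.  If no
    candidate reaches ``min_angle_deg`` a :class:`TurnNotFoundError`
    signals the fiber should be excluded from compartment analysis.
    """
    if TURN_LANDMARK in fiber.landmarks:
        return fiber.landmarks[TURN_LANDMARK]
    if len(fiber.nodes) < 10:
        raise TurnNotFoundError(f"{fiber.tree_id}: too few nodes to locate a turn")
    g = _weighted_graph(fiber)
    a = _farthest_node(g, next(iter(fiber.nodes)))
    b = _farthest_node(g, a)
    path = nx.shortest_path(g, a, b, weight="weight")
    pts = fiber.positions(path) / NM_PER_UM
    in_zone = np.ones(len(path), dtype=bool)
    if frame is not None:
        radial = frame.radial_direction()
        s = ((pts * NM_PER_UM - frame.rows[1].point) @ radial) / NM_PER_UM
        in_zone = (s >= opc_zone_um[0]) & (s <= opc_zone_um[1])
        if not in_zone.any():
            in_zone[:] = True  # fiber entirely outside the zone: search all
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    best_angle, best_node = -1.0, None
    for i in range(1, len(path) - 1):
        if not in_zone[i]:
            continue
        back = (arc[i] - arc >= 0) & (arc[i] - arc <= window_um)
        fwd = (arc - arc[i] > 0) & (arc - arc[i] <= window_um)
        if back.sum() < 2 or fwd.sum() < 1:
            continue
        v_in = pts[i] - pts[back].mean(axis=0)
        v_out = pts[fwd].mean(axis=0) - pts[i]
        ni, no = np.linalg.norm(v_in), np.linalg.norm(v_out)
        if ni < 1e-9 or no < 1e-9:
            continue
        ang = math.degrees(math.acos(float(np.clip(v_in @ v_out / (ni * no), -1, 1))))
        if ang > best_angle:
            best_angle, best_node = ang, path[i]
    if best_node is None or best_angle < min_angle_deg:
        raise TurnNotFoundError(
            f"{fiber.tree_id}: max direction change {best_angle:.1f} deg < "
            f"{min_angle_deg} deg"
        )
    return best_node


# ---------------------------------------------------------------------------
# profiles and the biphasic fit
# ---------------------------------------------------------------------------

def build_support_index(trees, landmark_pairs=None):
    """KDTree over densely resampled trunk points of supporting cells.

    Prebuild once and pass to :func:`build_profile` when profiling many
    fibers against the same Deiters-cell/pillar-cell population.
    """
    return _support_index(trees, landmark_pairs or SUPPORT_LANDMARKS)


def _support_index(trees, landmark_pairs):
    points, labels = [], []
    for tree in trees:
        pair = landmark_pairs.get(tree.cell_class)
        if pair is None:
            continue
        lo, hi = pair
        if lo in tree.landmarks and hi in tree.landmarks:
            ids = tree.path_between(tree.landmarks[lo], tree.landmarks[hi])
        else:
            ids = sorted(tree.nodes)
        pts = tree.positions(ids)
        # subdivide edges to ~0.5 um so point distance approximates
        # segment distance within the attachment radius
        for p, q in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(q - p)
            n = max(1, int(seg / (0.5 * NM_PER_UM)))
            for t in np.linspace(0, 1, n, endpoint=False):
                points.append(p + t * (q - p))
                labels.append(tree)
        points.append(pts[-1])
        labels.append(tree)
    if not points:
        return None, []
    return cKDTree(np.array(points)), labels


SUPPORT_LANDMARKS = {"DC": ("DC_root", "PhP_branch_point"), "OPC": ("opc_base", "opc_apex")}


def build_profile(
    fiber: SkeletonTree,
    contacts,
    frame: ReferenceFrame,
    support_trees,
    attach_radius_um: float = 2.0,
) -> FiberProfile:
    """Height/longitudinal profile of one type-2 fiber past its turn.

    One sample per main-trunk node after the turn; each sample carries
    its height above the BM and the nearest supporting-cell trunk (DC
    main trunk or OPC) within ``attach_radius_um``, else none.
    ``contacts`` are this fiber's afferent contact records; collateral
    origins are mapped back onto the trunk.  ``support_trees`` may be a
    list of DC/OPC trees or a prebuilt :func:`build_support_index`.
    """
    turn = locate_turn(fiber, frame)
    path = trunk_path(fiber, turn)
    trunk_set = set(path)
    pts = fiber.positions(path)
    arc = (
        np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        / NM_PER_UM
    )
    line = frame.row_line(1)
    longitudinal = ((pts - line.point) @ line.direction) / NM_PER_UM
    heights = frame.bm.signed_distance(pts) / NM_PER_UM
    if np.any(heights < 0):
        logger.warning(
            "%s: %d trunk samples below the BM plane", fiber.tree_id, int((heights < 0).sum())
        )

    if isinstance(support_trees, tuple) and len(support_trees) == 2:
        tree_index, labels = support_trees
    else:
        tree_index, labels = _support_index(support_trees, SUPPORT_LANDMARKS)
    attached_id = [None] * len(path)
    attached_class = [None] * len(path)
    if tree_index is not None:
        dist, idx = tree_index.query(pts, k=1)
        for i, (d, j) in enumerate(zip(dist, idx)):
            if d <= attach_radius_um * NM_PER_UM:
                t = labels[j]
                attached_id[i] = t.tree_id
                attached_class[i] = "OPC" if t.cell_class == "OPC" else f"DC{t.row}"

    g = _weighted_graph(fiber)
    origins: dict[int, list[str]] = {}
    for c in contacts:
        if c.fiber_id != fiber.tree_id or c.bouton_class not in AFFERENT_CLASSES:
            continue
        if c.contact_node not in fiber.nodes:
            raise ValidationError(
                f"{fiber.tree_id}: contact node {c.contact_node} absent"
            )
        walk = nx.shortest_path(g, c.contact_node, turn, weight="weight")
        origin = next(n for n in walk if n in trunk_set)
        origins.setdefault(origin, []).append(c.target_id)
    origins = {k: sorted(v) for k, v in origins.items()}

    arc_of = dict(zip(path, arc))
    breakpoint_arc = min((arc_of[n] for n in origins), default=None)
    samples = pd.DataFrame(
        {
            "node_id": path,
            "arc_um": arc,
            "longitudinal_um": longitudinal,
            "height_um": heights,
            "attached_id": attached_id,
            "attached_class": attached_class,
        }
    )
    return FiberProfile(
        fiber_id=fiber.tree_id,
        samples=samples,
        collateral_origins=origins,
        turn_node=turn,
        breakpoint_arc=breakpoint_arc,
    )


def fit_biphasic(profile: FiberProfile, dc_pitch_um: float = 6.8) -> CompartmentFit:
    """Two-compartment OLS fit of height vs longitudinal position.

    The breakpoint is the first collateral origin (the anatomical start
    of the OHC-contact region), not a free change point.  Slopes are
    dimensionless (um height per um longitudinal distance); per-DC
    variants multiply by the configured Deiters-cell pitch.
    """
    s = profile.samples
    if profile.breakpoint_arc is None:
        x, h = s["longitudinal_um"].to_numpy(), s["height_um"].to_numpy()
        slope, resid = _ols(x, h)
        return CompartmentFit(
            profile.fiber_id, None, slope, None, slope * dc_pitch_um, None, resid, None
        )
    idx = int(np.searchsorted(s["arc_um"].to_numpy(), profile.breakpoint_arc))
    climb, contact = s.iloc[:idx], s.iloc[idx:]
    if len(climb) < 2 or len(contact) < 2:
        raise ValidationError(
            f"{profile.fiber_id}: breakpoint leaves fewer than 2 samples on one side"
        )
    m_c, r_c = _ols(climb["longitudinal_um"].to_numpy(), climb["height_um"].to_numpy())
    m_s, r_s = _ols(contact["longitudinal_um"].to_numpy(), contact["height_um"].to_numpy())
    return CompartmentFit(
        fiber_id=profile.fiber_id,
        breakpoint_index=idx,
        climbing_slope=m_c,
        contact_slope=m_s,
        climbing_slope_per_dc=m_c * dc_pitch_um,
        contact_slope_per_dc=m_s * dc_pitch_um,
        climbing_residual=r_c,
        contact_residual=r_s,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sqrt(np.mean((y - A @ coef) ** 2)))
    return float(coef[0]), resid


def contact_height_stats(profiles, fits=None) -> pd.DataFrame:
    """Heights above the BM grouped by supporting cell and compartment.

    Climbing-region samples are grouped by support (OPC, DC1-DC3);
    OHC-contact-region samples are pooled as the synapsing group.  One
    observation per (fiber, supporting cell, region): the mean height of
    that fiber's samples on that cell.  Empty groups report n = 0.
    """
    rows = []
    for p in profiles:
        s = p.samples[p.samples["attached_id"].notna()].copy()
        if p.breakpoint_arc is None:
            s["region"] = "climbing"
        else:
            s["region"] = np.where(
                s["arc_um"] < p.breakpoint_arc, "climbing", "contact"
            )
        for (aid, acls, region), grp in s.groupby(
            ["attached_id", "attached_class", "region"]
        ):
            rows.append(
                {
                    "fiber_id": p.fiber_id,
                    "support_id": aid,
                    "support_class": acls,
                    "region": region,
                    "height_um": float(grp["height_um"].mean()),
                }
            )
    obs = pd.DataFrame(rows, columns=["fiber_id", "support_id", "support_class", "region", "height_um"])
    groups = []
    for region, cls in [("climbing", "OPC"), ("climbing", "DC1"),
                        ("climbing", "DC2"), ("climbing", "DC3"),
                        ("contact", "any")]:
        sel = obs[obs["region"] == region]
        if cls != "any":
            sel = sel[sel["support_class"] == cls]
        groups.append(
            {
                "region": region,
                "support_class": cls,
                "mean": float(sel["height_um"].mean()) if len(sel) else float("nan"),
                "sd": float(sel["height_um"].std(ddof=1)) if len(sel) > 1 else float("nan"),
                "n": int(len(sel)),
            }
        )
    return pd.DataFrame(groups)


def fibers_per_dc(profiles) -> pd.DataFrame:
    """Distinct fibers attached to each supporting cell across profiles.

    Returns a DataFrame (support_id, support_class, n_fibers); cells no
    fiber touches are absent (join against the census for zeros).
    """
    pairs = set()
    for p in profiles:
        s = p.samples[p.samples["attached_id"].notna()]
        for aid, acls in zip(s["attached_id"], s["attached_class"]):
            pairs.add((p.fiber_id, aid, acls))
    df = pd.DataFrame(sorted(pairs), columns=["fiber_id", "support_id", "support_class"])
    if df.empty:
        return pd.DataFrame(columns=["support_id", "support_class", "n_fibers"])
    out = (
        df.groupby(["support_id", "support_class"])["fiber_id"]
        .nunique()
        .rename("n_fibers")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# innervation matrices
# ---------------------------------------------------------------------------

class InnervationMatrix:
    """Fiber x OHC synapse-count ledger with bouton classes retained.

    Rows cover every fiber of the requested kind and columns every
    labeled OHC, including zero-contact ones, so count denominators
    follow the full census.  Column/row marginals always equal the
    number of contact records the matrix was built from.
    """

    def __init__(self, counts: pd.DataFrame, long: pd.DataFrame, target_rows: pd.Series):
        self.counts = counts
        self.long = long
        self.target_rows = target_rows

    @classmethod
    def from_annotation(cls, annotation: AnnotationSet, kind: str) -> "InnervationMatrix":
        if kind == "afferent":
            classes, fiber_class = AFFERENT_CLASSES, "T2SGN"
        elif kind == "efferent":
            classes, fiber_class = ("efferent",), "MOC"
        else:
            raise ValueError(f"kind must be afferent or efferent, not {kind!r}")
        fibers = sorted(t.tree_id for t in annotation.trees_of_class(fiber_class))
        targets = sorted(t.tree_id for t in annotation.trees_of_class("OHC"))
        target_rows = pd.Series(
            {t.tree_id: t.row for t in annotation.trees_of_class("OHC")}
        )
        recs = [
            {
                "fiber_id": c.fiber_id,
                "target_id": c.target_id,
                "bouton_class": c.bouton_class,
                "target_row": target_rows[c.target_id],
            }
            for c in annotation.contacts
            if c.bouton_class in classes
        ]
        long = pd.DataFrame(
            recs, columns=["fiber_id", "target_id", "bouton_class", "target_row"]
        )
        counts = pd.DataFrame(0, index=fibers, columns=targets, dtype=int)
        for _, r in long.iterrows():
            counts.loc[r["fiber_id"], r["target_id"]] += 1
        return cls(counts, long, target_rows)

    @property
    def n_contacts(self) -> int:
        return int(self.counts.to_numpy().sum())


def afferent_counts(matrix: InnervationMatrix):
    """Per-OHC afferent contact totals, per-row summaries, ribbon fractions."""
    per_ohc = matrix.counts.sum(axis=0).rename("n_contacts").to_frame()
    per_ohc["row"] = matrix.target_rows
    per_row = per_ohc.groupby("row")["n_contacts"].agg(["mean", "std", "count"])
    ribbon = {}
    for row, grp in matrix.long.groupby("target_row"):
        n_all = len(grp)
        n_rib = int((grp["bouton_class"] == "afferent_ribbon").sum())
        ribbon[row] = n_rib / n_all if n_all else float("nan")
    return per_ohc, per_row, pd.Series(ribbon, name="ribbon_fraction")


def row_specificity(matrix: InnervationMatrix):
    """Row-sampling specificity of individual fibers.

    Per fiber: the set of OHC rows contacted, exclusivity (single row)
    and the modal-row fraction of its synapses.  Fibers with zero
    contacts are excluded from the population fractions and counted
    separately.
    """
    per_fiber = []
    for fiber_id in matrix.counts.index:
        grp = matrix.long[matrix.long["fiber_id"] == fiber_id]
        if len(grp) == 0:
            per_fiber.append(
                {"fiber_id": fiber_id, "n_contacts": 0, "rows": "",
                 "exclusive": None, "modal_fraction": float("nan")}
            )
            continue
        row_counts = grp["target_row"].value_counts()
        per_fiber.append(
            {
                "fiber_id": fiber_id,
                "n_contacts": int(len(grp)),
                "rows": ",".join(str(r) for r in sorted(row_counts.index)),
                "exclusive": bool(len(row_counts) == 1),
                "modal_fraction": float(row_counts.max() / len(grp)),
            }
        )
    table = pd.DataFrame(per_fiber)
    active = table[table["n_contacts"] > 0]
    n_active = len(active)
    n_exclusive = int(active["exclusive"].sum()) if n_active else 0
    summary = {
        "n_fibers": int(len(table)),
        "n_zero_contact": int(len(table) - n_active),
        "n_exclusive": n_exclusive,
        "n_multi_row": int(n_active - n_exclusive),
        "exclusive_fraction": n_exclusive / n_active if n_active else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------------
# MOC classification
# ---------------------------------------------------------------------------

def _slab_graph(fiber: SkeletonTree, zone: TunnelZone):
    """Graph with virtual nodes inserted where edges cross the slab faces."""
    g = nx.Graph()
    coord = {nid: zone.coordinate(n.position) for nid, n in fiber.nodes.items()}
    for nid in fiber.nodes:
        g.add_node(nid, s=coord[nid])
    virtual = 0
    for a, b in fiber.edges:
        sa, sb = coord[a], coord[b]
        cuts = sorted(
            t
            for bound in (zone.lo_um, zone.hi_um)
            if sa != sb
            for t in [(bound - sa) / (sb - sa)]
            if 0.0 < t < 1.0
        )
        prev = a
        for k, t in enumerate(cuts):
            vid = ("v", a, b, k)
            virtual += 1
            g.add_node(vid, s=sa + t * (sb - sa))
            g.add_edge(prev, vid)
            prev = vid
        g.add_edge(prev, b)
    return g


def classify_moc(
    fiber: SkeletonTree,
    tc_zone: TunnelZone,
    n_synapses: int = 0,
    eps: float = 1e-9,
) -> MocClass:
    """Branched/unbranched classification by tunnel-crossing count.

    A crossing is a distinct connected stretch of the fiber inside the
    tunnel slab whose ends reach both slab faces (entry on the modiolar
    side, exit on the Deiters side).  Branched iff >= 2 crossings.  The
    count is invariant to node-resampling density: edges are split at
    the slab faces before counting.  A fiber that never traverses the
    slab raises :class:`MocClassificationError`.
    """
    g = _slab_graph(fiber, tc_zone)
    inside = [n for n, d in g.nodes(data=True) if d["s"] >= tc_zone.lo_um - eps]
    sub = g.subgraph(inside)
    crossings = 0
    for comp in nx.connected_components(sub):
        smax = max(g.nodes[n]["s"] for n in comp)
        touches_a = any(
            g.nodes[nb]["s"] < tc_zone.lo_um - eps
            for n in comp
            for nb in g.neighbors(n)
        ) or any(abs(g.nodes[n]["s"] - tc_zone.lo_um) <= eps for n in comp)
        if smax >= tc_zone.hi_um - eps and touches_a:
            crossings += 1
    if crossings == 0:
        raise MocClassificationError(
            f"{fiber.tree_id}: fiber never traverses the tunnel slab"
        )
    subtype = "branched" if crossings >= 2 else "unbranched"
    return MocClass(fiber.tree_id, crossings, subtype, n_synapses)


def classify_all_moc(annotation: AnnotationSet, tc_zone: TunnelZone):
    """Classify every MOC tree; returns (classes, flagged_fiber_ids)."""
    matrix = InnervationMatrix.from_annotation(annotation, "efferent")
    per_fiber = matrix.counts.sum(axis=1)
    classes, flagged = [], []
    for fiber in sorted(annotation.trees_of_class("MOC"), key=lambda t: t.tree_id):
        try:
            classes.append(
                classify_moc(fiber, tc_zone, int(per_fiber.get(fiber.tree_id, 0)))
            )
        except MocClassificationError:
            flagged.append(fiber.tree_id)
    return classes, flagged


def efferent_counts(matrix: InnervationMatrix, moc_classes):
    """Efferent innervation summaries.

    Returns per-OHC counts, per-row mean/SD, per-subtype synapse-count
    statistics (mean, SD, range) and per-subtype row-distribution
    percentages.
    """
    per_ohc = matrix.counts.sum(axis=0).rename("n_contacts").to_frame()
    per_ohc["row"] = matrix.target_rows
    per_row = per_ohc.groupby("row")["n_contacts"].agg(["mean", "std", "count"])
    subtype_of = {c.fiber_id: c.subtype for c in moc_classes}
    stats_rows, dist_rows = [], []
    for subtype in ("branched", "unbranched"):
        ids = [f for f, s in subtype_of.items() if s == subtype]
        n_syn = np.array([c.n_synapses for c in moc_classes if c.subtype == subtype])
        stats_rows.append(
            {
                "subtype": subtype,
                "n_fibers": len(ids),
                "mean_synapses": float(n_syn.mean()) if len(n_syn) else float("nan"),
                "sd_synapses": float(n_syn.std(ddof=1)) if len(n_syn) > 1 else float("nan"),
                "min_synapses": int(n_syn.min()) if len(n_syn) else 0,
                "max_synapses": int(n_syn.max()) if len(n_syn) else 0,
            }
        )
        long = matrix.long[matrix.long["fiber_id"].isin(ids)]
        total = len(long)
        for row in (1, 2, 3):
            n = int((long["target_row"] == row).sum())
            dist_rows.append(
                {
                    "subtype": subtype,
                    "row": row,
                    "n_synapses": n,
                    "percent": 100.0 * n / total if total else float("nan"),
                }
            )
    return per_ohc, per_row, pd.DataFrame(stats_rows), pd.DataFrame(dist_rows)
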