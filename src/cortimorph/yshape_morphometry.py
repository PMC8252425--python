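"""Morphometry of the Y-shaped OHC/Deiters-cell complexes.

Each complex couples one outer hair cell (OHC) to the Deiters cell (DC)
that cradles its base; the DC's phalangeal process (PhP) tilts the
opposite way, so between the basilar membrane and the reticular lamina
(RL) the pair forms a Y.  This module measures, per complex:

* path lengths L_OHC (basal pole -> cuticular plate), L_DC (DC root ->
  PhP branch point) and L_PhP (branch point -> apical insertion);
* whole-structure principal axes (first right-singular vector of the
  centred path nodes), co-oriented from the BM toward the RL;
* the intersection angle alpha between the OHC and PhP axes (3D, with a
  longitudinal-plane projection variant reported alongside);
* longitudinal angles beta of each axis against the structure's own
  fitted DC row line;
* the RL mosaic span: how many OHC columns of its own row the PhP
  crosses between the DC base column and the apical insertion.

With both axes co-oriented BM->RL a straight continuation reads
alpha = 0 deg, matching the ~30-52 deg opening angles of the Y.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cortimorph.reference_geometry import (
    NM_PER_UM,
    DegenerateGeometryError,
    ReferenceFrame,
)
from cortimorph.skeleton_io import AnnotationSet, SkeletonTree, ValidationError

#: landmark names used by the measurement conventions
OHC_BASE, OHC_APEX = "basal_pole", "cuticular_plate"
DC_ROOT, PHP_BRANCH, PHP_TIP = "DC_root", "PhP_branch_point", "PhP_apical_insertion"


@dataclass
class YShapeMeasure:
    complex_id: str
    row: int
    L_OHC: float  # um
    L_PhP: float
    L_DC: float
    axis_OHC: np.ndarray
    axis_PhP: np.ndarray
    axis_DC: np.ndarray
    alpha: float  # degrees
    alpha_proj: float
    beta_OHC: float
    beta_PhP: float
    beta_DC: float
    beta_OHC_proj: float
    beta_PhP_proj: float
    beta_DC_proj: float
    span: int
    partner_ids: list[str] = field(default_factory=list)
    qc_flags: list[str] = field(default_factory=list)


def path_length(tree: SkeletonTree, from_landmark: str, to_landmark: str) -> float:
    """Euclidean length (um) of the unique tree path between two landmarks."""
    for name in (from_landmark, to_landmark):
        if name not in tree.landmarks:
            raise ValidationError(f"tree {tree.tree_id}: landmark {name!r} missing")
    path = tree.path_between(
        tree.landmarks[from_landmark], tree.landmarks[to_landmark]
    )
    pts = tree.positions(path)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()) / NM_PER_UM


def principal_axis(
    tree: SkeletonTree, from_landmark: str, to_landmark: str
) -> np.ndarray:
    """First right-singular vector of the centred landmark-to-landmark path.

    The sign is chosen so the axis points from ``from_landmark`` toward
    ``to_landmark`` (positive projection onto the chord), giving every
    structure a BM->RL orientation when called base-first.
    """
    for name in (from_landmark, to_landmark):
        if name not in tree.landmarks:
            raise ValidationError(f"tree {tree.tree_id}: landmark {name!r} missing")
    a, b = tree.landmarks[from_landmark], tree.landmarks[to_landmark]
    pts = tree.positions(tree.path_between(a, b))
    if pts.shape[0] < 2:
        raise DegenerateGeometryError(f"tree {tree.tree_id}: need >= 2 path nodes")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError(f"tree {tree.tree_id}: path nodes coincide")
    axis = vt[0]
    chord = tree.nodes[b].position - tree.nodes[a].position
    if axis @ chord < 0:
        axis = -axis
    return axis


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector (|v| = {norm:.8f})")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn(f"{name} renormalized (|v| = {norm:.9f})", stacklevel=2)
    return v / norm


def intersection_angle(axis_ohc, axis_php) -> float:
    """Angle alpha (degrees) between co-oriented OHC and PhP axes.

    No folding to <= 90 deg: both vectors share the BM->RL orientation, so
    the unclipped arccos is the opening angle of the Y.
    """
    a = _as_unit(axis_ohc, "axis_ohc")
    b = _as_unit(axis_php, "axis_php")
    return math.degrees(math.acos(float(np.clip(a @ b, -1.0, 1.0))))


def longitudinal_angle(
    axis, frame: ReferenceFrame, row: int
) -> tuple[float, float]:
    """Angle beta of an axis against its row's fitted line direction.

    Returns ``(beta3d, beta_proj)``: the full 3D angle (headline value)
    and the same after projecting the axis into the longitudinal plane
    spanned by the row direction and the BM normal.
    """
    axis = _as_unit(axis, "axis")
    line = frame.row_line(row)
    beta3d = math.degrees(
        math.acos(float(np.clip(axis @ line.direction, -1.0, 1.0)))
    )
    n = frame.bm.normal
    u = line.direction
    proj = (axis @ u) * u + (axis @ n) * n
    norm = np.linalg.norm(proj)
    if norm < 1e-12:
        beta_proj = 90.0  # axis perpendicular to the longitudinal plane
    else:
        beta_proj = math.degrees(
            math.acos(float(np.clip((proj / norm) @ u, -1.0, 1.0)))
        )
    return beta3d, beta_proj


class RLLattice:
    """OHC apical (cuticular-plate) landmarks ranked into columns per row.

    Column rank is assigned by projecting each row's apices onto that
    row's fitted line (toward-base positive) and ranking; this defines
    the column indexing in which the mosaic span is counted.
    """

    def __init__(self, annotation: AnnotationSet, frame: ReferenceFrame):
        self.frame = frame
        self.by_row: dict[int, list[tuple[float, str, np.ndarray]]] = {1: [], 2: [], 3: []}
        for ohc in annotation.trees_of_class("OHC"):
            if OHC_APEX not in ohc.landmarks:
                continue
            pos = ohc.landmark_position(OHC_APEX)
            s = float((pos - frame.row_line(ohc.row).point) @ frame.row_line(ohc.row).direction)
            self.by_row[ohc.row].append((s, ohc.tree_id, pos))
        for row in self.by_row:
            self.by_row[row].sort()
        self.rank: dict[str, int] = {
            tid: i for row in self.by_row for i, (_, tid, _) in enumerate(self.by_row[row])
        }
        self._all = [
            (tid, pos) for row in self.by_row for (_, tid, pos) in self.by_row[row]
        ]

    def nearest_column(self, row: int, point: np.ndarray) -> tuple[int, bool]:
        """Rank of the nearest column of ``row`` by longitudinal projection.

        Returns ``(rank, tied)``; exact ties break toward the base (the
        larger projection, i.e. the more basal column).
        """
        line = self.frame.row_line(row)
        s = float((point - line.point) @ line.direction)
        entries = self.by_row[row]
        if not entries:
            raise DegenerateGeometryError(f"row {row} has no RL columns")
        d = np.abs(np.array([e[0] for e in entries]) - s)
        best = d.min()
        candidates = np.flatnonzero(np.isclose(d, best))
        tied = len(candidates) > 1
        return int(candidates[-1]), tied  # entries sorted ascending; last = most basal

    def partners_near(self, point: np.ndarray, radius_um: float) -> list[str]:
        """OHC apices within ``radius_um`` of a point, in the RL projection.

        Proximity is evaluated in the plane perpendicular to the BM normal
        (the lamina is a 2D mosaic; insertion depth is not part of
        abutment).
        """
        n = self.frame.bm.normal
        out = []
        for tid, pos in self._all:
            d = pos - point
            d = d - (d @ n) * n
            if np.linalg.norm(d) <= radius_um * NM_PER_UM:
                out.append(tid)
        return sorted(out)


def mosaic_span(
    php_tree: SkeletonTree,
    rl_lattice: RLLattice,
    own_ohc_id: str,
    partner_radius_um: float = 6.0,
) -> tuple[int, list[str], bool]:
    """RL mosaic span of one complex's phalangeal process.

    span = |column_rank(nearest RL column to the PhP insertion)
            - column_rank(own OHC column)| + 1, counted in the PhP's own
    row's column indexing.  Returns ``(span, partner_ids, tie_flag)``.
    """
    if PHP_TIP not in php_tree.landmarks:
        raise ValidationError(
            f"tree {php_tree.tree_id}: landmark {PHP_TIP!r} missing"
        )
    if own_ohc_id not in rl_lattice.rank:
        raise ValidationError(f"own OHC {own_ohc_id!r} absent from RL lattice")
    tip = php_tree.landmark_position(PHP_TIP)
    nearest, tied = rl_lattice.nearest_column(php_tree.row, tip)
    span = abs(nearest - rl_lattice.rank[own_ohc_id]) + 1
    partners = rl_lattice.partners_near(tip, partner_radius_um)
    return span, partners, tied


def _complex_pairs(annotation: AnnotationSet):
    """Pair DCs with OHCs sharing row and id suffix (OHC2_017 <-> DC2_017)."""
    ohcs = {t.tree_id: t for t in annotation.trees_of_class("OHC")}
    for dc in sorted(annotation.trees_of_class("DC"), key=lambda t: t.tree_id):
        ohc_id = "OHC" + dc.tree_id[len("DC"):]
        if ohc_id in ohcs:
            yield dc, ohcs[ohc_id]


SUMMARY_FIELDS = (
    "L_OHC", "L_PhP", "L_DC", "alpha", "beta_OHC", "beta_PhP", "beta_DC", "span"
)


def measure_all_yshapes(
    annotation: AnnotationSet,
    frame: ReferenceFrame,
    partner_radius_um: float = 6.0,
    consistency_tol_deg: float = 5.0,
):
    """Measure every complete OHC-DC complex.

    A complex is complete when its OHC carries basal-pole and
    cuticular-plate landmarks and its DC carries root, branch-point and
    apical-insertion landmarks; incomplete complexes are excluded and
    counted, mirroring an intact-complexes-only analysis.

    Returns ``(measures, table, summary, n_excluded)`` where ``table`` is
    one row per complex and ``summary`` holds per-row mean, SD and n for
    every measured field.
    """
    lattice = RLLattice(annotation, frame)
    radial = frame.radial_direction()
    measures: list[YShapeMeasure] = []
    n_excluded = 0
    for dc, ohc in _complex_pairs(annotation):
        needed = (
            OHC_BASE in ohc.landmarks
            and OHC_APEX in ohc.landmarks
            and all(k in dc.landmarks for k in (DC_ROOT, PHP_BRANCH, PHP_TIP))
        )
        if not needed:
            n_excluded += 1
            continue
        axis_ohc = principal_axis(ohc, OHC_BASE, OHC_APEX)
        axis_php = principal_axis(dc, PHP_BRANCH, PHP_TIP)
        axis_dc = principal_axis(dc, DC_ROOT, PHP_BRANCH)
        alpha = intersection_angle(axis_ohc, axis_php)
        b_ohc, b_ohc_p = longitudinal_angle(axis_ohc, frame, ohc.row)
        b_php, b_php_p = longitudinal_angle(axis_php, frame, dc.row)
        b_dc, b_dc_p = longitudinal_angle(axis_dc, frame, dc.row)
        # projected alpha: angle between the two axes after projection into
        # the longitudinal (row x normal) plane
        alpha_proj = abs(b_ohc_p - b_php_p)
        span, partners, tied = mosaic_span(dc, lattice, ohc.tree_id, partner_radius_um)
        flags = []
        if tied:
            flags.append("span_tie_broken_toward_base")
        near_plane = (
            abs(axis_ohc @ radial) < math.sin(math.radians(10.0))
            and abs(axis_php @ radial) < math.sin(math.radians(10.0))
        )
        if near_plane and abs((b_ohc - b_php) - alpha) > consistency_tol_deg:
            flags.append("alpha_beta_inconsistent")
        measures.append(
            YShapeMeasure(
                complex_id=dc.tree_id.replace("DC", "Y", 1),
                row=dc.row,
                L_OHC=path_length(ohc, OHC_BASE, OHC_APEX),
                L_PhP=path_length(dc, PHP_BRANCH, PHP_TIP),
                L_DC=path_length(dc, DC_ROOT, PHP_BRANCH),
                axis_OHC=axis_ohc,
                axis_PhP=axis_php,
                axis_DC=axis_dc,
                alpha=alpha,
                alpha_proj=alpha_proj,
                beta_OHC=b_ohc,
                beta_PhP=b_php,
                beta_DC=b_dc,
                beta_OHC_proj=b_ohc_p,
                beta_PhP_proj=b_php_p,
                beta_DC_proj=b_dc_p,
                span=span,
                partner_ids=partners,
                qc_flags=flags,
            )
        )
    table = pd.DataFrame(
        [
            {
                "complex_id": m.complex_id,
                "row": m.row,
                **{f: getattr(m, f) for f in SUMMARY_FIELDS},
                "alpha_proj": m.alpha_proj,
                "beta_OHC_proj": m.beta_OHC_proj,
                "beta_PhP_proj": m.beta_PhP_proj,
                "beta_DC_proj": m.beta_DC_proj,
                "partner_ids": ";".join(m.partner_ids),
                "qc_flags": ";".join(m.qc_flags),
            }
            for m in measures
        ]
    )
    if len(table):
        summary = (
            table.groupby("row")[list(SUMMARY_FIELDS)]
            .agg(["mean", "std", "count"])
            .rename(columns={"count": "n"})
        )
    else:
        summary = pd.DataFrame()
    return measures, table, summary, n_excluded


def measure_opc_angles(annotation: AnnotationSet, frame: ReferenceFrame):
    """Longitudinal angles of outer pillar cells, against row 1's line.

    OPCs abut row 1, so their beta is referenced to that row's fitted
    direction.  Returns a DataFrame (tree_id, beta_OPC, beta_OPC_proj).
    """
    rows = []
    for opc in sorted(annotation.trees_of_class("OPC"), key=lambda t: t.tree_id):
        if "opc_base" not in opc.landmarks or "opc_apex" not in opc.landmarks:
            continue
        axis = principal_axis(opc, "opc_base", "opc_apex")
        b, bp = longitudinal_angle(axis, frame, 1)
        rows.append({"tree_id": opc.tree_id, "beta_OPC": b, "beta_OPC_proj": bp})
    return pd.DataFrame(rows)
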