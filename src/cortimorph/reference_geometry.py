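"""Measurement reference frame: basilar-membrane plane and Deiters-cell row lines.

All angles and heights in the morphometry modules are measured against a
frame built from the annotation itself: the BM plane is the total-least-
squares plane through the Deiters-cell root landmarks (all three rows
pooled), each row's direction is the first principal axis of that row's
roots, and a configured ``basal_hint`` vector disambiguates which way
along the rows points toward the cochlear base.  The mid-cochlear segment
analysed here (~200 um) is treated as locally straight; no spiral
unrolling is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

NM_PER_UM = 1000.0


class DegenerateGeometryError(ValueError):
    """Raised when a fit is requested on insufficient or collapsed points."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateGeometryError("zero-length vector")
    return np.asarray(v, dtype=float) / n


@dataclass(frozen=True)
class Plane:
    """Oriented plane; ``normal`` points from the BM toward the reticular lamina."""

    point: np.ndarray  # (3,) nm
    normal: np.ndarray  # unit

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed perpendicular distance (nm) along the oriented normal."""
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass(frozen=True)
class RowLine:
    """Fitted line of one Deiters-cell row; direction points toward the base."""

    row: int
    point: np.ndarray  # (3,) nm
    direction: np.ndarray  # unit

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction))


@dataclass(frozen=True)
class ReferenceFrame:
    bm: Plane
    rows: dict[int, RowLine]
    basal_hint: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "basal_hint", np.asarray(self.basal_hint, float))
        if set(self.rows) != {1, 2, 3}:
            raise DegenerateGeometryError(
                f"reference frame requires rows 1-3, got {sorted(self.rows)}"
            )
        dirs = [self.rows[r].direction for r in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                ang = np.degrees(np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1)))
                if ang > 30.0:
                    raise DegenerateGeometryError(
                        f"row directions {i + 1} and {j + 1} diverge by {ang:.1f} deg"
                    )

    def row_line(self, row: int) -> RowLine:
        if row not in self.rows:
            raise KeyError(f"row {row} absent from reference frame")
        return self.rows[row]

    def radial_direction(self) -> np.ndarray:
        """Unit vector in the BM plane perpendicular to the rows (toward row 3)."""
        rad = np.cross(self.bm.normal, self.rows[1].direction)
        d = self.rows[3].point - self.rows[1].point
        return rad if rad @ d >= 0 else -rad

    def to_json(self, path=None) -> str:
        payload = {
            "bm": {"point": self.bm.point.tolist(), "normal": self.bm.normal.tolist()},
            "rows": {
                str(r): {
                    "point": line.point.tolist(),
                    "direction": line.direction.tolist(),
                }
                for r, line in sorted(self.rows.items())
            },
            "basal_hint": self.basal_hint.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReferenceFrame":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            bm=Plane(payload["bm"]["point"], payload["bm"]["normal"]),
            rows={
                int(r): RowLine(int(r), d["point"], d["direction"])
                for r, d in payload["rows"].items()
            },
            basal_hint=np.array(payload["basal_hint"]),
        )


def fit_bm_plane(
    dc_root_points, orientation_hint: np.ndarray | None = None
) -> Plane:
    """Total-least-squares plane through the Deiters-cell roots.

    The normal is the smallest principal component of the centred points;
    its sign is chosen so ``orientation_hint`` (e.g. the mean apical OHC
    landmark minus the centroid, or simply +z for the synthetic frame)
    lies on the positive side.
    """
    pts = np.atleast_2d(np.asarray(dc_root_points, dtype=float))
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(f"plane fit needs >= 3 points, got {pts.shape[0]}")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    if orientation_hint is not None and normal @ np.asarray(orientation_hint, float) < 0:
        normal = -normal
    return Plane(point=centroid, normal=normal)


def fit_row_line(dc_root_points_of_row, basal_hint, row: int = 0) -> RowLine:
    """First principal axis of one row's roots, oriented toward the base."""
    pts = np.atleast_2d(np.asarray(dc_root_points_of_row, dtype=float))
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("row-line fit needs >= 2 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError("all row points identical; line is undefined")
    direction = vt[0]
    if direction @ np.asarray(basal_hint, dtype=float) < 0:
        direction = -direction
    return RowLine(row=row, point=centroid, direction=direction)


def height_above_bm(point, bm: Plane) -> float:
    """Signed perpendicular height of a point above the BM plane, in um."""
    point = np.asarray(point, dtype=float)
    if point.shape != (3,) or not np.all(np.isfinite(point)):
        raise ValueError("height_above_bm expects a finite 3-vector")
    return float(bm.signed_distance(point)[0]) / NM_PER_UM


def build_reference_frame(
    annotation,
    basal_hint,
    root_landmark: str = "DC_root",
    apex_landmark: str = "cuticular_plate",
) -> ReferenceFrame:
    """Build the frame from an annotation's DC root landmarks.

    BM plane from all rooted DCs pooled; one line per row; plane normal
    oriented so the mean OHC apical landmark lies on the positive side.
    """
    roots_by_row: dict[int, list[np.ndarray]] = {1: [], 2: [], 3: []}
    for dc in annotation.trees_of_class("DC"):
        if root_landmark in dc.landmarks:
            roots_by_row[dc.row].append(dc.landmark_position(root_landmark))
    all_roots = [p for pts in roots_by_row.values() for p in pts]
    if len(all_roots) < 3:
        raise DegenerateGeometryError("not enough DC root landmarks for a BM plane")
    apices = [
        t.landmark_position(apex_landmark)
        for t in annotation.trees_of_class("OHC")
        if apex_landmark in t.landmarks
    ]
    hint = None
    if apices:
        hint = np.mean(apices, axis=0) - np.mean(all_roots, axis=0)
    bm = fit_bm_plane(all_roots, orientation_hint=hint)
    rows = {
        r: fit_row_line(pts, basal_hint, row=r) for r, pts in roots_by_row.items()
    }
    return ReferenceFrame(bm=bm, rows=rows, basal_hint=np.asarray(basal_hint, float))
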