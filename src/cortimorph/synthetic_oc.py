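"""Seeded synthetic organ-of-Corti generator with a ground-truth ledger.

The generator emits annotation sets (skeleton trees plus a contact
table) whose per-row geometry, trajectory and innervation statistics are
drawn from a configuration transcribed from published mid-cochlear
measurements (presets ``cba1`` and ``cba2``), so that every analysis
stage of the package can be exercised against known ground truth
without an EM volume.

Construction principles
-----------------------

* Deiters-cell roots sit on a jittered honeycomb over the basilar-
  membrane plane; per-complex lengths and angles are drawn from
  truncated Gaussians (+-4 SD).
* For each complex the sampled ``L_DC``/``beta_DC`` place the main
  trunk, ``L_OHC``/``beta_OHC`` the hair cell, and the phalangeal
  process is solved so that BOTH the sampled intersection angle alpha
  AND the row's mosaic-span rule (insertion at the apex column
  ``span - 1`` columns toward the base) hold exactly: the longitudinal
  component of the PhP direction is fixed by the span target and its
  radial (inter-row) component absorbs the remaining freedom.  The
  longitudinal PhP angle beta_PhP is therefore *emergent*; the
  generator reports its realized mean next to the configured reference
  value rather than forcing it.
* Skeleton nodes are placed at a configured spacing with smooth
  low-mode perpendicular bowing (so jitter does not inflate path
  lengths) and quantized to voxels.
* Type-2 fibers turn ~90 deg at the outer-pillar zone and follow a
  piecewise-linear height profile: sampled climbing slope up to a
  sampled plateau height, then the sampled contact slope past the first
  collateral.  Row-exclusive innervation is broken with the configured
  mixing probability.  Because a bounded segment cannot hold enough
  fully-contained fibers to reproduce the observed per-Deiters-cell
  fiber abundance, the generator adds boundary-truncated contact-free
  "passing" fiber segments whose per-row runs are solved from the
  configured abundance (they are excluded from innervation statistics
  by the zero-contact rule, exactly like truncated fibers in a real
  volume).
* MOC fibers cross the tunnel slab radially; the branched subtype count
  is ``round(branched_fraction * n)`` (deterministic), branched fibers
  carry >= 2 tunnel-crossing branches, and integer synapse counts come
  from a discretized Gaussian whose latent parameters are solved so the
  truncated distribution has exactly the configured mean and SD.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import optimize

from cortimorph.reference_geometry import NM_PER_UM
from cortimorph.skeleton_io import AnnotationSet, ContactRecord, SkeletonTree, VoxelPitch

RowStat = tuple[float, float]  # (mean, sd)


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class OCConfig:
    """Study conditions of one synthetic organ-of-Corti segment.

    All lengths in um, all angles in degrees unless noted.  Defaults are
    the CBA1 preset (mid-cochlear segment, 32 OHC columns x 3 rows).
    """

    name: str = "CBA1"
    # --- lattice -----------------------------------------------------
    n_columns: int = 32
    ohc_pitch_um: float = 6.8  # longitudinal OHC/DC column pitch
    row_spacing_um: float = 10.0
    opc_offset_um: float = -7.0  # OPC row radial offset from row 1
    opc_length_um: RowStat = (35.0, 1.5)
    voxel_pitch_nm: tuple[float, float, float] = (11.0, 11.0, 40.0)
    node_spacing_um: float = 1.0
    jitter_perp_um: float = 0.15  # smooth perpendicular bowing amplitude
    root_jitter_inplane_um: float = 0.3
    root_jitter_outplane_um: float = 0.2
    n_dropout: tuple[int, int, int] = (3, 2, 3)  # incomplete complexes per row
    # --- per-row Y-shape geometry (mean, sd) x rows 1..3 -------------
    L_OHC: tuple[RowStat, ...] = ((22.80, 0.80), (23.45, 1.05), (24.75, 1.06))
    L_PhP: tuple[RowStat, ...] = ((37.86, 2.11), (38.01, 2.90), (33.18, 1.51))
    L_DC: tuple[RowStat, ...] = ((33.65, 2.28), (32.57, 3.18), (36.61, 1.68))
    alpha: tuple[RowStat, ...] = ((45.58, 2.29), (36.09, 3.37), (30.22, 2.44))
    beta_DC: tuple[RowStat, ...] = ((91.77, 3.01), (86.38, 2.98), (78.73, 3.45))
    beta_OHC: tuple[RowStat, ...] = ((109.79, 3.07), (105.43, 2.92), (107.23, 3.35))
    #: reference values only; beta_PhP is emergent from span + alpha
    beta_PhP_ref: tuple[RowStat, ...] = ((61.45, 2.48), (66.58, 3.75), (75.01, 3.25))
    beta_OPC: RowStat = (101.04, 3.04)
    spans: tuple[int, int, int] = (4, 3, 2)
    #: longitudinal offset of the PhP tip from its target cuticular plate
    #: (negative = apical: the tip wedges in just before the abutting OHC)
    php_insertion_offset_um: float = -1.5
    # --- type-2 SGN fibers -------------------------------------------
    n_t2sgn: int = 40
    ohc_afferent_mean: tuple[float, float, float] = (2.39, 1.97, 2.03)
    ribbon_fraction: tuple[float, float, float] = (0.316, 0.311, 0.538)
    row_mixing_prob: float = 0.125
    climbing_slope: RowStat = (0.23, 0.07)  # dimensionless dz/dx
    contact_slope: RowStat = (0.02, 0.09)
    turn_height_um: RowStat = (13.0, 2.0)
    plateau_height_um: RowStat = (36.53, 3.0)
    contact_heights_um: tuple[RowStat, ...] = (
        (21.39, 3.06),  # on OPC (reference)
        (17.81, 5.23),  # on DC1
        (19.73, 5.64),  # on DC2
        (23.85, 6.68),  # on DC3
    )
    per_dc_abundance: tuple[float, float, float] | None = (20.4, 13.6, 7.6)
    fiber_row_offset_um: float = 1.2  # radial gap between fiber and DC row
    # --- MOC fibers ---------------------------------------------------
    n_moc: int = 70
    moc_branched_fraction: float = 0.243
    moc_branched_synapses: tuple[float, float, int, int] = (5.18, 2.30, 3, 11)
    moc_unbranched_synapses: tuple[float, float, int, int] = (2.26, 1.00, 1, 4)
    moc_branched_rows: tuple[float, float, float] = (0.400, 0.367, 0.233)
    moc_unbranched_rows: tuple[float, float, float] = (0.344, 0.353, 0.303)
    moc_modal_concentration: float = 0.7
    tc_zone_um: tuple[float, float] = (-22.0, -14.0)  # radial slab, rel. row 1
    basal_hint: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self):
        for fname in ("L_OHC", "L_PhP", "L_DC", "alpha", "beta_DC", "beta_OHC"):
            for mean, sd in getattr(self, fname):
                if sd < 0:
                    raise ConfigError(f"{fname}: negative SD")
                if fname.startswith("L") and mean - 4 * sd <= 0:
                    raise ConfigError(f"{fname}: config implies negative lengths")
        for probs in (self.moc_branched_rows, self.moc_unbranched_rows):
            if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1) > 1e-6:
                raise ConfigError(f"row probabilities {probs} must sum to 1")
        if not 0 <= self.row_mixing_prob <= 1:
            raise ConfigError("row_mixing_prob must be in [0, 1]")
        if not 0 <= self.moc_branched_fraction <= 1:
            raise ConfigError("moc_branched_fraction must be in [0, 1]")
        for r, (n_drop, span) in enumerate(zip(self.n_dropout, self.spans), start=1):
            if n_drop < span - 1:
                raise ConfigError(
                    f"row {r}: n_dropout must cover the {span - 1} basal edge "
                    "columns whose span target lies outside the lattice"
                )

    @property
    def extent_um(self) -> float:
        return self.n_columns * self.ohc_pitch_um

    @property
    def pitch(self) -> VoxelPitch:
        return VoxelPitch(*self.voxel_pitch_nm)

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "OCConfig":
        def tuplify(v):
            return tuple(tuplify(x) for x in v) if isinstance(v, (list, tuple)) else v

        return cls(**{k: tuplify(v) for k, v in payload.items()})

    def to_yaml(self, path=None) -> str:
        def listify(v):
            return [listify(x) for x in v] if isinstance(v, tuple) else v

        text = yaml.safe_dump(
            {k: listify(v) for k, v in self.to_dict().items()}, sort_keys=False
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "OCConfig":
        if isinstance(source, str) and "\n" in source:
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        return cls.from_dict(payload)


def load_preset(name: str) -> OCConfig:
    """Load a shipped preset configuration (``cba1`` or ``cba2``)."""
    path = resources.files("cortimorph").joinpath(f"presets/{name.lower()}.yaml")
    if not path.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    return OCConfig.from_dict(yaml.safe_load(path.read_text()))


def trajectory_config(config: OCConfig, n_fibers: int = 15) -> OCConfig:
    """Variant used for trajectory-focused runs: a small fully-profiled
    fiber cohort with abundance matching (and its truncated passing
    segments) disabled."""
    return replace(config, n_t2sgn=n_fibers, per_dc_abundance=None)


# ---------------------------------------------------------------------------
# ground-truth ledger
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthLedger:
    """Generator-side record of every sampled parameter (recovery oracle)."""

    config: dict
    seed: int
    bm_plane: dict = field(default_factory=dict)
    row_lines: dict = field(default_factory=dict)
    basal_hint: list = field(default_factory=list)
    complexes: dict = field(default_factory=dict)  # complex_id -> params
    opcs: dict = field(default_factory=dict)
    fibers: dict = field(default_factory=dict)  # fiber_id -> params
    mocs: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruthLedger":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(**payload)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, n_sigma=4.0, lo=None, hi=None):
    """Gaussian draw truncated at +-n_sigma SD (and optional hard bounds)."""
    if sd == 0:
        return mean
    lo_b = mean - n_sigma * sd if lo is None else max(lo, mean - n_sigma * sd)
    hi_b = mean + n_sigma * sd if hi is None else min(hi, mean + n_sigma * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo_b <= x <= hi_b:
            return x
    return float(np.clip(mean, lo_b, hi_b))


def discretized_gaussian_pmf(mean, sd, lo, hi):
    """Integer pmf on [lo, hi] with exactly the requested mean and SD.

    Maximum-entropy family ``p_k proportional to exp(a k + b k^2)``: for
    b < 0 this is a discretized Gaussian; solving (a, b) against the two
    moments removes the bias a plainly cut Gaussian would have on an
    asymmetric range, and the same family extends continuously to
    moment pairs a cut Gaussian cannot reach on a short support.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    kc = ks - ks.mean()  # centred for conditioning

    def pmf(a, b):
        logw = a * kc + b * kc**2
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def residual(params):
        p = pmf(*params)
        m = float(ks @ p)
        v = float(((ks - m) ** 2) @ p)
        return [m - mean, v - sd * sd]

    sol = optimize.root(residual, x0=[0.0, -1.0 / (2 * sd * sd)], method="hybr")
    p = pmf(*sol.x)
    m = float(ks @ p)
    s = float(np.sqrt(((ks - m) ** 2) @ p))
    if not sol.success or abs(m - mean) > 1e-6 or abs(s - sd) > 1e-6:
        raise ConfigError(
            f"no exponential-quadratic pmf on [{lo},{hi}] with mean {mean}, sd {sd}"
        )
    return ks.astype(int), p


# ---------------------------------------------------------------------------
# skeleton building blocks
# ---------------------------------------------------------------------------

class _TreeBuilder:
    """Accumulates trees with globally unique node ids and voxel snapping."""

    def __init__(self, config: OCConfig):
        self.aset = AnnotationSet(pitch=config.pitch, provenance=f"synthetic:{config.name}")
        self.factor = config.pitch.as_array()
        self._next = 1

    def new_tree(self, tree_id, cell_class, row) -> SkeletonTree:
        tree = SkeletonTree(tree_id=tree_id, cell_class=cell_class, row=row)
        self.aset.add_tree(tree)
        return tree

    def snap(self, pos_um: np.ndarray) -> np.ndarray:
        nm = np.asarray(pos_um, dtype=float) * NM_PER_UM
        return np.rint(nm / self.factor) * self.factor

    def add_chain(self, tree, points_um, attach_to=None) -> list[int]:
        """Add a polyline of nodes; returns node ids (first..last)."""
        ids = []
        prev = attach_to
        for p in points_um:
            nid = self._next
            self._next += 1
            tree.add_node(nid, self.snap(p))
            if prev is not None:
                tree.add_edge(prev, nid)
            prev = nid
            ids.append(nid)
        return ids


def _smooth_polyline(rng, start, end, spacing, perp_sigma, include_start=True):
    """Straight segment sampled at ~spacing with smooth low-mode bowing.

    Bowing is a two-mode sinusoid with zero endpoints, so path length is
    inflated only at second order (tortuosity stays ~1) while
    perpendicular positions scatter at the requested amplitude.
    """
    start, end = np.asarray(start, float), np.asarray(end, float)
    chord = end - start
    length = np.linalg.norm(chord)
    n = max(2, int(round(length / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + t[:, None] * chord[None, :]
    if perp_sigma > 0 and length > 0:
        d = chord / length
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        a = rng.normal(0.0, perp_sigma, size=2)
        b = rng.normal(0.0, 0.5 * perp_sigma, size=2)
        bow = (
            np.sin(np.pi * t)[:, None] * (a[0] * u + a[1] * v)[None, :]
            + np.sin(2 * np.pi * t)[:, None] * (b[0] * u + b[1] * v)[None, :]
        )
        pts = pts + bow
    return pts if include_start else pts[1:]


def _dir_in_xz(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return np.array([np.cos(a), 0.0, np.sin(a)])


# ---------------------------------------------------------------------------
# lattice generation
# ---------------------------------------------------------------------------

def generate_lattice(config: OCConfig, seed: int):
    """Generate the OHC/DC/OPC lattice; returns (AnnotationSet, ledger).

    Rows 1..3 lie at radial offsets 0, d, 2d over the z = 0 BM plane,
    columns run toward the cochlear base along +x at the configured
    pitch, honeycomb-staggered by half a pitch on row 2.  Complexes in
    the configured dropout columns are generated without the PhP apical
    insertion landmark (their process leaves the volume), mimicking
    edge-incomplete cells; their OHC apices still populate the RL
    lattice.
    """
    rng = np.random.default_rng(seed)
    builder = _TreeBuilder(config)
    ledger = GroundTruthLedger(config=config.to_dict(), seed=seed)
    ledger.bm_plane = {"point": [0.0, 0.0, 0.0], "normal": [0.0, 0.0, 1.0]}
    ledger.basal_hint = list(config.basal_hint)
    pitch = config.ohc_pitch_um
    spacing = config.node_spacing_um
    sigma = config.jitter_perp_um

    # roots, sampled per-complex geometry (two passes: the span target of a
    # complex is the *realized* apex of the OHC `span-1` columns basal)
    roots: dict[tuple[int, int], np.ndarray] = {}
    draws: dict[tuple[int, int], dict] = {}
    for row in (1, 2, 3):
        y = (row - 1) * config.row_spacing_um
        stagger = pitch / 2.0 if row == 2 else 0.0
        ledger.row_lines[str(row)] = {
            "point": [0.0, y, 0.0],
            "direction": [1.0, 0.0, 0.0],
        }
        for col in range(config.n_columns):
            jx, jy = rng.normal(0, config.root_jitter_inplane_um, size=2)
            jz = rng.normal(0, config.root_jitter_outplane_um)
            i = row - 1
            d = {
                "L_OHC": _trunc_normal(rng, *config.L_OHC[i]),
                "L_PhP": _trunc_normal(rng, *config.L_PhP[i]),
                "L_DC": _trunc_normal(rng, *config.L_DC[i]),
                "alpha": _trunc_normal(rng, *config.alpha[i]),
                "beta_DC": _trunc_normal(rng, *config.beta_DC[i]),
                "beta_OHC": _trunc_normal(rng, *config.beta_OHC[i]),
            }
            draws[(row, col)] = d
            # The reticular-lamina mosaic is the regular structure in the
            # epithelium: apical columns sit on the pitch grid and the
            # basal root positions absorb the per-cell tilt variation
            # (the root honeycomb keeps a correlated ~2 um scatter).
            tilt_dx = d["L_DC"] * np.cos(np.radians(d["beta_DC"])) + d[
                "L_OHC"
            ] * np.cos(np.radians(d["beta_OHC"]))
            roots[(row, col)] = np.array(
                [col * pitch + stagger - tilt_dx + jx, y + jy, jz]
            )

    basal_offset = np.array([0.0, 0.8, 0.5])  # DC cup -> OHC basal pole
    apex: dict[tuple[int, int], np.ndarray] = {}
    branch: dict[tuple[int, int], np.ndarray] = {}
    for key, d in draws.items():
        b = roots[key] + d["L_DC"] * _dir_in_xz(d["beta_DC"])
        branch[key] = b
        apex[key] = b + basal_offset + d["L_OHC"] * _dir_in_xz(d["beta_OHC"])

    incomplete = _incomplete_columns(config)
    for row in (1, 2, 3):
        span = config.spans[row - 1]
        for col in range(config.n_columns):
            key = (row, col)
            d = draws[key]
            target_col = col + span - 1
            target_key = (row, target_col)
            if target_key in apex:
                target_x = apex[target_key][0] + config.php_insertion_offset_um
            else:  # edge cell: extrapolate a virtual column (truncated anyway)
                target_x = (
                    apex[(row, config.n_columns - 1)][0]
                    + (target_col - config.n_columns + 1) * pitch
                    + config.php_insertion_offset_um
                )
            d.update(_solve_php(rng, config, row, d, branch[key], target_x))
            d["span"] = span
            d["complete"] = col not in incomplete[row]
            _build_complex(builder, rng, config, row, col, roots[key], branch[key],
                           apex[key], basal_offset, d)
            ledger.complexes[f"Y{row}_{col:03d}"] = {
                "row": row, "col": col, **{k: v for k, v in d.items()},
                "root": roots[key].tolist(), "branch": branch[key].tolist(),
                "apex": apex[key].tolist(),
            }

    # outer pillar cells (radially before row 1, tilted like OHCs)
    for col in range(config.n_columns):
        beta = _trunc_normal(rng, *config.beta_OPC)
        length = _trunc_normal(rng, *config.opc_length_um)
        base = np.array(
            [
                col * pitch + rng.normal(0, config.root_jitter_inplane_um),
                config.opc_offset_um + rng.normal(0, config.root_jitter_inplane_um),
                rng.normal(0, config.root_jitter_outplane_um),
            ]
        )
        top = base + length * _dir_in_xz(beta)
        tree = builder.new_tree(f"OPC1_{col:03d}", "OPC", 1)
        ids = builder.add_chain(tree, _smooth_polyline(rng, base, top, spacing, sigma))
        tree.landmarks["opc_base"] = ids[0]
        tree.landmarks["opc_apex"] = ids[-1]
        ledger.opcs[tree.tree_id] = {"beta_OPC": beta, "length": length}

    builder.aset.validate()
    return builder.aset, ledger, builder


def _incomplete_columns(config: OCConfig) -> dict[int, set[int]]:
    out = {}
    for row in (1, 2, 3):
        span, n_drop = config.spans[row - 1], config.n_dropout[row - 1]
        forced = set(range(config.n_columns - (span - 1), config.n_columns))
        extra = n_drop - len(forced)
        out[row] = forced | set(range(extra))
    return out


def _solve_php(rng, config: OCConfig, row: int, d: dict, branch_pos, target_x):
    """PhP direction with exact alpha and exact span-target insertion.

    dx is fixed by the longitudinal distance to the target apex column,
    dz by the sampled alpha against the OHC axis, and the radial
    component dy takes up the slack.  Infeasible draws (the extreme
    small-alpha / short-PhP corner) resample alpha and L_PhP.
    """
    i = row - 1
    o = _dir_in_xz(d["beta_OHC"])
    alpha, L_php = d["alpha"], d["L_PhP"]
    for attempt in range(200):
        dx = (target_x - branch_pos[0]) / L_php
        dz = (np.cos(np.radians(alpha)) - dx * o[0]) / o[2]
        rest = 1.0 - dx * dx - dz * dz
        if rest >= 0.0 and dz > 0.0:
            dy = np.sqrt(rest)  # radially outward
            d["alpha"], d["L_PhP"] = alpha, L_php
            return {"php_dir": [dx, dy, dz]}
        alpha = _trunc_normal(rng, *config.alpha[i])
        L_php = _trunc_normal(rng, *config.L_PhP[i])
    # degenerate fallback: planar PhP, alpha becomes emergent
    dx = np.clip((target_x - branch_pos[0]) / L_php, -0.99, 0.99)
    dz = np.sqrt(1 - dx * dx)
    d["alpha"] = float(np.degrees(np.arccos(np.clip(dx * o[0] + dz * o[2], -1, 1))))
    d["L_PhP"] = L_php
    return {"php_dir": [dx, 0.0, dz]}


def _build_complex(builder, rng, config, row, col, root, branch_pos, apex_pos,
                   basal_offset, d):
    spacing, sigma = config.node_spacing_um, config.jitter_perp_um
    ohc = builder.new_tree(f"OHC{row}_{col:03d}", "OHC", row)
    basal = branch_pos + basal_offset
    ids = builder.add_chain(
        ohc, _smooth_polyline(rng, basal, apex_pos, spacing, sigma)
    )
    ohc.landmarks["basal_pole"] = ids[0]
    ohc.landmarks["cuticular_plate"] = ids[-1]

    dc = builder.new_tree(f"DC{row}_{col:03d}", "DC", row)
    trunk_ids = builder.add_chain(
        dc, _smooth_polyline(rng, root, branch_pos, spacing, sigma)
    )
    php_dir = np.asarray(d["php_dir"])
    tip = branch_pos + d["L_PhP"] * php_dir
    if not d["complete"]:
        tip = branch_pos + 0.6 * d["L_PhP"] * php_dir  # truncated at the edge
    php_ids = builder.add_chain(
        dc,
        _smooth_polyline(rng, branch_pos, tip, spacing, sigma, include_start=False),
        attach_to=trunk_ids[-1],
    )
    dc.landmarks["DC_root"] = trunk_ids[0]
    dc.landmarks["PhP_branch_point"] = trunk_ids[-1]
    if d["complete"]:
        dc.landmarks["PhP_apical_insertion"] = php_ids[-1]
    d["php_tip"] = tip.tolist()
    d["beta_PhP_emergent"] = float(np.degrees(np.arccos(np.clip(php_dir[0], -1, 1))))


# ---------------------------------------------------------------------------
# type-2 SGN fibers
# ---------------------------------------------------------------------------

def generate_t2sgn(config: OCConfig, builder: _TreeBuilder, ledger: GroundTruthLedger,
                   rng: np.random.Generator):
    """Generate type-2 fibers, their collaterals and afferent contacts."""
    pitch, spacing, sigma = config.ohc_pitch_um, config.node_spacing_um, config.jitter_perp_um
    D = config.extent_um
    y_row = {r: (r - 1) * config.row_spacing_um for r in (1, 2, 3)}
    off = config.fiber_row_offset_um
    totals = [m * config.n_columns for m in config.ohc_afferent_mean]
    k_bar = sum(totals) / config.n_t2sgn
    n_home = _apportion([t / k_bar for t in totals], config.n_t2sgn)
    homes = [r for r in (1, 2, 3) for _ in range(n_home[r - 1])]
    rng.shuffle(homes)

    # per-row ladders of realized DC-root and OHC-base longitudinal
    # positions (roots are tilt-shifted relative to the apical grid)
    root_x = {
        r: np.array(
            [ledger.complexes[f"Y{r}_{c:03d}"]["root"][0] for c in range(config.n_columns)]
        )
        for r in (1, 2, 3)
    }
    base_x = {
        r: np.array(
            [
                ledger.complexes[f"Y{r}_{c:03d}"]["branch"][0]
                + 2.0 * np.cos(np.radians(ledger.complexes[f"Y{r}_{c:03d}"]["beta_OHC"]))
                for c in range(config.n_columns)
            ]
        )
        for r in (1, 2, 3)
    }

    #: realized row-run intervals (transitions excluded) for abundance accounting
    run_intervals: dict[int, list[tuple[float, float]]] = {1: [], 2: [], 3: []}

    for i, home in enumerate(homes):
        fiber_intervals: dict[int, list[tuple[float, float]]] = {}
        fid = f"T2SGN_{i:03d}"
        m_c = _trunc_normal(rng, *config.climbing_slope, lo=0.08, hi=0.45)
        m_s = _trunc_normal(rng, *config.contact_slope, lo=-0.20, hi=0.25)
        h0 = _trunc_normal(rng, *config.turn_height_um, lo=6.0, hi=20.0)
        h_plateau = _trunc_normal(rng, *config.plateau_height_um, lo=26.0, hi=46.0)
        k_mean = totals[home - 1] / max(1, n_home[home - 1])
        k_max = max(2, int((D - 12.0) / pitch) - 1)
        k = int(np.clip(round(rng.normal(k_mean, 1.0)), 2, k_max))
        contact_run = (k + 0.8) * pitch
        climb_run = (h_plateau - h0) / m_c
        climb_run = float(np.clip(climb_run, 25.0, 2.0 * D))
        # Place the breakpoint uniformly over the segment so per-column
        # fiber coverage is flat, as it is in a boundary-truncated
        # window of a much longer epithelium: fibers whose climb starts
        # before the segment simply turn outside it.
        x_b_target = rng.uniform(3.0, max(3.5, D - contact_run - 3.0))
        x0 = x_b_target - climb_run

        tree = builder.new_tree(fid, "T2SGN", None)
        if x0 >= 1.0:
            # approach: cross the tunnel floor, round the nearest outer
            # pillar cell and turn sharply toward the base right past it
            opc_col = int(np.clip(round((x0 + 1.9) / pitch), 0, config.n_columns - 1))
            opc_entry = ledger.opcs[f"OPC1_{opc_col:03d}"]
            cot_opc = 1.0 / np.tan(np.radians(opc_entry["beta_OPC"]))
            x_opc_mid = opc_col * pitch + 0.75 * h0 * cot_opc
            x_opc_turn = opc_col * pitch + h0 * cot_opc
            waypoint = np.array(
                [x_opc_mid + rng.normal(0, 0.3), config.opc_offset_um - 1.0, 0.75 * h0]
            )
            turn_pt = np.array([x_opc_turn, config.opc_offset_um + 1.0, h0])
            pre1 = _smooth_polyline(
                rng,
                np.array([x0, config.opc_offset_um - 6.0, 0.45 * h0]),
                waypoint, spacing, 0.5 * sigma,
            )
            pre2 = _smooth_polyline(
                rng, waypoint, turn_pt, spacing, 0.3 * sigma, include_start=False
            )
            ids = builder.add_chain(tree, np.vstack([pre1, pre2]))
        else:
            # turn lies before the imaged segment: short radial stub
            turn_pt = np.array([x0, config.opc_offset_um + 1.0, h0])
            pre = _smooth_polyline(
                rng,
                np.array([x0, config.opc_offset_um - 5.0, 0.6 * h0]),
                turn_pt, spacing, 0.3 * sigma,
            )
            ids = builder.add_chain(tree, pre)
        tree.landmarks["turn"] = ids[-1]
        turn_xyz = turn_pt.copy()

        # climbing region across rows 1..home, z linear in x with slope m_c
        def z_climb(x):
            return h0 + m_c * (x - x0)

        n_seg = home
        seg_len = climb_run / n_seg
        x_cursor = x0
        last = ids[-1]
        trans = min(2.5, 0.4 * seg_len)
        for s, r in enumerate(range(1, home + 1)):
            y_r = y_row[r] - off
            if s == 0:
                p_in = np.array([x_cursor, y_r, z_climb(x_cursor)])
                approach = _smooth_polyline(
                    rng, turn_pt, p_in, spacing, 0.0, include_start=False
                )
                last = builder.add_chain(tree, approach, attach_to=last)[-1]
            x_end = x_cursor + seg_len - (trans if s < n_seg - 1 else 0.0)
            run_intervals[r].append((x_cursor, x_end))
            fiber_intervals.setdefault(r, []).append((x_cursor, x_end))
            pts = _smooth_polyline(
                rng,
                np.array([x_cursor, y_r, z_climb(x_cursor)]),
                np.array([x_end, y_r, z_climb(x_end)]),
                spacing, sigma, include_start=False,
            )
            last = builder.add_chain(tree, pts, attach_to=last)[-1]
            if s < n_seg - 1:
                y_next = y_row[r + 1] - off
                pts = _smooth_polyline(
                    rng,
                    np.array([x_end, y_r, z_climb(x_end)]),
                    np.array([x_end + trans, y_next, z_climb(x_end + trans)]),
                    spacing, 0.0, include_start=False,
                )
                last = builder.add_chain(tree, pts, attach_to=last)[-1]
                x_cursor = x_end + trans
            else:
                x_cursor = x_end

        # OHC-contact region on the home row; collateral targets are the
        # first k columns whose OHC base lies past the breakpoint
        x_b = x_cursor
        z_b = z_climb(x_b)
        c0 = int(np.clip(
            np.searchsorted(base_x[home], x_b + 0.5), 0, config.n_columns - k
        ))
        x_e = float(base_x[home][c0 + k - 1] + 1.5)
        if x_e <= x_b + 2.0:
            x_e = x_b + 2.0 + k * pitch

        def z_contact(x):
            return z_b + m_s * (x - x_b)

        y_h = y_row[home] - off
        run_intervals[home].append((x_b, x_e))
        fiber_intervals.setdefault(home, []).append((x_b, x_e))
        pts = _smooth_polyline(
            rng, np.array([x_b, y_h, z_b]), np.array([x_e, y_h, z_contact(x_e)]),
            spacing, sigma, include_start=False,
        )
        contact_ids = builder.add_chain(tree, pts, attach_to=last)
        tree.landmarks["fiber_end"] = contact_ids[-1]

        target_cols = list(range(c0, c0 + k))
        target_rows = [home] * k
        mixed = bool(rng.random() < config.row_mixing_prob)
        if mixed and k >= 2:
            neighbours = [r for r in (home - 1, home + 1) if 1 <= r <= 3]
            other = int(rng.choice(neighbours))
            n_mix = int(rng.integers(1, k))
            for j in rng.choice(k, size=n_mix, replace=False):
                target_rows[j] = other
        contacts = []
        trunk_pts = builder.aset.trees[fid].positions(contact_ids) / NM_PER_UM
        for c_i, (col, r) in enumerate(zip(target_cols, target_rows)):
            key = f"Y{r}_{col:03d}"
            cx = ledger.complexes[key]
            ohc_id = f"OHC{r}_{col:03d}"
            basal = np.array(cx["branch"]) + np.array([0.0, 0.8, 0.5])
            contact_pt = basal + 2.0 * _dir_in_xz(cx["beta_OHC"]) + np.array([0.0, -0.4, 0.0])
            # first collateral leaves at the very start of the contact
            # region, so the anatomical breakpoint and the slope change
            # coincide; later collaterals leave near their target column
            if c_i == 0:
                j = 0
            else:
                j = int(np.argmin(np.abs(trunk_pts[:, 0] - contact_pt[0])))
            origin_id = contact_ids[j]
            branch_pts = _smooth_polyline(
                rng, trunk_pts[j], contact_pt, spacing, 0.5 * sigma, include_start=False
            )
            bouton = builder.add_chain(tree, branch_pts, attach_to=origin_id)[-1]
            is_ribbon = rng.random() < config.ribbon_fraction[r - 1]
            cls = "afferent_ribbon" if is_ribbon else "afferent_ribbonless"
            builder.aset.contacts.append(
                ContactRecord(
                    fiber_id=fid, target_id=ohc_id, bouton_class=cls,
                    position=builder.snap(contact_pt), contact_node=bouton,
                )
            )
            contacts.append({"target": ohc_id, "row": r, "class": cls})

        ledger.fibers[fid] = {
            "home_row": home, "complete": True, "mixed_rows": mixed,
            "climbing_slope": m_c, "contact_slope": m_s,
            "turn_height": h0, "turn_xyz": turn_xyz.tolist(),
            "breakpoint_x": x_b, "n_contacts": k, "contacts": contacts,
            "row_intervals": {str(r): iv for r, iv in fiber_intervals.items()},
        }

    if config.per_dc_abundance is not None:
        _add_passing_fibers(
            config, builder, ledger, rng, run_intervals, root_x, y_row, off
        )


def _apportion(weights, total):
    """Largest-remainder rounding of nonnegative weights to a fixed sum."""
    base = [int(np.floor(w)) for w in weights]
    rem = total - sum(base)
    order = np.argsort([b - w for b, w in zip(base, weights)])
    for j in order[:rem]:
        base[j] += 1
    return base


def _add_passing_fibers(config, builder, ledger, rng, run_intervals, root_x,
                        y_row, off):
    """Boundary-truncated contact-free fiber segments filling the
    configured per-DC abundance.

    The coverage already realized by the complete fibers is counted with
    the analyzer's own attachment rule (nearest Deiters trunk within the
    attachment radius), then the per-row deficit against the configured
    mean is covered by passing segments spanning whole or partial column
    ranges, as truncated through-going fibers would in a real volume.
    Passing segments are laid out against the trunk positions at their
    own height, so every column they span is attachable.
    """
    from scipy.spatial import cKDTree

    pitch = config.ohc_pitch_um
    spacing, sigma = config.node_spacing_um, config.jitter_perp_um
    radius_nm = 2.0 * NM_PER_UM

    # trunk point cloud of all Deiters cells (root -> branch path)
    pts, labels = [], []
    for r in (1, 2, 3):
        for c in range(config.n_columns):
            dc = builder.aset.trees[f"DC{r}_{c:03d}"]
            ids = dc.path_between(
                dc.landmarks["DC_root"], dc.landmarks["PhP_branch_point"]
            )
            p = dc.positions(ids)
            pts.append(p)
            labels.extend([(r, c)] * len(p))
    tree_index = cKDTree(np.vstack(pts))

    covered: dict[int, set] = {1: set(), 2: set(), 3: set()}
    for fid, entry in ledger.fibers.items():
        if not entry["complete"]:
            continue
        fiber = builder.aset.trees[fid]
        path = fiber.path_between(
            fiber.landmarks["turn"], fiber.landmarks["fiber_end"]
        )
        dist, idx = tree_index.query(fiber.positions(path), k=1)
        for d, j in zip(dist, idx):
            if d <= radius_nm:
                r, c = labels[j]
                covered[r].add((fid, c))

    idx_f = len(ledger.fibers)
    for r in (1, 2, 3):
        n_cols = config.n_columns
        target = config.per_dc_abundance[r - 1] * n_cols
        per_col = np.zeros(n_cols)
        for _, c in covered[r]:
            per_col[c] += 1
        deficit_total = max(0.0, target - per_col.sum())
        # water-filling: added coverage goes to the least-covered cells
        # first, which keeps the per-cell profile as flat as additions
        # allow (through-going segments cannot remove existing overlap)
        add = np.zeros(n_cols, dtype=int)
        if deficit_total >= 1:
            level = per_col.copy()
            for _ in range(int(round(deficit_total))):
                j = int(np.argmin(level))
                add[j] += 1
                level[j] += 1
        jobs = []
        work = add.copy()
        while work.any():
            in_run = False
            for c in range(n_cols + 1):
                if c < n_cols and work[c] > 0:
                    if not in_run:
                        s0, in_run = c, True
                else:
                    if in_run:
                        jobs.append((s0, c - s0))
                        work[s0:c] -= 1
                        in_run = False
        z_mean = config.contact_heights_um[r][0]  # index r = DC-row-r entry
        for s, cols in jobs:
            if cols < 1:
                continue
            fid = f"T2SGN_{idx_f:03d}"
            idx_f += 1
            z0 = _trunc_normal(rng, z_mean, 2.5, lo=6.0, hi=28.0)
            # trunk longitudinal position at the segment's own height
            led = [ledger.complexes[f"Y{r}_{c:03d}"] for c in range(s, s + cols)]
            tx = [
                e["root"][0] + z0 / np.tan(np.radians(e["beta_DC"])) for e in led
            ]
            lo, hi = float(min(tx) - 2.0), float(max(tx) + 2.0)
            y_r = y_row[r] - off
            tree = builder.new_tree(fid, "T2SGN", None)
            pts_f = _smooth_polyline(
                rng, np.array([lo, y_r, z0]), np.array([hi, y_r, z0]),
                spacing, 0.5 * sigma,
            )
            ids = builder.add_chain(tree, pts_f)
            # entry node stands in for the turn on truncated segments
            tree.landmarks["turn"] = ids[0]
            tree.landmarks["fiber_end"] = ids[-1]
            ledger.fibers[fid] = {
                "home_row": r, "complete": False, "mixed_rows": False,
                "n_contacts": 0, "contacts": [],
                "row_intervals": {str(r): [(lo, hi)]},
            }


# ---------------------------------------------------------------------------
# MOC fibers
# ---------------------------------------------------------------------------

def generate_moc(config: OCConfig, builder: _TreeBuilder, ledger: GroundTruthLedger,
                 rng: np.random.Generator):
    """Generate MOC efferent fibers and their boutons on OHC basal poles."""
    pitch, spacing, sigma = config.ohc_pitch_um, config.node_spacing_um, config.jitter_perp_um
    D = config.extent_um
    lo, hi = config.tc_zone_um
    n = config.n_moc
    n_branched = int(round(config.moc_branched_fraction * n))
    subtypes = ["branched"] * n_branched + ["unbranched"] * (n - n_branched)
    rng.shuffle(subtypes)
    pmfs = {
        "branched": discretized_gaussian_pmf(*config.moc_branched_synapses),
        "unbranched": discretized_gaussian_pmf(*config.moc_unbranched_synapses),
    }
    row_probs = {
        "branched": np.array(config.moc_branched_rows),
        "unbranched": np.array(config.moc_unbranched_rows),
    }

    for i, subtype in enumerate(subtypes):
        fid = f"MOC_{i:03d}"
        ks, pmf = pmfs[subtype]
        n_syn = int(rng.choice(ks, p=pmf))
        probs = row_probs[subtype]
        if subtype == "branched":
            modal = int(rng.choice([1, 2, 3], p=probs))
            others = [r for r in (1, 2, 3) if r != modal]
            q = probs[[r - 1 for r in others]]
            q = q / q.sum()
            syn_rows = [
                modal
                if rng.random() < config.moc_modal_concentration
                else int(rng.choice(others, p=q))
                for _ in range(n_syn)
            ]
            n_cross = 2 if rng.random() < 0.75 else 3
        else:
            syn_rows = [int(rng.choice([1, 2, 3], p=probs)) for _ in range(n_syn)]
            n_cross = 1

        x_f = rng.uniform(6.0, D - 6.0)
        z_f = rng.uniform(26.0, 31.0)
        tree = builder.new_tree(fid, "MOC", None)
        trunk = _smooth_polyline(
            rng,
            np.array([x_f, lo - 12.0, z_f]),
            np.array([x_f, lo - 2.0, z_f]),
            spacing, sigma,
        )
        fork = builder.add_chain(tree, trunk)[-1]
        fork_pt = trunk[-1]

        # split synapses over crossing branches
        groups = [syn_rows[j::n_cross] for j in range(n_cross)]
        x_offsets = [0.0] if n_cross == 1 else list(
            rng.uniform(4.0, 12.0) * np.linspace(-1, 1, n_cross)
        )
        crossings = 0
        for j, (grp, dx) in enumerate(zip(groups, x_offsets)):
            x_b = float(np.clip(x_f + dx, 3.0, D - 3.0))
            land = np.array([x_b, hi + 3.0, z_f + rng.uniform(-1, 1)])
            pts = _smooth_polyline(rng, fork_pt, land, spacing, sigma, include_start=False)
            last = builder.add_chain(tree, pts, attach_to=fork)
            crossings += 1
            branch_head, head_pt = last[-1], land
            if subtype == "unbranched" and len(grp) >= 2 and rng.random() < 0.5:
                # post-slab bifurcation: must NOT affect the crossing count
                mid = head_pt + np.array([rng.uniform(-3, 3), 4.0, 0.0])
                last_m = builder.add_chain(
                    tree,
                    _smooth_polyline(rng, head_pt, mid, spacing, sigma, include_start=False),
                    attach_to=branch_head,
                )
                heads = [(branch_head, head_pt), (last_m[-1], mid)]
            else:
                heads = [(branch_head, head_pt)]
            for s_i, r in enumerate(grp):
                col = int(
                    np.clip(round(x_b / pitch) + (s_i - len(grp) // 2), 0,
                            config.n_columns - 1)
                )
                cx = ledger.complexes[f"Y{r}_{col:03d}"]
                basal = np.array(cx["branch"]) + np.array([0.0, 0.8, 0.5])
                contact_pt = basal + 1.2 * _dir_in_xz(cx["beta_OHC"]) + np.array(
                    [0.0, -0.5, 0.0]
                )
                head_id, hp = heads[s_i % len(heads)]
                pts = _smooth_polyline(
                    rng, hp, contact_pt, spacing, 0.5 * sigma, include_start=False
                )
                bouton = builder.add_chain(tree, pts, attach_to=head_id)[-1]
                builder.aset.contacts.append(
                    ContactRecord(
                        fiber_id=fid, target_id=f"OHC{r}_{col:03d}",
                        bouton_class="efferent",
                        position=builder.snap(contact_pt), contact_node=bouton,
                    )
                )
        ledger.mocs[fid] = {
            "subtype": subtype, "n_crossings": crossings, "n_synapses": n_syn,
            "rows": syn_rows,
        }


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_annotation(config: OCConfig, seed: int):
    """Full synthetic annotation set (lattice + fibers) and its ledger.

    Identical config and seed yield identical output, byte-for-byte
    once written.  The lattice, fiber and MOC stages draw from
    independent child streams of ``seed`` so that, e.g., enlarging the
    fiber cohort does not perturb the lattice.
    """
    aset, ledger, builder = generate_lattice(config, seed)
    generate_t2sgn(
        config, builder, ledger, np.random.default_rng(np.random.SeedSequence([seed, 1]))
    )
    generate_moc(
        config, builder, ledger, np.random.default_rng(np.random.SeedSequence([seed, 2]))
    )
    aset.validate()
    return aset, ledger
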