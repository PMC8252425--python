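"""Reading, writing and validation of skeleton annotations and contact tables.

Skeletons follow the webKNOSSOS NML dialect (XML trees of nodes/edges with
integer voxel coordinates) or standard 7-column SWC.  All coordinates are
converted to physical nanometres on read by component-wise multiplication
with the voxel pitch (0-based voxel index times pitch = node centre).
Internally everything is nanometres; reporting layers convert to
micrometres and degrees.

Tree names encode cell class and row through a configurable grammar,
``<CLASS><row>_<id>`` by default (``OHC2_017``, ``MOC_007``).  Landmarks
(named anatomical reference nodes such as the Deiters-cell root or the
phalangeal-process apical insertion) travel as node comments with the
reserved prefix ``landmark:``; SWC, which has no comment channel, carries
them in a sidecar table.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from lxml import etree

logger = logging.getLogger(__name__)

CELL_CLASSES = ("OHC", "DC", "OPC", "T2SGN", "MOC")
#: classes whose trees must carry a row label
ROWED_CLASSES = ("OHC", "DC", "OPC")
AFFERENT_CLASSES = ("afferent_ribbon", "afferent_ribbonless")
BOUTON_CLASSES = AFFERENT_CLASSES + ("efferent",)

#: default tree-naming grammar: class, optional row digit, underscore, id
DEFAULT_NAME_GRAMMAR = re.compile(r"^(OHC|DC|OPC|T2SGN|MOC)([1-3])?_(\w+)$")

LANDMARK_PREFIX = "landmark:"


class AnnotationError(ValueError):
    """Base class for annotation I/O and validation failures."""


class ParseError(AnnotationError):
    """Malformed input file."""


class ValidationError(AnnotationError):
    """Structurally invalid annotation (non-tree graph, dangling ids...)."""


@dataclass(frozen=True)
class VoxelPitch:
    """Physical length of one voxel step along each axis, in nm."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if not all(p > 0 and np.isfinite(p) for p in (self.dx, self.dy, self.dz)):
            raise ValidationError(f"voxel pitch must be strictly positive, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass
class SkeletonNode:
    node_id: int
    position: np.ndarray  # (3,) nm
    radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"node {self.node_id}: position must be a finite 3-vector"
            )


@dataclass
class SkeletonTree:
    """Node/edge graph of one cell or fiber, with class/row labels and landmarks."""

    tree_id: str
    cell_class: str | None
    row: int | None
    nodes: dict[int, SkeletonNode] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    landmarks: dict[str, int] = field(default_factory=dict)

    def add_node(self, node_id: int, position, radius: float | None = None) -> None:
        if node_id in self.nodes:
            raise ValidationError(f"tree {self.tree_id}: duplicate node id {node_id}")
        self.nodes[node_id] = SkeletonNode(node_id, position, radius)

    def add_edge(self, a: int, b: int) -> None:
        self.edges.add((a, b) if a <= b else (b, a))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def positions(self, node_ids=None) -> np.ndarray:
        ids = sorted(self.nodes) if node_ids is None else list(node_ids)
        return np.array([self.nodes[i].position for i in ids], dtype=float)

    def landmark_position(self, name: str) -> np.ndarray:
        if name not in self.landmarks:
            raise ValidationError(f"tree {self.tree_id}: landmark {name!r} not present")
        return self.nodes[self.landmarks[name]].position

    def path_between(self, a: int, b: int) -> list[int]:
        """Node ids along the unique tree path from ``a`` to ``b``."""
        return nx.shortest_path(self.graph(), a, b)

    def validate(self) -> None:
        dangling = sorted(
            {i for e in self.edges for i in e if i not in self.nodes}
        )
        if dangling:
            raise ValidationError(
                f"tree {self.tree_id}: edges cite absent node ids {dangling}"
            )
        if self.nodes:
            g = self.graph()
            if not nx.is_connected(g):
                raise ValidationError(f"tree {self.tree_id}: graph is disconnected")
            if g.number_of_edges() != g.number_of_nodes() - 1:
                raise ValidationError(f"tree {self.tree_id}: graph contains a cycle")
        for name, nid in self.landmarks.items():
            if nid not in self.nodes:
                raise ValidationError(
                    f"tree {self.tree_id}: landmark {name!r} refers to absent node {nid}"
                )
        if self.cell_class in ROWED_CLASSES and self.row not in (1, 2, 3):
            raise ValidationError(
                f"tree {self.tree_id}: class {self.cell_class} requires a row label 1-3"
            )


@dataclass
class ContactRecord:
    """One fiber->OHC synaptic contact (a bouton annotation)."""

    fiber_id: str
    target_id: str
    bouton_class: str
    position: np.ndarray  # (3,) nm
    contact_node: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.bouton_class not in BOUTON_CLASSES:
            raise ValidationError(f"unknown bouton class {self.bouton_class!r}")


@dataclass
class AnnotationSet:
    pitch: VoxelPitch
    trees: dict[str, SkeletonTree] = field(default_factory=dict)
    contacts: list[ContactRecord] = field(default_factory=list)
    provenance: str = ""

    def add_tree(self, tree: SkeletonTree) -> None:
        if tree.tree_id in self.trees:
            raise ValidationError(f"duplicate tree id {tree.tree_id}")
        self.trees[tree.tree_id] = tree

    def trees_of_class(self, cell_class: str, row: int | None = None):
        return [
            t
            for t in self.trees.values()
            if t.cell_class == cell_class and (row is None or t.row == row)
        ]

    def validate(self) -> None:
        for tree in self.trees.values():
            tree.validate()
        for i, c in enumerate(self.contacts):
            self._validate_contact(c, where=f"contact #{i}")

    def _validate_contact(self, c: ContactRecord, where: str = "contact") -> None:
        if c.fiber_id not in self.trees:
            raise ValidationError(f"{where}: unknown fiber {c.fiber_id!r}")
        if c.target_id not in self.trees:
            raise ValidationError(f"{where}: unknown target {c.target_id!r}")
        fiber_class = self.trees[c.fiber_id].cell_class
        if c.bouton_class in AFFERENT_CLASSES and fiber_class != "T2SGN":
            raise ValidationError(
                f"{where}: afferent bouton on a {fiber_class} fiber {c.fiber_id!r}"
            )
        if c.bouton_class == "efferent" and fiber_class != "MOC":
            raise ValidationError(
                f"{where}: efferent bouton on a {fiber_class} fiber {c.fiber_id!r}"
            )


def parse_tree_name(name: str, grammar: re.Pattern = DEFAULT_NAME_GRAMMAR):
    """Return ``(cell_class, row, tree_id)`` for a tree name, or ``(None, None, name)``.

    Unknown names are retained (class ``None``) and flagged by the caller.
    """
    m = grammar.match(name)
    if not m:
        return None, None, name
    cls, row, _ = m.groups()
    return cls, (int(row) if row else None), name


# ---------------------------------------------------------------------------
# NML
# ---------------------------------------------------------------------------

def read_nml(
    path,
    pitch: VoxelPitch | None = None,
    grammar: re.Pattern = DEFAULT_NAME_GRAMMAR,
) -> AnnotationSet:
    """Read a webKNOSSOS-style NML file into an :class:`AnnotationSet`.

    Integer voxel coordinates are scaled to nm by ``pitch`` (taken from the
    file's ``<scale>`` element when not given).  Landmarks are recovered
    from ``landmark:`` comments.
    """
    try:
        doc = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed NML {path}: {exc}") from exc
    root = doc.getroot()

    if pitch is None:
        scale = root.find("parameters/scale")
        if scale is None:
            raise ParseError(f"{path}: no voxel pitch given and no <scale> element")
        pitch = VoxelPitch(
            float(scale.get("x")), float(scale.get("y")), float(scale.get("z"))
        )
    factor = pitch.as_array()

    aset = AnnotationSet(pitch=pitch)
    exp = root.find("parameters/experiment")
    if exp is not None:
        aset.provenance = exp.get("name", "")

    node_owner: dict[int, SkeletonTree] = {}
    for thing in root.iter("thing"):
        name = thing.get("name", f"thing{thing.get('id')}")
        cls, row, tree_id = parse_tree_name(name, grammar)
        if cls is None:
            logger.warning("tree %r does not match the naming grammar; class unknown", name)
        tree = SkeletonTree(tree_id=tree_id, cell_class=cls, row=row)
        for nd in thing.iter("node"):
            nid = int(nd.get("id"))
            voxel = np.array(
                [float(nd.get("x")), float(nd.get("y")), float(nd.get("z"))]
            )
            radius = float(nd.get("radius")) if nd.get("radius") else None
            tree.add_node(nid, voxel * factor, radius)
            node_owner[nid] = tree
        for ed in thing.iter("edge"):
            tree.add_edge(int(ed.get("source")), int(ed.get("target")))
        # per-thing comments (also accepted, though written globally)
        for cm in thing.iter("comment"):
            _apply_comment(cm, node_owner)
        tree.validate()
        aset.add_tree(tree)

    for cm in root.findall("comments/comment"):
        _apply_comment(cm, node_owner)
    return aset


def _apply_comment(cm, node_owner) -> None:
    content = cm.get("content", "")
    if not content.startswith(LANDMARK_PREFIX):
        return
    nid = int(cm.get("node"))
    tree = node_owner.get(nid)
    if tree is None:
        raise ValidationError(f"landmark comment cites absent node {nid}")
    tree.landmarks[content[len(LANDMARK_PREFIX):]] = nid


def _write_nml(aset: AnnotationSet, path) -> None:
    root = etree.Element("things")
    params = etree.SubElement(root, "parameters")
    etree.SubElement(params, "experiment", name=aset.provenance or "cortimorph")
    p = aset.pitch
    etree.SubElement(
        params, "scale", x=repr(p.dx), y=repr(p.dy), z=repr(p.dz)
    )
    factor = p.as_array()
    comments = []
    for i, tree_id in enumerate(sorted(aset.trees), start=1):
        tree = aset.trees[tree_id]
        thing = etree.SubElement(root, "thing", id=str(i), name=tree_id)
        nodes_el = etree.SubElement(thing, "nodes")
        for nid in sorted(tree.nodes):
            node = tree.nodes[nid]
            voxel = np.rint(node.position / factor).astype(int)
            attrs = {
                "id": str(nid),
                "x": str(voxel[0]),
                "y": str(voxel[1]),
                "z": str(voxel[2]),
            }
            if node.radius is not None:
                attrs["radius"] = repr(float(node.radius))
            etree.SubElement(nodes_el, "node", **attrs)
        edges_el = etree.SubElement(thing, "edges")
        for a, b in sorted(tree.edges):
            etree.SubElement(edges_el, "edge", source=str(a), target=str(b))
        for name in sorted(tree.landmarks):
            comments.append((tree.landmarks[name], name))
    comments_el = etree.SubElement(root, "comments")
    for nid, name in sorted(comments):
        etree.SubElement(
            comments_el, "comment", node=str(nid), content=LANDMARK_PREFIX + name
        )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(
    paths,
    pitch: VoxelPitch,
    labels: dict[str, tuple[str | None, int | None]] | None = None,
) -> AnnotationSet:
    """Read one-or-more standard 7-column SWC files (one cell each).

    ``labels`` maps file stem -> ``(cell_class, row)``; stems become tree
    ids, which keeps ids unique across files sharing internal numbering.
    A sidecar ``landmarks.csv`` (columns tree_id,landmark,node_id) next to
    the first file is honoured when present.
    """
    labels = labels or {}
    factor = pitch.as_array()
    aset = AnnotationSet(pitch=pitch)
    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    for path in paths:
        stem = path.stem
        cls, row = labels.get(stem, (None, None))
        tree = SkeletonTree(tree_id=stem, cell_class=cls, row=row)
        parents: dict[int, int] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 SWC columns")
            nid, _stype, x, y, z, radius, parent = parts
            nid, parent = int(nid), int(parent)
            tree.add_node(
                nid, np.array([float(x), float(y), float(z)]) * factor, float(radius)
            )
            parents[nid] = parent
        for nid, parent in parents.items():
            if parent == -1:
                tree.landmarks.setdefault("swc_root", nid)
            else:
                if parent not in tree.nodes:
                    raise ValidationError(
                        f"{path}: node {nid} cites absent parent {parent}"
                    )
                tree.add_edge(nid, parent)
        _check_acyclic_parents(parents, path)
        tree.validate()
        aset.add_tree(tree)
    if paths:
        sidecar = paths[0].parent / "landmarks.csv"
        if sidecar.exists():
            with open(sidecar, newline="") as fh:
                for rec in csv.DictReader(fh):
                    t = aset.trees.get(rec["tree_id"])
                    if t is not None:
                        t.landmarks[rec["landmark"]] = int(rec["node_id"])
                        t.validate()
    return aset


def _check_acyclic_parents(parents: dict[int, int], path) -> None:
    for start in parents:
        seen = set()
        nid = start
        while nid != -1:
            if nid in seen:
                raise ValidationError(f"{path}: cyclic parent chain at node {nid}")
            seen.add(nid)
            nid = parents.get(nid, -1)


def _write_swc(aset: AnnotationSet, path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    factor = aset.pitch.as_array()
    landmark_rows = []
    for tree_id, tree in sorted(aset.trees.items()):
        g = tree.graph()
        lines = ["# generated by cortimorph"]
        root = tree.landmarks.get("swc_root", min(tree.nodes) if tree.nodes else None)
        parent_of = {root: -1}
        if root is not None and tree.nodes:
            for a, b in nx.bfs_edges(g, root):
                parent_of[b] = a
        for nid in sorted(tree.nodes):
            node = tree.nodes[nid]
            voxel = np.rint(node.position / factor).astype(int)
            radius = node.radius if node.radius is not None else 1.0
            lines.append(
                f"{nid} 0 {voxel[0]} {voxel[1]} {voxel[2]} {radius:g} {parent_of.get(nid, -1)}"
            )
        (out / f"{tree_id}.swc").write_text("\n".join(lines) + "\n")
        for name, nid in sorted(tree.landmarks.items()):
            if name != "swc_root":
                landmark_rows.append((tree_id, name, nid))
    with open(out / "landmarks.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tree_id", "landmark", "node_id"])
        w.writerows(landmark_rows)


# ---------------------------------------------------------------------------
# contact tables
# ---------------------------------------------------------------------------

CONTACT_COLUMNS = ["fiber_id", "target_id", "bouton_class", "x", "y", "z", "node_id"]


def read_contacts(path, annotation: AnnotationSet) -> AnnotationSet:
    """Append validated contacts from a delimited text table.

    Coordinates in the table are voxel indices; they are scaled by the
    annotation's pitch.  Rows citing unknown trees or class-inconsistent
    fibers raise :class:`ValidationError` naming the row.
    """
    factor = annotation.pitch.as_array()
    n_before = len(annotation.contacts)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CONTACT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing contact columns {sorted(missing)}")
        for i, rec in enumerate(reader, start=2):
            contact = ContactRecord(
                fiber_id=rec["fiber_id"],
                target_id=rec["target_id"],
                bouton_class=rec["bouton_class"],
                position=np.array(
                    [float(rec["x"]), float(rec["y"]), float(rec["z"])]
                )
                * factor,
                contact_node=int(rec["node_id"]),
            )
            annotation._validate_contact(contact, where=f"{path} row {i}")
            annotation.contacts.append(contact)
    if len(annotation.contacts) == n_before:
        logger.warning("contact table %s contained no rows", path)
    return annotation


def _write_contacts(aset: AnnotationSet, path) -> None:
    factor = aset.pitch.as_array()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CONTACT_COLUMNS)
        for c in aset.contacts:
            voxel = np.rint(c.position / factor).astype(int)
            w.writerow(
                [c.fiber_id, c.target_id, c.bouton_class, *voxel, c.contact_node]
            )


def write_annotation(aset: AnnotationSet, path, format: str) -> None:
    """Write an annotation set; ``format`` in {nml, swc, contacts-csv}.

    Round-trip contract: topology and labels survive write->read exactly;
    coordinates agree within half a voxel per axis (quantization).
    """
    if format == "nml":
        _write_nml(aset, path)
    elif format == "swc":
        _write_swc(aset, path)
    elif format == "contacts-csv":
        _write_contacts(aset, path)
    else:
        raise AnnotationError(f"unsupported format {format!r}")
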