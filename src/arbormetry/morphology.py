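"""Data model and I/O for annotated single-neuron reconstructions.

A reconstruction consists of one or more rooted trees of reconstruction points
(SWC format: id, type, x, y, z, radius, parent) plus an optional annotation
sidecar carrying the soma contour stack and the retinal-layer model.

Coordinate convention
---------------------
``X`` is the lateral slice axis, ``Y`` is retinal depth (increasing from the
inner nuclear layer toward the ganglion cell layer), ``Z`` is the optical
axis.  The "XZ plane" is therefore parallel to the retinal surface.  Soma
contours are closed polygons traced at focal planes, i.e. at constant ``Z``,
with vertices in the ``XY`` plane.  All coordinates and radii are in µm.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon


class MorphologyError(ValueError):
    """Base class for reconstruction errors."""


class SWCParseError(MorphologyError):
    """Malformed SWC input (bad columns, duplicate or orphan ids, cycles)."""


class ValidationError(MorphologyError):
    """Structurally valid input with invalid values (e.g. radius <= 0)."""


class DegenerateGeometryError(MorphologyError):
    """Geometric operation on degenerate input (collinear/coplanar points)."""


class PointLabel(IntEnum):
    """SWC type codes as used here.

    1 marks a soma anchor point; 2 is reused for the apical dendrite, 3/4 for
    lobular/arboreal processes; 0 is unspecified.
    """

    UNSPECIFIED = 0
    SOMA = 1
    APICAL = 2
    LOBULAR = 3
    ARBOREAL = 4


#: Laminar bins in order of increasing retinal depth.
LAYER_BINS = ("INL", "S1", "S2", "S3", "S4", "S5", "GCL")


# ---------------------------------------------------------------------------
# Soma contour stack
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SomaContour:
    """A closed planar polygon traced at one focal plane.

    ``depth`` is the Z (optical axis) coordinate of the plane; ``vertices``
    is an (k, 2) array of (x, y) pairs, k >= 3, implicitly closed.
    """

    depth: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("soma contour needs >= 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)
        if not self.polygon.is_simple:
            raise ValidationError("soma contour polygon is self-intersecting")

    @property
    def polygon(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        return self.polygon.length


@dataclass
class SomaContourStack:
    """Soma traced as a stack of contours at consecutive focal planes."""

    contours: list[SomaContour]

    def __post_init__(self) -> None:
        if not self.contours:
            raise ValidationError("empty soma contour stack")
        depths = [c.depth for c in self.contours]
        if any(b < a for a, b in zip(depths, depths[1:])):
            self.contours = sorted(self.contours, key=lambda c: c.depth)

    @property
    def depths(self) -> np.ndarray:
        return np.array([c.depth for c in self.contours])

    def centroid(self) -> np.ndarray:
        """Volume-weighted centroid of the stack, (x, y, z) in µm.

        Each contour contributes its polygon centroid weighted by area times
        the local plane spacing; a single contour is weighted by area alone.
        """
        xs, ys, zs, ws = [], [], [], []
        depths = self.depths
        n = len(self.contours)
        for i, c in enumerate(self.contours):
            if n == 1:
                dz = 1.0
            elif i == 0:
                dz = depths[1] - depths[0]
            elif i == n - 1:
                dz = depths[-1] - depths[-2]
            else:
                dz = (depths[i + 1] - depths[i - 1]) / 2.0
            cen = c.polygon.centroid
            w = c.area * max(dz, 1e-12)
            xs.append(cen.x)
            ys.append(cen.y)
            zs.append(c.depth)
            ws.append(w)
        w = np.asarray(ws)
        if w.sum() <= 0:
            w = np.ones_like(w)
        return np.array(
            [np.average(xs, weights=w), np.average(ys, weights=w), np.average(zs, weights=w)]
        )

    def distance_to(self, point: Sequence[float]) -> float:
        """3D distance from ``point`` to the nearest contour polygon."""
        x, y, z = point
        p = _ShapelyPoint(x, y)
        best = math.inf
        for c in self.contours:
            dxy = c.polygon.exterior.distance(p) if not c.polygon.contains(p) else 0.0
            best = min(best, math.hypot(dxy, z - c.depth))
        return best


# ---------------------------------------------------------------------------
# Layer model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerModel:
    """Two boundary depths defining INL | IPL | GCL.

    The IPL (between ``y_inl_ipl`` and ``y_ipl_gcl``) is divided into five
    equally thick strata S1–S5.  Orientation is carried by the sign of
    ``y_ipl_gcl - y_inl_ipl``.
    """

    y_inl_ipl: float
    y_ipl_gcl: float

    def __post_init__(self) -> None:
        if self.y_inl_ipl == self.y_ipl_gcl:
            raise ValidationError("degenerate layer model: equal boundaries")

    @property
    def orientation(self) -> int:
        return 1 if self.y_ipl_gcl > self.y_inl_ipl else -1

    @property
    def ipl_thickness(self) -> float:
        return abs(self.y_ipl_gcl - self.y_inl_ipl)

    def stratum_boundaries(self) -> np.ndarray:
        """Depths of the six boundaries INL|S1, S1|S2, ..., S5|GCL."""
        return np.linspace(self.y_inl_ipl, self.y_ipl_gcl, 6)

    def bin_depths(self, y: np.ndarray) -> np.ndarray:
        """Bin depth coordinates into indices over LAYER_BINS.

        Points exactly on a boundary go to the bin on the INL side
        (deterministic tie-break), so the IPL/INL boundary itself bins INL
        and the S1/S2 boundary bins S1.
        """
        y = np.asarray(y, dtype=float)
        t = (y - self.y_inl_ipl) / (self.y_ipl_gcl - self.y_inl_ipl)
        out = np.empty(t.shape, dtype=int)
        out[t <= 0] = 0
        out[t > 1] = 6
        inside = (t > 0) & (t <= 1)
        # stratum k covers t in ((k-1)/5, k/5]
        out[inside] = np.ceil(t[inside] * 5 - 1e-12).astype(int)
        return out

    def bin_names(self, y: np.ndarray) -> np.ndarray:
        return np.array(LAYER_BINS, dtype=object)[self.bin_depths(y)]


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

@dataclass
class Morphology:
    """A reconstruction: point trees plus optional soma stack and layer model.

    Points are stored in parallel arrays; ``parents`` holds array *indices*
    (-1 for roots) and is guaranteed topologically ordered (parent before
    child).  ``ids`` keeps the original 1-based SWC ids for round-trips.
    """

    ids: np.ndarray
    parents: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    labels: np.ndarray
    soma: SomaContourStack | None = None
    layers: LayerModel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.ids)
        if not (len(self.parents) == self.xyz.shape[0] == len(self.radius) == len(self.labels) == n):
            raise MorphologyError("inconsistent array lengths")
        if n and ((self.parents >= np.arange(n)) & (self.parents != -1)).any():
            raise MorphologyError("parents must precede children (topological order)")
        if (self.radius <= 0).any():
            bad = self.ids[self.radius <= 0].tolist()
            raise ValidationError(f"non-positive radius at point id(s) {bad}")

    # -- basic structure ----------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.ids)

    @property
    def diameters(self) -> np.ndarray:
        return 2.0 * self.radius

    def root_indices(self) -> np.ndarray:
        return np.flatnonzero(self.parents < 0)

    def children_lists(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_points)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                ch[p].append(i)
        return ch

    def n_children(self) -> np.ndarray:
        out = np.zeros(self.n_points, dtype=int)
        valid = self.parents >= 0
        np.add.at(out, self.parents[valid], 1)
        return out

    def trees(self) -> list[np.ndarray]:
        """Point indices of each tree, in topological order."""
        comp = np.full(self.n_points, -1, dtype=int)
        roots = self.root_indices()
        for k, r in enumerate(roots):
            comp[r] = k
        for i in range(self.n_points):
            p = self.parents[i]
            if p >= 0:
                comp[i] = comp[p]
        return [np.flatnonzero(comp == k) for k in range(len(roots))]

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(parent_index, child_index) arrays over all non-root points."""
        child = np.flatnonzero(self.parents >= 0)
        return self.parents[child], child

    def neurite_mask(self) -> np.ndarray:
        """Points that belong to processes (everything not labelled soma)."""
        return self.labels != int(PointLabel.SOMA)

    def soma_centroid(self) -> np.ndarray:
        """Soma centroid; falls back to the mean of root points."""
        if self.soma is not None:
            return self.soma.centroid()
        roots = self.root_indices()
        if len(roots) == 0:
            raise MorphologyError("empty morphology has no soma centroid")
        return self.xyz[roots].mean(axis=0)

    def copy(self) -> "Morphology":
        return Morphology(
            ids=self.ids.copy(),
            parents=self.parents.copy(),
            xyz=self.xyz.copy(),
            radius=self.radius.copy(),
            labels=self.labels.copy(),
            soma=self.soma,
            layers=self.layers,
            metadata=dict(self.metadata),
        )

    def total_path_length(self) -> float:
        pi, ci = self.edges()
        if len(ci) == 0:
            return 0.0
        return float(np.linalg.norm(self.xyz[ci] - self.xyz[pi], axis=1).sum())


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _toposort(ids, types, xyz, radius, parents_swc):
    """Resolve SWC parent ids to indices and order parents before children."""
    index_of = {}
    for i, pid in enumerate(ids):
        if pid in index_of:
            raise SWCParseError(f"duplicate SWC id {pid}")
        index_of[pid] = i
    parent_idx = np.empty(len(ids), dtype=int)
    for i, pp in enumerate(parents_swc):
        if pp < 0:
            parent_idx[i] = -1
        elif pp not in index_of:
            raise SWCParseError(f"point id {ids[i]} references missing parent {pp}")
        else:
            parent_idx[i] = index_of[pp]
    # already topologically ordered files keep their order (stable round-trip)
    if all(p < i for i, p in enumerate(parent_idx)):
        return (
            np.asarray(ids),
            np.asarray(types),
            np.asarray(xyz),
            np.asarray(radius),
            parent_idx,
        )
    # Kahn topological order; leftovers indicate a cycle.
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg_root = []
    for i, p in enumerate(parent_idx):
        if p == -1:
            indeg_root.append(i)
        else:
            children[p].append(i)
    order = []
    stack = list(reversed(indeg_root))
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(reversed(children[i]))
    if len(order) != n:
        raise SWCParseError("cycle detected in SWC parent references")
    order = np.asarray(order)
    remap = np.empty(n, dtype=int)
    remap[order] = np.arange(n)
    new_parents = np.where(parent_idx[order] >= 0, remap[np.maximum(parent_idx[order], 0)], -1)
    return (
        np.asarray(ids)[order],
        np.asarray(types)[order],
        np.asarray(xyz)[order],
        np.asarray(radius)[order],
        new_parents,
    )


def read_swc(source) -> Morphology:
    """Read a standard 7-column SWC file (path, string, or open file)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        p = Path(source)
        if p.exists():
            text = p.read_text(encoding="utf-8")
        else:
            text = str(source)
    ids, types, pts, radii, parents = [], [], [], [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            ids.append(int(parts[0]))
            types.append(int(parts[1]))
            pts.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from exc
    if not ids:
        raise SWCParseError("empty SWC input")
    ids, types, xyz, radius, parent_idx = _toposort(
        ids, types, np.asarray(pts, dtype=float), np.asarray(radii, dtype=float), parents
    )
    return Morphology(ids=ids, parents=parent_idx, xyz=xyz, radius=radius, labels=types)


def write_swc(morph: Morphology, target=None) -> str:
    """Serialize to SWC text (UTF-8, LF).  Returns the text; writes if given a path."""
    lines = ["# SWC export (id type x y z radius parent); units µm"]
    swc_parent = np.where(morph.parents >= 0, morph.ids[np.maximum(morph.parents, 0)], -1)
    for i in range(morph.n_points):
        x, y, z = morph.xyz[i]
        lines.append(
            f"{morph.ids[i]} {morph.labels[i]} {x:.6f} {y:.6f} {z:.6f} "
            f"{morph.radius[i]:.6f} {swc_parent[i]}"
        )
    text = "\n".join(lines) + "\n"
    if target is not None:
        Path(target).write_text(text, encoding="utf-8", newline="\n")
    return text


def read_annotation(source) -> dict:
    """Read the JSON sidecar (layers, soma contours, metadata)."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        p = Path(source)
        payload = json.loads(p.read_text(encoding="utf-8")) if p.exists() else json.loads(str(source))
    out: dict = {"layers": None, "soma": None, "metadata": dict(payload.get("metadata", {}))}
    if "layers" in payload and payload["layers"] is not None:
        lay = payload["layers"]
        out["layers"] = LayerModel(float(lay["y_inl_ipl"]), float(lay["y_ipl_gcl"]))
    if payload.get("soma_contours"):
        contours = [
            SomaContour(depth=float(c["z"]), vertices=np.asarray(c["xy"], dtype=float))
            for c in payload["soma_contours"]
        ]
        out["soma"] = SomaContourStack(contours)
    return out


def write_annotation(morph: Morphology, target=None) -> str:
    payload: dict = {"metadata": morph.metadata}
    if morph.layers is not None:
        payload["layers"] = {
            "y_inl_ipl": morph.layers.y_inl_ipl,
            "y_ipl_gcl": morph.layers.y_ipl_gcl,
        }
    if morph.soma is not None:
        payload["soma_contours"] = [
            {"z": c.depth, "xy": np.round(c.vertices, 6).tolist()} for c in morph.soma.contours
        ]
    text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
    if target is not None:
        Path(target).write_text(text, encoding="utf-8", newline="\n")
    return text


def read_reconstruction(swc_source, annotation_source=None) -> Morphology:
    """Read an SWC reconstruction with an optional JSON annotation sidecar."""
    morph = read_swc(swc_source)
    if annotation_source is not None:
        ann = read_annotation(annotation_source)
        morph.layers = ann["layers"]
        morph.soma = ann["soma"]
        morph.metadata.update(ann["metadata"])
    return morph


# ---------------------------------------------------------------------------
# Layer annotation
# ---------------------------------------------------------------------------

def annotate_layers(morph: Morphology, layers: LayerModel | None = None) -> np.ndarray:
    """Per-point laminar bin names over {INL, S1..S5, GCL}."""
    layers = layers or morph.layers
    if layers is None:
        raise MorphologyError("no layer model available")
    return layers.bin_names(morph.xyz[:, 1])


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest principal component of a point cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 points for a principal axis")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 0 or (w[1] / w[-1]) < 1e-12:
        raise DegenerateGeometryError("collinear point cloud has no stable major axis")
    axis = v[:, -1]
    if axis[1] < 0:
        axis = -axis
    return axis


def align_major_axis(morph: Morphology) -> Morphology:
    """Rotate so the major axis of the arbor is parallel to the depth (Y) axis.

    Rotations are restricted to the XY plane (about Z) followed by the YZ
    plane (about X), about the soma centroid, so the transform is a rigid
    isometry with the soma centroid fixed.  The contour stack is left
    unrotated (the rotation fixes its centroid, so soma-relative distances
    are unchanged and the stack remains planar per focal plane).
    """
    axis = principal_axis(morph.xyz)
    phi = math.atan2(axis[0], axis[1])  # about Z: zero the X component
    c, s = math.cos(phi), math.sin(phi)
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    a2 = rz @ axis
    psi = math.atan2(a2[2], a2[1])  # about X: zero the Z component
    c2, s2 = math.cos(-psi), math.sin(-psi)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c2, -s2], [0.0, s2, c2]])
    rot = rx @ rz
    center = morph.soma_centroid()
    out = morph.copy()
    out.xyz = (morph.xyz - center) @ rot.T + center
    out.metadata = {**morph.metadata, "alignment_rotation": rot.tolist()}
    return out


# ---------------------------------------------------------------------------
# Dendritic-field splitting
# ---------------------------------------------------------------------------

def frustum_lateral_area(r0: float, r1: float, length: float) -> float:
    """Lateral surface of a conical frustum between radii r0 and r1."""
    slant = math.hypot(length, r1 - r0)
    return math.pi * (r0 + r1) * slant


@dataclass
class FieldSplit:
    """Partition of a morphology at a retinal-depth (XZ) plane.

    ``distal`` is the INL side (soma, apical, lobular processes), ``proximal``
    the GCL side (arboreal processes).  Fractions are % of total surface area
    (soma plus dendritic frusta); edges crossing the plane are clipped there
    with linearly interpolated radius.
    """

    y_split: float
    distal_mask: np.ndarray
    proximal_mask: np.ndarray
    distal_area: float
    proximal_area: float

    @property
    def total_area(self) -> float:
        return self.distal_area + self.proximal_area

    @property
    def distal_fraction(self) -> float:
        return 100.0 * self.distal_area / self.total_area

    @property
    def proximal_fraction(self) -> float:
        return 100.0 * self.proximal_area / self.total_area


def split_dendritic_fields(morph: Morphology, y_split: float) -> FieldSplit:
    """Split at the XZ plane ``y = y_split`` and report surface-area shares."""
    y = morph.xyz[:, 1]
    if not (y.min() < y_split < y.max()):
        raise MorphologyError(f"y_split={y_split} outside arbor depth range [{y.min()}, {y.max()}]")
    neurite = morph.neurite_mask()
    distal_mask = (y <= y_split) & neurite
    proximal_mask = (y > y_split) & neurite

    areas = [0.0, 0.0]  # distal, proximal
    pi_arr, ci_arr = morph.edges()
    for p, cidx in zip(pi_arr, ci_arr):
        if not (neurite[p] and neurite[cidx]):
            continue
        p0, p1 = morph.xyz[p], morph.xyz[cidx]
        r0, r1 = morph.radius[p], morph.radius[cidx]
        length = float(np.linalg.norm(p1 - p0))
        if length == 0.0:
            continue
        y0, y1 = p0[1], p1[1]
        side0 = 0 if y0 <= y_split else 1
        side1 = 0 if y1 <= y_split else 1
        if side0 == side1:
            areas[side0] += frustum_lateral_area(r0, r1, length)
        else:
            t = (y_split - y0) / (y1 - y0)
            rm = r0 + t * (r1 - r0)
            areas[side0] += frustum_lateral_area(r0, rm, length * t)
            areas[side1] += frustum_lateral_area(rm, r1, length * (1 - t))
    if morph.soma is not None:
        from .branches import soma_metrics  # local import to avoid a cycle

        sm = soma_metrics(morph.soma)
        if sm.get("surface_area") is not None:
            side = 0 if morph.soma.centroid()[1] <= y_split else 1
            areas[side] += sm["surface_area"]
    return FieldSplit(
        y_split=float(y_split),
        distal_mask=distal_mask,
        proximal_mask=proximal_mask,
        distal_area=areas[0],
        proximal_area=areas[1],
    )


def suggest_field_split(morph: Morphology, n_bins: int = 50) -> float:
    """Automatic split depth: the waist of the depth-density profile.

    Finds the depth of minimum process length density between the two modes
    of the (bimodal) depth histogram; a plain default when no split plane has
    been chosen by hand.
    """
    pi_arr, ci_arr = morph.edges()
    ym = (morph.xyz[pi_arr, 1] + morph.xyz[ci_arr, 1]) / 2.0
    w = np.linalg.norm(morph.xyz[ci_arr] - morph.xyz[pi_arr], axis=1)
    hist, edges = np.histogram(ym, bins=n_bins, weights=w)
    # smooth lightly, find the global peak on each side of the valley
    kernel = np.array([0.25, 0.5, 0.25])
    smooth = np.convolve(hist, kernel, mode="same")
    peak = int(np.argmax(smooth))
    # search the second mode on the opposite side of the highest peak
    left = smooth[:peak]
    right = smooth[peak + 1 :]
    if len(left) and (not len(right) or left.max() >= right.max()):
        other = int(np.argmax(left))
    else:
        other = peak + 1 + int(np.argmax(right)) if len(right) else peak
    lo, hi = sorted((peak, other))
    if hi - lo < 2:
        return float((edges[0] + edges[-1]) / 2.0)
    valley = lo + 1 + int(np.argmin(smooth[lo + 1 : hi]))
    return float((edges[valley] + edges[valley + 1]) / 2.0)


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    nonpositive_radius: list[int] = field(default_factory=list)
    orphan_parents: list[int] = field(default_factory=list)
    cycles: list[int] = field(default_factory=list)
    detached_trees: list[int] = field(default_factory=list)
    multi_root_trees: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.nonpositive_radius
            or self.orphan_parents
            or self.cycles
            or self.detached_trees
            or self.multi_root_trees
        )

    def issues(self) -> list[str]:
        out = []
        for name in ("nonpositive_radius", "orphan_parents", "cycles", "detached_trees", "multi_root_trees"):
            vals = getattr(self, name)
            if vals:
                out.append(f"{name}: {vals}")
        return out


def validate(
    morph: Morphology,
    soma_attachment_tolerance: float = 2.0,
    raw_points: tuple | None = None,
) -> ValidationReport:
    """Report structural problems without raising.

    ``raw_points`` may carry (ids, parents_swc) for inputs that could not be
    topologically sorted; for an already constructed Morphology the parent
    array is sound by construction, so only radii and soma attachment can
    fail here.
    """
    report = ValidationReport()
    report.nonpositive_radius = morph.ids[morph.radius <= 0].tolist() if len(morph.ids) else []
    if raw_points is not None:
        ids, parents_swc = raw_points
        known = set(ids)
        report.orphan_parents = [i for i, p in zip(ids, parents_swc) if p >= 0 and p not in known]
    if morph.soma is not None:
        for r in morph.root_indices():
            if morph.labels[r] == int(PointLabel.SOMA):
                continue
            if morph.soma.distance_to(morph.xyz[r]) > soma_attachment_tolerance:
                report.detached_trees.append(int(morph.ids[r]))
    return report


def check_cycles(ids: Iterable[int], parents_swc: Iterable[int]) -> list[int]:
    """Ids of points participating in a parent-reference cycle."""
    ids = list(ids)
    parents_swc = list(parents_swc)
    index_of = {pid: i for i, pid in enumerate(ids)}
    color = [0] * len(ids)  # 0 unseen, 1 in progress, 2 done
    in_cycle: set[int] = set()
    for start in range(len(ids)):
        path = []
        i = start
        while i is not None and color[i] == 0:
            color[i] = 1
            path.append(i)
            p = parents_swc[i]
            i = index_of.get(p) if p >= 0 else None
        if i is not None and color[i] == 1:
            # found a cycle; everything from i onward in path is cyclic
            k = path.index(i)
            in_cycle.update(path[k:])
        for j in path:
            color[j] = 2
    return sorted(ids[i] for i in in_cycle)
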