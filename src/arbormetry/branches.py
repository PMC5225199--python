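"""Segment decomposition, branch ordering, and per-cell branch metrics.

A branch segment is the part of a process between two branch points (nodes),
or between a node and a termination (ending).  The number of segments always
equals the number of nodes plus the number of endings; for a single purely
bifurcating tree the number of endings equals the number of nodes plus one.

Two branch-ordering schemes are supported:

* ``centrifugal`` — stems have order 1 and every branch point increments the
  order of both daughters.
* ``central_shaft`` — the continuing daughter (the thicker one) keeps the
  parent's order and only side daughters increment, so a thick apical shaft
  keeps order 1 along its length.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.ops import unary_union

from .geometry import convex_hull_2d, convex_hull_3d, feret_diameters
from .morphology import (
    DegenerateGeometryError,
    Morphology,
    MorphologyError,
    PointLabel,
    SomaContourStack,
    ValidationError,
    frustum_lateral_area,
)

OrderScheme = Literal["centrifugal", "central_shaft"]


# ---------------------------------------------------------------------------
# Segment decomposition
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """A run of points between consecutive branch events.

    ``points`` are morphology point indices; the first entry is the origin
    (tree root or parent branch node, shared with the parent segment), the
    last the segment's own end (a node or a tip).  Interior points and the
    end point are owned by the segment; the origin is owned by the parent.
    """

    index: int
    points: np.ndarray
    parent: int | None
    children: list[int] = field(default_factory=list)
    order_centrifugal: int = 0
    order_shaft: int = 0

    @property
    def terminal(self) -> bool:
        return not self.children


@dataclass
class SegmentDecomposition:
    segments: list[Segment]
    node_points: np.ndarray      # point indices of branch points (>= 2 children, non-root)
    ending_points: np.ndarray    # point indices of tips
    stem_segments: list[int]     # segment indices starting at tree roots
    point_segment: np.ndarray    # owning segment per point (-1 for roots/soma anchors)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_nodes(self) -> int:
        return len(self.node_points)

    @property
    def n_endings(self) -> int:
        return len(self.ending_points)


def decompose_segments(morph: Morphology) -> SegmentDecomposition:
    """Decompose every tree into branch segments.

    A tree root is never counted as a node: a root with several children
    simply starts that many stems (the root acts as a soma-side origin), so
    ``n_segments == n_nodes + n_endings`` holds for every cell.
    """
    children = morph.children_lists()
    roots = morph.root_indices()
    segments: list[Segment] = []
    stem_ids: list[int] = []
    node_pts: list[int] = []
    ending_pts: list[int] = []
    point_segment = np.full(morph.n_points, -1, dtype=int)

    def walk(origin: int, first: int, parent_seg: int | None) -> None:
        stack = [(origin, first, parent_seg)]
        while stack:
            origin, first, parent_seg = stack.pop()
            pts = [origin]
            cur = first
            while True:
                pts.append(cur)
                ch = children[cur]
                if len(ch) == 1:
                    cur = ch[0]
                else:
                    break
            seg = Segment(index=len(segments), points=np.asarray(pts), parent=parent_seg)
            segments.append(seg)
            if parent_seg is None:
                stem_ids.append(seg.index)
            else:
                segments[parent_seg].children.append(seg.index)
            point_segment[seg.points[1:]] = seg.index
            ch = children[cur]
            if not ch:
                ending_pts.append(cur)
            else:
                node_pts.append(cur)
                for nxt in reversed(ch):
                    stack.append((cur, nxt, seg.index))

    for r in roots:
        ch = children[r]
        for first in ch:
            walk(r, first, None)

    return SegmentDecomposition(
        segments=segments,
        node_points=np.asarray(node_pts, dtype=int),
        ending_points=np.asarray(ending_pts, dtype=int),
        stem_segments=stem_ids,
        point_segment=point_segment,
    )


# ---------------------------------------------------------------------------
# Branch ordering
# ---------------------------------------------------------------------------

def _chord(morph: Morphology, seg: Segment) -> np.ndarray:
    return morph.xyz[seg.points[-1]] - morph.xyz[seg.points[0]]


def _subtree_length(morph: Morphology, decomp: SegmentDecomposition, seg_idx: int,
                    cache: dict[int, float]) -> float:
    if seg_idx in cache:
        return cache[seg_idx]
    seg = decomp.segments[seg_idx]
    total = segment_geometry(morph, seg)["path_length"]
    for c in seg.children:
        total += _subtree_length(morph, decomp, c, cache)
    cache[seg_idx] = total
    return total


def assign_branch_orders(morph: Morphology, decomp: SegmentDecomposition,
                         scheme: OrderScheme = "centrifugal") -> np.ndarray:
    """Assign branch orders to every segment; returns the per-segment orders.

    Central-shaft continuation rule (the thick apical shaft keeps its order):
    the daughter with the larger radius at its first own point continues; on
    a tie, the daughter with the smaller deviation angle from the parent
    direction; on a further tie, the daughter with the larger subtree length.
    Trifurcations are a single node: under centrifugal ordering all daughters
    increment; under shaft ordering exactly one continues.
    """
    if scheme not in ("centrifugal", "central_shaft"):
        raise ValueError(f"unknown ordering scheme: {scheme}")
    orders = np.zeros(decomp.n_segments, dtype=int)
    length_cache: dict[int, float] = {}
    for stem in decomp.stem_segments:
        stack = [(stem, 1)]
        while stack:
            idx, order = stack.pop()
            seg = decomp.segments[idx]
            orders[idx] = order
            if not seg.children:
                continue
            if scheme == "centrifugal":
                for c in seg.children:
                    stack.append((c, order + 1))
            else:
                cont = _continuing_daughter(morph, decomp, seg, length_cache)
                for c in seg.children:
                    stack.append((c, order if c == cont else order + 1))
    if scheme == "centrifugal":
        for s in decomp.segments:
            s.order_centrifugal = int(orders[s.index])
    else:
        for s in decomp.segments:
            s.order_shaft = int(orders[s.index])
    return orders


def _continuing_daughter(morph, decomp, seg, length_cache) -> int:
    daughters = seg.children
    radii = np.array([morph.radius[decomp.segments[c].points[1]] for c in daughters])
    best = np.flatnonzero(radii >= radii.max() - 1e-9)
    if len(best) == 1:
        return daughters[int(best[0])]
    # tie: smallest deviation angle from parent direction
    pdir = _parent_direction(morph, seg)
    devs = []
    for b in best:
        chord = _chord(morph, decomp.segments[daughters[int(b)]])
        n = np.linalg.norm(chord)
        devs.append(_angle_between(pdir, chord) if n > 0 else math.pi)
    dmin = min(devs)
    best2 = [b for b, d in zip(best, devs) if d <= dmin + 1e-12]
    if len(best2) == 1:
        return daughters[int(best2[0])]
    # final tie: largest subtree length
    lengths = [_subtree_length(morph, decomp, daughters[int(b)], length_cache) for b in best2]
    return daughters[int(best2[int(np.argmax(lengths))])]


def _parent_direction(morph: Morphology, seg: Segment) -> np.ndarray:
    """Direction of the last (non-degenerate) edge of a segment."""
    pts = seg.points
    for i in range(len(pts) - 1, 0, -1):
        v = morph.xyz[pts[i]] - morph.xyz[pts[i - 1]]
        n = np.linalg.norm(v)
        if n > 0:
            return v / n
    return np.array([0.0, 1.0, 0.0])


def _angle_between(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length vector has no direction")
    cosv = float(np.dot(a, b) / (na * nb))
    return math.acos(min(1.0, max(-1.0, cosv)))


# ---------------------------------------------------------------------------
# Segment geometry
# ---------------------------------------------------------------------------

def segment_geometry(morph: Morphology, seg: Segment) -> dict:
    """Path length, frusta surface and volume, and contraction of a segment.

    Each edge is a conical frustum: surface ``π (r0 + r1) · slant`` and
    volume ``π L / 3 · (r0² + r0 r1 + r1²)``.  Contraction is the ratio of
    the Euclidean chord to the path length (1 for a straight segment).
    Coincident consecutive points (zero-length edges) are skipped.
    """
    pts = seg.points
    xyz = morph.xyz[pts]
    r = morph.radius[pts]
    d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    keep = d > 0
    path = float(d[keep].sum())
    r0, r1 = r[:-1][keep], r[1:][keep]
    dk = d[keep]
    slant = np.sqrt(dk**2 + (r1 - r0) ** 2)
    surface = float((math.pi * (r0 + r1) * slant).sum())
    volume = float((math.pi * dk / 3.0 * (r0**2 + r0 * r1 + r1**2)).sum())
    chord = float(np.linalg.norm(xyz[-1] - xyz[0]))
    contraction = chord / path if path > 0 else None
    return {
        "path_length": path,
        "surface": surface,
        "volume": volume,
        "contraction": contraction,
        "chord": chord,
    }


def all_segment_geometry(morph: Morphology, decomp: SegmentDecomposition) -> list[dict]:
    return [segment_geometry(morph, s) for s in decomp.segments]


# ---------------------------------------------------------------------------
# Topological metrics
# ---------------------------------------------------------------------------

def _tip_counts(decomp: SegmentDecomposition) -> np.ndarray:
    """Number of tips in the subtree rooted at each segment."""
    tips = np.zeros(decomp.n_segments, dtype=int)
    for seg in reversed(decomp.segments):  # children have higher indices
        if seg.terminal:
            tips[seg.index] = 1
        else:
            tips[seg.index] = sum(tips[c] for c in seg.children)
    return tips


def partition_asymmetry(decomp: SegmentDecomposition, per_node: bool = False):
    """Partition asymmetry per bifurcation: |n1 - n2| / (n1 + n2 - 2).

    ``n1`` and ``n2`` are the daughter subtrees' tip counts; a tip
    bifurcation (n1 = n2 = 1) is defined as 0, a stub bifurcation (one
    terminal daughter, the other bifurcating further) evaluates to 1.  For
    trifurcations the value is the mean over daughter pairs.  Returns the
    mean (and per-node values if requested); None when there is no
    bifurcation.
    """
    tips = _tip_counts(decomp)
    values = {}
    for seg in decomp.segments:
        if len(seg.children) < 2:
            continue
        counts = [tips[c] for c in seg.children]
        pair_vals = []
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                n1, n2 = counts[i], counts[j]
                pair_vals.append(0.0 if n1 == n2 == 1 else abs(n1 - n2) / (n1 + n2 - 2))
        values[int(seg.points[-1])] = float(np.mean(pair_vals))
    if not values:
        return (None, {}) if per_node else None
    mean = float(np.mean(list(values.values())))
    return (mean, values) if per_node else mean


def bifurcation_angles(morph: Morphology, decomp: SegmentDecomposition) -> dict:
    """Remote bifurcation amplitude per node: the angle (degrees) between
    the chords from the branch point to each daughter segment's end point.

    Bifurcations with a zero-length daughter chord are skipped and counted.
    Multifurcations contribute the mean over daughter pairs.  The SD is the
    population SD over this cell's bifurcations.
    """
    values = []
    skipped = 0
    for seg in decomp.segments:
        if len(seg.children) < 2:
            continue
        chords = [_chord(morph, decomp.segments[c]) for c in seg.children]
        norms = [np.linalg.norm(c) for c in chords]
        if min(norms) == 0:
            skipped += 1
            continue
        pair_vals = []
        for i in range(len(chords)):
            for j in range(i + 1, len(chords)):
                pair_vals.append(math.degrees(_angle_between(chords[i], chords[j])))
        values.append(float(np.mean(pair_vals)))
    arr = np.asarray(values)
    return {
        "values": arr,
        "mean": float(arr.mean()) if len(arr) else None,
        "sd": float(arr.std()) if len(arr) else None,
        "n_skipped": skipped,
    }


def bifurcation_tilts(morph: Morphology, decomp: SegmentDecomposition) -> dict:
    """Remote bifurcation tilt per node, in degrees.

    For each daughter, the tilt is the angle between the daughter chord and
    the *backward* direction of the parent segment's last edge, so 0°
    corresponds to doubling back along the parent and 180° to continuing
    straight ahead.  Per bifurcation, the smaller (most backward) daughter
    tilt is reported.
    """
    values = []
    skipped = 0
    for seg in decomp.segments:
        if len(seg.children) < 2:
            continue
        pts = seg.points
        if len(pts) < 2:
            skipped += 1
            continue
        backward = -_parent_direction(morph, seg)
        tilts = []
        for c in seg.children:
            chord = _chord(morph, decomp.segments[c])
            if np.linalg.norm(chord) == 0:
                continue
            tilts.append(math.degrees(_angle_between(chord, backward)))
        if len(tilts) < 2:
            skipped += 1
            continue
        values.append(min(tilts))
    arr = np.asarray(values)
    return {
        "values": arr,
        "mean": float(arr.mean()) if len(arr) else None,
        "sd": float(arr.std()) if len(arr) else None,
        "n_skipped": skipped,
    }


# ---------------------------------------------------------------------------
# Path-shape metrics
# ---------------------------------------------------------------------------

def polyline_fractal_dimension(points: np.ndarray) -> float | None:
    """Slope of log path length against log Euclidean distance from the
    polyline's start, over its points.

    1 for straight growth, about 2 for a random walk.  None when fewer than
    two usable points remain.
    """
    xyz = np.asarray(points, dtype=float)
    if len(xyz) < 3:
        return None
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    path = np.cumsum(steps)
    eucl = np.linalg.norm(xyz[1:] - xyz[0], axis=1)
    ok = (eucl > 0) & (path > 0)
    if ok.sum() < 2 or np.ptp(np.log(path[ok])) == 0:
        return None
    # regress the (noisy) distance on the (monotone) path length, then
    # invert: this keeps D = 2 for a random walk instead of attenuating it
    slope = np.polyfit(np.log(path[ok]), np.log(eucl[ok]), 1)[0]
    if slope <= 0:
        return None
    return float(1.0 / slope)


def fractal_dimension(morph: Morphology, decomp: SegmentDecomposition) -> dict:
    """Per-branch fractal dimension and its unweighted mean over branches.

    Branches with fewer than three points are skipped.
    """
    values = []
    for seg in decomp.segments:
        d = polyline_fractal_dimension(morph.xyz[seg.points])
        if d is not None:
            values.append(d)
    arr = np.asarray(values)
    return {"values": arr, "mean": float(arr.mean()) if len(arr) else None}


def polyline_helicity(points: np.ndarray) -> np.ndarray:
    """Normalized triple products over sliding windows of three edges.

    For consecutive edge vectors v1, v2, v3 the helicity is
    ``(v1 × v2) · v3 / (|v1||v2||v3|)``; its sign gives the handedness and it
    vanishes for planar paths.  Windows with a degenerate (zero) edge are
    skipped.
    """
    xyz = np.asarray(points, dtype=float)
    if len(xyz) < 4:
        return np.empty(0)
    v = np.diff(xyz, axis=0)
    out = []
    for i in range(len(v) - 2):
        v1, v2, v3 = v[i], v[i + 1], v[i + 2]
        n = np.linalg.norm(v1) * np.linalg.norm(v2) * np.linalg.norm(v3)
        if n == 0:
            continue
        out.append(float(np.dot(np.cross(v1, v2), v3) / n))
    return np.asarray(out)


def helicity(morph: Morphology, decomp: SegmentDecomposition) -> dict:
    """Mean helicity over all windows of all segments (sign = handedness)."""
    windows = [polyline_helicity(morph.xyz[seg.points]) for seg in decomp.segments]
    windows = [w for w in windows if len(w)]
    if not windows:
        return {"values": np.empty(0), "mean": None}
    all_w = np.concatenate(windows)
    return {"values": all_w, "mean": float(all_w.mean())}


def euclidean_distance_stats(morph: Morphology) -> dict:
    """Unweighted mean and maximum 3D distance of reconstruction points from
    the soma centroid."""
    mask = morph.neurite_mask()
    if not mask.any():
        raise MorphologyError("no reconstruction points")
    d = np.linalg.norm(morph.xyz[mask] - morph.soma_centroid(), axis=1)
    return {"mean": float(d.mean()), "max": float(d.max())}


# ---------------------------------------------------------------------------
# Soma metrics
# ---------------------------------------------------------------------------

def soma_metrics(soma: SomaContourStack) -> dict:
    """Soma volume/surface from the contour stack, and XY-projection metrics.

    Volume integrates the contour areas along the stack (trapezoid rule);
    the lateral surface treats consecutive contours as frusta of their
    perimeters (slant from the spacing and the change of equivalent radius),
    with the two end contours added as caps.  With a single contour only the
    projection metrics are defined.
    """
    contours = soma.contours
    areas = np.array([c.area for c in contours])
    perims = np.array([c.perimeter for c in contours])
    depths = soma.depths
    out: dict = {"volume": None, "surface_area": None}
    if len(contours) >= 2:
        dz = np.abs(np.diff(depths))
        out["volume"] = float(((areas[:-1] + areas[1:]) / 2.0 * dz).sum())
        r_eff = np.sqrt(areas / math.pi)
        slant = np.sqrt(dz**2 + np.diff(r_eff) ** 2)
        lateral = float(((perims[:-1] + perims[1:]) / 2.0 * slant).sum())
        out["surface_area"] = lateral + float(areas[0] + areas[-1])
    union = unary_union([c.polygon for c in contours])
    out["projection_area"] = float(union.area)
    out["projection_perimeter"] = float(union.length)
    try:
        hull = convex_hull_2d(np.vstack([c.vertices for c in contours]))
        out["feret_max"], out["feret_min"] = hull.feret_max, hull.feret_min
    except DegenerateGeometryError:
        out["feret_max"] = out["feret_min"] = None
    return out


# ---------------------------------------------------------------------------
# Diameter correction and capacitance
# ---------------------------------------------------------------------------

def thinnest_point_mean(morph: Morphology, decomp: SegmentDecomposition | None = None,
                        n: int = 10) -> float:
    """Mean diameter of the ``n`` thinnest reconstruction points taken on
    ``n`` unique branch segments (per-segment minimum, then the n smallest)."""
    decomp = decomp or decompose_segments(morph)
    if decomp.n_segments < n:
        raise MorphologyError(f"need >= {n} branch segments, have {decomp.n_segments}")
    minima = []
    for seg in decomp.segments:
        owned = seg.points[1:]
        if len(owned):
            minima.append(morph.diameters[owned].min())
    minima = np.sort(np.asarray(minima))
    return float(minima[:n].mean())


def correct_diameters(morph: Morphology, target: float = 0.23, n: int = 10) -> tuple[Morphology, float]:
    """Add one constant to every process diameter so that the mean of the 10
    thinnest points (one per unique segment) equals ``target`` exactly.

    The soma contours are untouched.  Returns the corrected morphology and
    the applied diameter shift (idempotent: re-applying yields shift 0).
    Raises when fewer than ``n`` segments exist or when the shift would make
    any diameter non-positive.
    """
    decomp = decompose_segments(morph)
    shift = target - thinnest_point_mean(morph, decomp, n=n)
    out = morph.copy()
    mask = morph.neurite_mask()
    new_radius = out.radius.copy()
    new_radius[mask] = out.radius[mask] + shift / 2.0
    if (new_radius <= 0).any():
        raise ValidationError("diameter correction would produce non-positive diameters")
    out.radius = new_radius
    out.metadata = {**morph.metadata, "diameter_shift": shift}
    return out, float(shift)


def capacitance_from_area(total_surface_area: float, specific_capacitance: float = 0.01) -> float:
    """Membrane capacitance (pF) from a surface area (µm²) at the standard
    0.01 pF/µm² specific membrane capacitance."""
    return total_surface_area * specific_capacitance


def estimate_capacitance(morph: Morphology, specific_capacitance: float = 0.01,
                         decomp: SegmentDecomposition | None = None) -> float:
    """Expected capacitance from total (soma + dendritic) surface area."""
    decomp = decomp or decompose_segments(morph)
    dendritic = sum(g["surface"] for g in all_segment_geometry(morph, decomp))
    soma_area = 0.0
    if morph.soma is not None:
        sm = soma_metrics(morph.soma)
        soma_area = sm["surface_area"] or 0.0
    return capacitance_from_area(dendritic + soma_area, specific_capacitance)


# ---------------------------------------------------------------------------
# Per-order profiles
# ---------------------------------------------------------------------------

def order_profiles(morph: Morphology, decomp: SegmentDecomposition,
                   scheme: OrderScheme = "central_shaft"):
    """Per-branch-order totals: segment count, length, surface, volume,
    nodes, endings.  Sums over orders equal the whole-cell totals."""
    import pandas as pd

    orders = assign_branch_orders(morph, decomp, scheme)
    geoms = all_segment_geometry(morph, decomp)
    max_order = int(orders.max()) if len(orders) else 0
    rows = []
    for order in range(1, max_order + 1):
        idx = np.flatnonzero(orders == order)
        segs = [decomp.segments[i] for i in idx]
        rows.append(
            {
                "order": order,
                "n_segments": len(idx),
                "length": sum(geoms[i]["path_length"] for i in idx),
                "surface": sum(geoms[i]["surface"] for i in idx),
                "volume": sum(geoms[i]["volume"] for i in idx),
                "n_nodes": sum(1 for s in segs if not s.terminal),
                "n_endings": sum(1 for s in segs if s.terminal),
            }
        )
    return pd.DataFrame(rows).set_index("order") if rows else pd.DataFrame(
        columns=["n_segments", "length", "surface", "volume", "n_nodes", "n_endings"]
    )


# ---------------------------------------------------------------------------
# Whole-cell summary
# ---------------------------------------------------------------------------

#: Field order of the per-cell metric table.
CELL_METRIC_FIELDS = (
    "soma_volume", "soma_surface_area", "soma_projection_area",
    "soma_projection_perimeter", "soma_feret_max", "soma_feret_min",
    "n_primary_dendrites", "main_primary_length", "main_primary_max_diameter",
    "dendritic_length", "dendritic_surface_area", "dendritic_volume",
    "average_diameter", "average_segment_path_length",
    "max_order_shaft", "max_order_centrifugal", "average_partition_asymmetry",
    "n_nodes", "n_endings", "n_segments", "n_varicosities",
    "hull2d_arboreal_area", "hull2d_arboreal_perimeter",
    "hull2d_arboreal_feret_max", "hull2d_arboreal_feret_min",
    "hull2d_lobular_area", "hull2d_lobular_perimeter",
    "hull2d_lobular_feret_max", "hull2d_lobular_feret_min",
    "hull3d_volume", "hull3d_surface_area",
    "euclidean_distance_mean", "euclidean_distance_max",
    "bifurcation_angle_mean", "bifurcation_angle_sd",
    "bifurcation_tilt_mean", "bifurcation_tilt_sd",
    "contraction", "fractal_dimension", "helicity_mean",
    "capacitance",
)


def cell_summary(morph: Morphology, varicosities: Sequence | None = None,
                 y_split: float | None = None) -> dict:
    """Assemble the full per-cell metric row.

    Metrics whose inputs are missing (no soma stack, no split plane, no
    varicosity list) are reported as None.  The average dendritic diameter is
    the unweighted mean over all reconstruction-point diameters; per-cell
    angle/tilt SDs are population SDs over that cell's bifurcations.
    """
    from .geometry import Hull2D  # noqa: F401  (type only)

    decomp = decompose_segments(morph)
    geoms = all_segment_geometry(morph, decomp)
    orders_cf = assign_branch_orders(morph, decomp, "centrifugal")
    orders_sh = assign_branch_orders(morph, decomp, "central_shaft")
    out: dict = {k: None for k in CELL_METRIC_FIELDS}

    if morph.soma is not None:
        sm = soma_metrics(morph.soma)
        out["soma_volume"] = sm["volume"]
        out["soma_surface_area"] = sm["surface_area"]
        out["soma_projection_area"] = sm["projection_area"]
        out["soma_projection_perimeter"] = sm["projection_perimeter"]
        out["soma_feret_max"] = sm["feret_max"]
        out["soma_feret_min"] = sm["feret_min"]

    stems = decomp.stem_segments
    out["n_primary_dendrites"] = len(stems)
    if stems:
        stem_max_d = [morph.diameters[decomp.segments[s].points].max() for s in stems]
        main = stems[int(np.argmax(stem_max_d))]
        out["main_primary_length"] = geoms[main]["path_length"]
        out["main_primary_max_diameter"] = float(max(stem_max_d))

    out["dendritic_length"] = sum(g["path_length"] for g in geoms)
    out["dendritic_surface_area"] = sum(g["surface"] for g in geoms)
    out["dendritic_volume"] = sum(g["volume"] for g in geoms)
    mask = morph.neurite_mask()
    out["average_diameter"] = float(morph.diameters[mask].mean()) if mask.any() else None
    if decomp.n_segments:
        out["average_segment_path_length"] = float(
            np.mean([g["path_length"] for g in geoms])
        )
    out["max_order_shaft"] = int(orders_sh.max()) if len(orders_sh) else None
    out["max_order_centrifugal"] = int(orders_cf.max()) if len(orders_cf) else None
    out["average_partition_asymmetry"] = partition_asymmetry(decomp)
    out["n_nodes"] = decomp.n_nodes
    out["n_endings"] = decomp.n_endings
    out["n_segments"] = decomp.n_segments
    out["n_varicosities"] = len(varicosities) if varicosities is not None else None

    if y_split is not None:
        from .profiles import field_metrics

        fm = field_metrics(morph, y_split)
        for side in ("arboreal", "lobular"):
            hull = fm[side]
            if hull is not None:
                out[f"hull2d_{side}_area"] = hull.area
                out[f"hull2d_{side}_perimeter"] = hull.perimeter
                out[f"hull2d_{side}_feret_max"] = hull.feret_max
                out[f"hull2d_{side}_feret_min"] = hull.feret_min

    try:
        h3 = convex_hull_3d(morph.xyz[mask])
        out["hull3d_volume"] = h3.volume
        out["hull3d_surface_area"] = h3.surface_area
    except DegenerateGeometryError:
        pass

    try:
        ed = euclidean_distance_stats(morph)
        out["euclidean_distance_mean"] = ed["mean"]
        out["euclidean_distance_max"] = ed["max"]
    except MorphologyError:
        pass

    ang = bifurcation_angles(morph, decomp)
    out["bifurcation_angle_mean"], out["bifurcation_angle_sd"] = ang["mean"], ang["sd"]
    tilt = bifurcation_tilts(morph, decomp)
    out["bifurcation_tilt_mean"], out["bifurcation_tilt_sd"] = tilt["mean"], tilt["sd"]

    contractions = [g["contraction"] for g in geoms if g["contraction"] is not None]
    out["contraction"] = float(np.mean(contractions)) if contractions else None
    out["fractal_dimension"] = fractal_dimension(morph, decomp)["mean"]
    out["helicity_mean"] = helicity(morph, decomp)["mean"]
    total_area = (out["dendritic_surface_area"] or 0.0) + (out["soma_surface_area"] or 0.0)
    out["capacitance"] = capacitance_from_area(total_area)
    return out
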