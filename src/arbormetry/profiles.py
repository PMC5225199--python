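"""Sholl-sphere analysis, laminar profiles, dendritic-field hulls, and the
branch-density / territory-volume scaling fit.

Sholl analysis uses nested concentric spheres (default 1 µm separation)
centred at the soma centroid.  Intersections count every geometric crossing
of an edge with a sphere (an edge crossing k spheres contributes to each; a
tangent touch without passing counts zero); shell quantities are computed by
clipping edges at sphere boundaries, and point-like quantities (nodes,
endings, varicosities) are binned by distance, with a point exactly on a
sphere assigned to the inner shell.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branches import SegmentDecomposition, decompose_segments, frustum_lateral_area
from .geometry import Hull2D, convex_hull_2d
from .morphology import (
    LAYER_BINS,
    DegenerateGeometryError,
    FieldSplit,
    LayerModel,
    Morphology,
    MorphologyError,
    split_dendritic_fields,
)

#: Reference scaling line for arbor density against territory volume
#: (log10 slope, log10 intercept) reported for a broad multi-type neuron
#: sample by Teeter & Stevens.
TEETER_STEVENS_REFERENCE = (-0.55, 0.45)


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

@dataclass
class ShollProfile:
    """Per-sphere intersections and per-shell totals."""

    step: float
    radii: np.ndarray          # sphere radii, step, 2*step, ...
    intersections: np.ndarray  # crossings per sphere
    shells: pd.DataFrame       # per shell: length, surface, volume, counts

    @property
    def enclosing_radius(self) -> float:
        """Radius of the outermost crossed sphere."""
        nz = np.flatnonzero(self.intersections > 0)
        return float(self.radii[nz[-1]]) if len(nz) else 0.0


def _shell_index(d: np.ndarray, step: float) -> np.ndarray:
    """Shell of a point at distance d; exact multiples go to the inner shell."""
    return np.maximum(np.ceil(np.asarray(d) / step - 1e-12).astype(int) - 1, 0)


def _sphere_crossings(p0, p1, r) -> list[float]:
    """Parameters t in (0, 1] where the edge p0 + t(p1-p0) crosses |p| = r.

    Tangencies (double roots) are skipped: touching without passing counts
    zero.  An endpoint exactly on the sphere registers at t = 1 only, so a
    path through an on-sphere vertex is counted once.
    """
    v = p1 - p0
    a = float(np.dot(v, v))
    if a == 0:
        return []
    b = 2.0 * float(np.dot(p0, v))
    c = float(np.dot(p0, p0)) - r * r
    disc = b * b - 4 * a * c
    if disc <= 0:
        return []
    sq = math.sqrt(disc)
    out = []
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 < t <= 1.0:
            out.append(t)
    return out


def sholl_profile(
    morph: Morphology,
    step: float = 1.0,
    varicosities: list | None = None,
    decomp: SegmentDecomposition | None = None,
) -> ShollProfile:
    """Sholl analysis around the soma centroid.

    Shell quantities (length, frusta surface/volume, length-weighted mean
    diameter) are conserved: their sums equal the whole-cell totals.
    """
    if step <= 0:
        raise ValueError("Sholl step must be positive")
    decomp = decomp or decompose_segments(morph)
    center = morph.soma_centroid()
    mask = morph.neurite_mask()
    rel = morph.xyz - center
    dist = np.linalg.norm(rel, axis=1)
    max_d = dist[mask].max() if mask.any() else 0.0
    n_shells = max(int(math.ceil(max_d / step - 1e-12)), 1)
    radii = step * np.arange(1, n_shells + 1)

    intersections = np.zeros(n_shells, dtype=int)
    length = np.zeros(n_shells)
    surface = np.zeros(n_shells)
    volume = np.zeros(n_shells)
    diam_weighted = np.zeros(n_shells)

    pi_arr, ci_arr = morph.edges()
    for p, cidx in zip(pi_arr, ci_arr):
        if not (mask[p] and mask[cidx]):
            continue
        p0, p1 = rel[p], rel[cidx]
        r0, r1 = morph.radius[p], morph.radius[cidx]
        edge_len = float(np.linalg.norm(p1 - p0))
        if edge_len == 0:
            continue
        # closest approach of the segment to the centre (may undercut both ends)
        v = p1 - p0
        t_star = min(max(-float(np.dot(p0, v)) / float(np.dot(v, v)), 0.0), 1.0)
        d_min = float(np.linalg.norm(p0 + t_star * v))
        lo = int(math.floor(d_min / step))
        hi = int(math.ceil(max(dist[p], dist[cidx]) / step))
        ts = []
        for m in range(max(lo, 1), min(hi, n_shells) + 1):
            cross = _sphere_crossings(p0, p1, m * step)
            intersections[m - 1] += len(cross)
            ts.extend(cross)
        cuts = sorted({0.0, 1.0, *[t for t in ts if 0 < t < 1]})
        for t0, t1 in zip(cuts[:-1], cuts[1:]):
            tm = (t0 + t1) / 2.0
            dm = float(np.linalg.norm(p0 + tm * (p1 - p0)))
            k = min(_shell_index(np.array([dm]), step)[0], n_shells - 1)
            sub_len = edge_len * (t1 - t0)
            ra = r0 + t0 * (r1 - r0)
            rb = r0 + t1 * (r1 - r0)
            length[k] += sub_len
            surface[k] += frustum_lateral_area(ra, rb, sub_len)
            volume[k] += math.pi * sub_len / 3.0 * (ra**2 + ra * rb + rb**2)
            diam_weighted[k] += sub_len * (ra + rb)  # mean diameter * length

    nodes = np.zeros(n_shells, dtype=int)
    endings = np.zeros(n_shells, dtype=int)
    if len(decomp.node_points):
        for k in _shell_index(dist[decomp.node_points], step):
            nodes[min(k, n_shells - 1)] += 1
    if len(decomp.ending_points):
        for k in _shell_index(dist[decomp.ending_points], step):
            endings[min(k, n_shells - 1)] += 1
    n_var = np.zeros(n_shells, dtype=int)
    if varicosities:
        vd = np.array([np.linalg.norm(v.location - center) for v in varicosities])
        for k in _shell_index(vd, step):
            n_var[min(k, n_shells - 1)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_diam = np.where(length > 0, diam_weighted / np.maximum(length, 1e-300), np.nan)
    shells = pd.DataFrame(
        {
            "radius": radii,
            "length": length,
            "surface": surface,
            "volume": volume,
            "n_nodes": nodes,
            "n_endings": endings,
            "n_varicosities": n_var,
            "mean_diameter": mean_diam,
        }
    )
    shells.index.name = "shell"
    return ShollProfile(step=step, radii=radii, intersections=intersections, shells=shells)


# ---------------------------------------------------------------------------
# Laminar profile
# ---------------------------------------------------------------------------

def laminar_profile(
    morph: Morphology,
    layers: LayerModel | None = None,
    varicosities: list | None = None,
    decomp: SegmentDecomposition | None = None,
) -> pd.DataFrame:
    """Process length, nodes and varicosities per retinal layer/stratum.

    Edges are clipped at the layer boundaries (linear interpolation of the
    depth coordinate); fractions per metric sum to 1.
    """
    layers = layers or morph.layers
    if layers is None:
        raise MorphologyError("no layer model available")
    decomp = decomp or decompose_segments(morph)
    mask = morph.neurite_mask()
    bounds = layers.stratum_boundaries()

    length = np.zeros(len(LAYER_BINS))
    pi_arr, ci_arr = morph.edges()
    for p, cidx in zip(pi_arr, ci_arr):
        if not (mask[p] and mask[cidx]):
            continue
        y0, y1 = morph.xyz[p, 1], morph.xyz[cidx, 1]
        edge_len = float(np.linalg.norm(morph.xyz[cidx] - morph.xyz[p]))
        if edge_len == 0:
            continue
        ts = sorted(
            {0.0, 1.0}
            | {
                (b - y0) / (y1 - y0)
                for b in bounds
                if y1 != y0 and 0.0 < (b - y0) / (y1 - y0) < 1.0
            }
        )
        for t0, t1 in zip(ts[:-1], ts[1:]):
            ym = y0 + (t0 + t1) / 2.0 * (y1 - y0)
            k = layers.bin_depths(np.array([ym]))[0]
            length[k] += edge_len * (t1 - t0)

    nodes = np.zeros(len(LAYER_BINS), dtype=int)
    for k in layers.bin_depths(morph.xyz[decomp.node_points, 1]) if len(decomp.node_points) else []:
        nodes[k] += 1
    endings = np.zeros(len(LAYER_BINS), dtype=int)
    for k in layers.bin_depths(morph.xyz[decomp.ending_points, 1]) if len(decomp.ending_points) else []:
        endings[k] += 1
    n_var = np.zeros(len(LAYER_BINS), dtype=int)
    if varicosities:
        for k in layers.bin_depths(np.array([v.y for v in varicosities])):
            n_var[k] += 1

    df = pd.DataFrame(
        {
            "length": length,
            "n_nodes": nodes,
            "n_endings": endings,
            "n_varicosities": n_var,
        },
        index=pd.Index(LAYER_BINS, name="layer"),
    )
    for col in ("length", "n_nodes", "n_varicosities"):
        total = df[col].sum()
        df[f"{col}_fraction"] = df[col] / total if total > 0 else 0.0
    return df


# ---------------------------------------------------------------------------
# Dendritic-field hulls
# ---------------------------------------------------------------------------

def field_metrics(
    morph: Morphology,
    y_split: float,
    varicosities: list | None = None,
) -> dict:
    """Arboreal (proximal) and lobular (distal) dendritic-field hulls.

    Both fields are projected onto the XZ plane (the retinal surface); the
    hulls use every reconstruction point of the field.  A field with fewer
    than three non-collinear points has no hull (None).
    """
    split = split_dendritic_fields(morph, y_split)

    def _hull(point_mask: np.ndarray) -> Hull2D | None:
        pts = morph.xyz[point_mask][:, [0, 2]]
        if len(pts) < 3:
            return None
        try:
            return convex_hull_2d(pts)
        except DegenerateGeometryError:
            return None

    arboreal = _hull(split.proximal_mask)
    lobular = _hull(split.distal_mask)
    out = {
        "split": split,
        "arboreal": arboreal,
        "lobular": lobular,
        "arboreal_larger": None,
    }
    if arboreal is not None and lobular is not None:
        out["arboreal_larger"] = bool(arboreal.area > lobular.area)
    if varicosities is not None:
        out["n_varicosities_distal"] = sum(1 for v in varicosities if v.y <= y_split)
        out["n_varicosities_proximal"] = sum(1 for v in varicosities if v.y > y_split)
    return out


# ---------------------------------------------------------------------------
# Density-territory scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    """Least-squares line through (log10 territory volume, log10 density)."""

    slope: float
    intercept: float
    volumes: np.ndarray
    densities: np.ndarray
    reference: tuple[float, float] = TEETER_STEVENS_REFERENCE

    def predict_density(self, volume: np.ndarray) -> np.ndarray:
        return 10 ** (self.intercept + self.slope * np.log10(volume))


def density_scaling_fit(volumes, lengths) -> ScalingFit:
    """Fit log10(density) = intercept + slope * log10(volume).

    ``density`` is total branch length over 3D convex-hull (territory)
    volume for each cell.
    """
    v = np.asarray(volumes, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if len(v) != len(ln) or len(v) < 2:
        raise ValueError("need >= 2 cells with matching volumes and lengths")
    if (v <= 0).any() or (ln <= 0).any():
        raise ValueError("volumes and lengths must be positive")
    dens = ln / v
    slope, intercept = np.polyfit(np.log10(v), np.log10(dens), 1)
    return ScalingFit(slope=float(slope), intercept=float(intercept), volumes=v, densities=dens)
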