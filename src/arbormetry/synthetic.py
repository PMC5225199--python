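"""Deterministic fixtures and a stochastic bistratified arbor generator.

The generator emulates narrow-field, bistratified AII-amacrine-like cells: a
soma at the INL/IPL border, a thick apical dendrite descending through
sublamina a (S1–S2) while emitting lobular side branches that end in large
appendages, and a conical arboreal subtree that ramifies through sublamina b
(S3–S5).  Default parameters reproduce the published population ranges for
this cell type: total dendritic length ≈ 500–1630 µm, 46–311 branch nodes,
1–9 stems, mean branch-segment path length ≈ 3.19 µm, arboreal field areas
of a few hundred to ~1500 µm², 59–268 varicosities per cell with diameters
0.39–2.7 µm, and a bimodal depth profile peaking in S2 and S4–S5.

Varicosities are inserted by locally scaling radii so that the peak/flank
diameter ratio is at least 2.0, comfortably clear of the 1.8 detection
threshold, and the ground truth records every insertion.  All randomness
comes from a single seeded generator threaded through every draw; the same
seed reproduces byte-identical serialized output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .morphology import (
    LayerModel,
    Morphology,
    MorphologyError,
    PointLabel,
    SomaContour,
    SomaContourStack,
    frustum_lateral_area,
    write_annotation,
    write_swc,
)


class GenerationError(MorphologyError):
    """Infeasible generator parameters."""


# ---------------------------------------------------------------------------
# Point builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.xyz: list[list[float]] = []
        self.radius: list[float] = []
        self.labels: list[int] = []
        self.parents: list[int] = []

    def add(self, xyz: Sequence[float], radius: float, parent: int, label: int = 0) -> int:
        self.xyz.append([float(v) for v in xyz])
        self.radius.append(float(radius))
        self.labels.append(int(label))
        self.parents.append(int(parent))
        return len(self.xyz) - 1

    def morphology(self, soma=None, layers=None, metadata=None) -> Morphology:
        n = len(self.xyz)
        return Morphology(
            ids=np.arange(1, n + 1),
            parents=np.asarray(self.parents, dtype=int),
            xyz=np.asarray(self.xyz, dtype=float),
            radius=np.asarray(self.radius, dtype=float),
            labels=np.asarray(self.labels, dtype=int),
            soma=soma,
            layers=layers,
            metadata=metadata or {},
        )


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, **kwargs) -> Morphology:
    """Build a named analytic fixture with closed-form metric values.

    Available: cylinder, y_tree, caterpillar, balanced_tree, square_arbor,
    helix, radial_ray.
    """
    builders = {
        "cylinder": _fixture_cylinder,
        "y_tree": _fixture_y_tree,
        "caterpillar": _fixture_caterpillar,
        "balanced_tree": _fixture_balanced_tree,
        "square_arbor": _fixture_square_arbor,
        "helix": _fixture_helix,
        "radial_ray": _fixture_radial_ray,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(builders)}")
    return builders[name](**kwargs)


def _fixture_cylinder(radius: float = 0.5, length: float = 10.0, n_points: int = 11,
                      axis: str = "y") -> Morphology:
    """A straight constant-radius cable: one segment, lateral surface 2πrL."""
    b = _Builder()
    k = {"x": 0, "y": 1, "z": 2}[axis]
    prev = -1
    for i in range(n_points):
        p = [0.0, 0.0, 0.0]
        p[k] = length * i / (n_points - 1)
        prev = b.add(p, radius, prev)
    return b.morphology()


def _fixture_y_tree(stem_length: float = 5.0, daughter_length: float = 5.0,
                    half_angle_deg: float = 45.0) -> Morphology:
    """A stem plus two terminal daughters at ±half_angle from the stem axis.

    The daughters' chords subtend 2·half_angle; with the default 45° the
    bifurcation amplitude is 90°.  The first daughter is thicker, so under
    central-shaft ordering it continues at order 1.
    """
    b = _Builder()
    root = b.add([0, 0, 0], 0.5, -1)
    node = b.add([0, stem_length, 0], 0.5, root)
    a = math.radians(half_angle_deg)
    dx, dy = daughter_length * math.sin(a), daughter_length * math.cos(a)
    b.add([dx, stem_length + dy, 0], 0.4, node)
    b.add([-dx, stem_length + dy, 0], 0.25, node)
    return b.morphology()


def _fixture_caterpillar(k: int = 5, segment_length: float = 3.0) -> Morphology:
    """A main shaft with k single terminal side branches.

    k bifurcations, k+1 endings, 2k+1 segments; max central-shaft order 2
    (the thick shaft continues), max centrifugal order k+1.
    """
    if k < 1:
        raise ValueError("caterpillar needs k >= 1")
    b = _Builder()
    prev = b.add([0, 0, 0], 0.5, -1)
    for i in range(1, k + 1):
        node = b.add([0, segment_length * i, 0], 0.5, prev)
        side = 1.0 if i % 2 else -1.0
        b.add([side * segment_length, segment_length * i, 0], 0.3, node)
        prev = node
    b.add([0, segment_length * (k + 1), 0], 0.5, prev)
    return b.morphology()


def _fixture_balanced_tree(depth: int = 3, stem_length: float = 5.0,
                           spread_deg: float = 40.0) -> Morphology:
    """A perfectly balanced binary tree: 2^depth − 1 nodes, 2^depth endings."""
    if depth < 1:
        raise ValueError("balanced_tree needs depth >= 1")
    b = _Builder()
    root = b.add([0, 0, 0], 0.6, -1)

    def grow(parent: int, pos, direction, level: int, length: float, radius: float) -> None:
        end = np.asarray(pos) + length * np.asarray(direction)
        node = b.add(end, radius, parent)
        if level == depth + 1:
            return
        a = math.radians(spread_deg)
        d = np.asarray(direction)
        # rotate in the plane spanned by d and a lateral axis alternating with level
        lateral = np.array([1.0, 0.0, 0.0]) if level % 2 == 0 else np.array([0.0, 0.0, 1.0])
        lateral = lateral - d * np.dot(lateral, d)
        lateral /= np.linalg.norm(lateral)
        for sign in (1.0, -1.0):
            nd = math.cos(a) * d + sign * math.sin(a) * lateral
            grow(node, end, nd / np.linalg.norm(nd), level + 1, length * 0.7, radius * 0.8)

    grow(root, [0, 0, 0], [0, 1, 0], 1, stem_length, 0.6)
    return b.morphology()


def _fixture_square_arbor(half_width: float = 8.0, y_top: float = 10.0,
                          y_bottom: float = 30.0, radius: float = 0.4) -> Morphology:
    """A shaft with two identical four-ray crosses, mirror-symmetric about
    the mid-depth plane; splitting there yields two identical fields."""
    b = _Builder()
    y_mid1 = y_top + (y_bottom - y_top) * 0.25
    y_mid2 = y_top + (y_bottom - y_top) * 0.75
    root = b.add([0, y_top, 0], radius, -1)
    n1 = b.add([0, y_mid1, 0], radius, root)
    for dx, dz in ((half_width, 0), (-half_width, 0), (0, half_width), (0, -half_width)):
        b.add([dx, y_mid1, dz], radius, n1)
    n2 = b.add([0, y_mid2, 0], radius, n1)
    for dx, dz in ((half_width, 0), (-half_width, 0), (0, half_width), (0, -half_width)):
        b.add([dx, y_mid2, dz], radius, n2)
    b.add([0, y_bottom, 0], radius, n2)
    return b.morphology()


def _fixture_helix(pitch: float = 2.0, radius: float = 1.0, turns: float = 2.0,
                   points_per_turn: int = 16, handedness: int = 1) -> Morphology:
    """A helical path around the Y axis; handedness flips the mirror image."""
    b = _Builder()
    n = int(points_per_turn * turns) + 1
    prev = -1
    for i in range(n):
        theta = 2 * math.pi * i / points_per_turn
        x = radius * math.cos(theta)
        z = handedness * radius * math.sin(theta)
        y = pitch * theta / (2 * math.pi)
        prev = b.add([x, y, z], 0.3, prev)
    return b.morphology()


def _fixture_radial_ray(length: float = 10.5, spacing: float = 0.5) -> Morphology:
    """A straight ray from the origin along +X, sampled every ``spacing``."""
    b = _Builder()
    n = int(round(length / spacing))
    prev = -1
    for i in range(n + 1):
        prev = b.add([spacing * i, 0, 0], 0.4, prev)
    return b.morphology()


# ---------------------------------------------------------------------------
# Generator parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the bistratified arbor generator.

    Defaults emulate the published population statistics for AII amacrine
    cells (see the module docstring); lengths in µm.
    """

    # layer frame: soma centre at the origin, IPL between the two depths
    y_inl_ipl: float = 2.0
    y_ipl_gcl: float = 52.0
    # stems: distribution over 1..9 primary dendrites (mean ≈ 3.4)
    n_stems_weights: tuple[float, ...] = (0.10, 0.20, 0.22, 0.18, 0.12, 0.08, 0.05, 0.03, 0.02)
    # branch-segment path lengths
    mean_segment_length: float = 3.19
    segment_length_sd: float = 0.80
    point_spacing: float = 1.1
    # topology
    node_target_range: tuple[int, int] = (60, 195)
    bifurcation_probability: float = 0.78
    # geometry
    arboreal_radius: float = 20.0
    lobular_radius_fraction: float = 0.55
    size_scale: float = 1.0
    # diameters
    apical_diameter: float = 3.05
    apical_taper: float = 0.93
    daughter_taper_main: float = 0.94
    daughter_taper_side: float = 0.80
    min_diameter: float = 0.32
    diameter_jitter: float = 0.015
    # varicosities
    varicosity_rate: float = 0.115          # insertions per µm of dendrite
    varicosity_log_mu: float = -0.38        # lognormal of diameter, µm
    varicosity_log_sigma: float = 0.33
    varicosity_diameter_range: tuple[float, float] = (0.39, 2.7)
    varicosity_lobular_boost: float = 1.35  # S1–S2 appendages are larger
    varicosity_min_ratio: float = 2.1       # peak/flank, clear of the 1.8 cut
    # field split
    y_split: float = 22.0                   # S2/S3 border

    @property
    def layers(self) -> LayerModel:
        return LayerModel(self.y_inl_ipl, self.y_ipl_gcl)


@dataclass
class InsertedVaricosity:
    point_index: int
    x: float
    y: float
    z: float
    diameter: float
    terminal: bool


@dataclass
class GroundTruth:
    """Exact bookkeeping of everything the generator planted."""

    varicosities: list[InsertedVaricosity] = field(default_factory=list)
    segment_orders: dict[int, tuple[int, int]] = field(default_factory=dict)
    # keyed by segment end-point index: (centrifugal, central-shaft) order
    y_split: float = 0.0
    distal_area: float = 0.0
    proximal_area: float = 0.0
    n_nodes: int = 0
    n_stems: int = 0
    total_length: float = 0.0

    @property
    def n_varicosities(self) -> int:
        return len(self.varicosities)

    @property
    def distal_fraction(self) -> float:
        total = self.distal_area + self.proximal_area
        return 100.0 * self.distal_area / total if total > 0 else math.nan


# ---------------------------------------------------------------------------
# Generator internals
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


class _Grower:
    """Stochastic growth of one bistratified cell."""

    def __init__(self, params: GeneratorParams, rng: np.random.Generator) -> None:
        self.p = params
        self.rng = rng
        self.b = _Builder()
        self.gt = GroundTruth(y_split=params.y_split)
        self.n_nodes = 0
        # per-point segment bookkeeping for varicosity insertion
        self.segment_points: list[list[int]] = []   # owned points per created segment
        self.segment_terminal: list[bool] = []
        self.segment_layerish: list[str] = []       # "lobular" or "arboreal"
        self.segment_orders: list[tuple[int, int]] = []

    # -- low-level ---------------------------------------------------------

    def _seg_length(self) -> float:
        v = self.rng.normal(self.p.mean_segment_length, self.p.segment_length_sd)
        return float(min(max(v, 1.4), 6.5))

    def _polyline(self, start_idx: int, start: np.ndarray, direction: np.ndarray,
                  length: float, d0: float, d1: float, label: int,
                  wiggle: float = 0.12, curve_sd: float = 0.0,
                  ) -> tuple[int, np.ndarray, np.ndarray, list[int]]:
        """Grow a meandering polyline of ``length`` µm.

        ``curve_sd`` draws one persistent curvature vector per polyline
        (smooth arc-like bending, which lowers contraction without making the
        path walk-like); ``wiggle`` adds small white directional jitter.
        Returns (end point index, end position, end direction, owned points).
        """
        n_steps = max(int(round(length / self.p.point_spacing)), 1)
        step = length / n_steps
        pos = start.copy()
        d = _unit(direction)
        # constant angular-velocity vector: each step rotates the heading by
        # roughly |omega| radians about a fixed random axis (smooth arcs)
        omega = curve_sd * self.rng.normal(size=3) if curve_sd > 0 else np.zeros(3)
        prev = start_idx
        owned = []
        for i in range(1, n_steps + 1):
            d = _unit(d + np.cross(omega, d) + wiggle * self.rng.normal(size=3))
            pos = pos + step * d
            # the first own point carries exactly d0: daughter thickness
            # ordering at branch points is then independent of step count
            frac = (i - 1) / n_steps
            jitter = 0.0 if i == 1 else self.p.diameter_jitter * self.rng.uniform(-1, 1)
            diam = (d0 + (d1 - d0) * frac) * (1 + jitter)
            prev = self.b.add(pos, max(diam, 0.1) / 2.0, prev, label)
            owned.append(prev)
        return prev, pos, d, owned

    def _record_segment(self, owned: list[int], terminal: bool, kind: str,
                        order_cf: int, order_shaft: int) -> None:
        self.segment_points.append(owned)
        self.segment_terminal.append(terminal)
        self.segment_layerish.append(kind)
        self.segment_orders.append((order_cf, order_shaft))
        if owned:
            self.gt.segment_orders[owned[-1]] = (order_cf, order_shaft)

    # -- soma --------------------------------------------------------------

    def soma(self) -> SomaContourStack:
        rx = 4.2 * self.p.size_scale**0.5
        rz = 3.4 * self.p.size_scale**0.5
        zs = np.arange(-rz + 0.4, rz - 0.399, 0.8)
        contours = []
        for z in zs:
            r = rx * math.sqrt(max(1.0 - (z / rz) ** 2, 0.02))
            theta = np.linspace(0, 2 * math.pi, 25)[:-1]
            verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            contours.append(SomaContour(depth=float(z), vertices=verts))
        return SomaContourStack(contours)

    # -- lobular branches ---------------------------------------------------

    def lobular_branch(self, parent_idx: int, pos: np.ndarray, order_cf: int,
                       order_shaft: int, budget_ok: bool) -> None:
        """A laterally spreading lobular process in sublamina a.

        Grows outward as a short caterpillar: a chain of branch segments that
        drifts toward mid-S2 and emits terminal stub daughters along the way,
        ending in a large terminal appendage site.  This keeps individual
        segments short while letting the lobular field reach its published
        Feret widths.
        """
        p = self.p
        rng = self.rng
        phi = rng.uniform(0, 2 * math.pi)
        azimuth = np.array([math.cos(phi), 0.0, math.sin(phi)])
        y_target = rng.uniform(13.0, 21.0)
        n_chain = int(rng.integers(3, 7))
        d0 = rng.uniform(0.8, 1.05)
        idx, cpos = parent_idx, pos
        edir = azimuth
        ocf, osh = order_cf, order_shaft
        for j in range(n_chain):
            reach = self._seg_length()
            vy = min(max((y_target - cpos[1]) / max(reach, 1.0), -0.4), 0.5)
            aim = _unit(azimuth + np.array([0.0, vy, 0.0]))
            direction = _unit(0.3 * edir + aim)
            d1 = d0 * 0.85
            idx, cpos, edir, owned = self._polyline(idx, cpos, direction, reach,
                                                    d0, d1, int(PointLabel.LOBULAR),
                                                    wiggle=0.12, curve_sd=0.30)
            last = j == n_chain - 1
            can_branch = budget_ok and self.n_nodes < self._node_target
            if last or not (can_branch and rng.uniform() < 0.60):
                self._record_segment(owned, True, "lobular", ocf, osh)
                return
            # bifurcate into a terminal stub and the continuing chain
            self.n_nodes += 1
            self._record_segment(owned, False, "lobular", ocf, osh)
            axis = _unit(np.cross(edir, [0.0, 1.0, 0.0]))
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            sd = _unit(edir + sign * 1.0 * axis + 0.2 * rng.normal(size=3))
            sf = 0.75 * p.min_diameter
            dd = sf + (d1 - sf) * p.daughter_taper_side
            _, _, _, owned2 = self._polyline(idx, cpos, sd, self._seg_length() * 0.8,
                                             dd, dd * 0.85, int(PointLabel.LOBULAR),
                                             wiggle=0.12, curve_sd=0.30)
            self._record_segment(owned2, True, "lobular", ocf + 1, osh + 1)
            d0 = p.min_diameter + (d1 - p.min_diameter) * p.daughter_taper_main
            ocf += 1

    # -- arboreal subtree ---------------------------------------------------

    def _arboreal_direction(self, pos: np.ndarray, d: np.ndarray) -> np.ndarray:
        p = self.p
        lateral = np.array([pos[0], 0.0, pos[2]])
        lat_n = np.linalg.norm(lateral)
        r_max = p.arboreal_radius * p.size_scale
        outward = lateral / lat_n if lat_n > 1e-6 else _unit(np.array([self.rng.normal(), 0, self.rng.normal()]) * [1, 0, 1])
        down = np.array([0.0, 1.0, 0.0])
        frac = (pos[1] - self.p.y_inl_ipl) / (self.p.y_ipl_gcl - self.p.y_inl_ipl)
        if frac < 0.60:        # descend through sublamina a/S3
            target = _unit(0.95 * down + 0.55 * outward)
        elif frac < 0.72:      # keep sinking into S4 before spreading
            target = _unit(0.60 * down + 0.75 * outward)
        else:                  # spread tangentially through S4-S5
            target = _unit(0.22 * down + 0.95 * outward)
        if lat_n > 0.9 * r_max:       # confine within the arboreal field
            target = _unit(target - 1.8 * outward)
        if pos[1] > self.p.y_ipl_gcl - 1.5:   # stay out of the deep GCL
            target = _unit(target - 1.5 * down)
        return _unit(0.7 * d + 0.5 * target)

    def grow_arboreal(self, start_idx: int, pos: np.ndarray, direction: np.ndarray,
                      diameter: float, order_cf: int, order_shaft: int) -> None:
        p = self.p
        # cone: (attach idx, pos, dir, diameter, order_cf, order_shaft, stub)
        cones = [(start_idx, pos, direction, diameter, order_cf, order_shaft, False)]
        guard = 0
        while cones:
            guard += 1
            if guard > 60000:
                raise GenerationError("arboreal growth did not converge")
            i = int(self.rng.integers(len(cones)))
            idx, cpos, cdir, cd, ocf, osh, stub = cones.pop(i)
            # one decomposition segment may span several growth chunks: the
            # dendrite keeps descending through S3 without branching, then
            # branches densely while spreading through S4-S5
            owned: list[int] = []
            end, epos, edir, end_d = idx, cpos, cdir, cd
            floor = p.min_diameter
            while True:
                gdir = self._arboreal_direction(epos, edir)
                new_d = floor + (end_d - floor) * 0.97
                end, epos, edir, chunk = self._polyline(end, epos, gdir, self._seg_length(),
                                                        end_d, new_d, int(PointLabel.ARBOREAL),
                                                        wiggle=0.12, curve_sd=0.35)
                owned.extend(chunk)
                end_d = new_d
                depth_frac = (epos[1] - p.y_inl_ipl) / (p.y_ipl_gcl - p.y_inl_ipl)
                if stub or depth_frac >= 0.60 or self.n_nodes >= self._node_target:
                    break
                if self.rng.uniform() < 0.06:   # rare branching already in S3
                    break
            # the last living cone always branches while budget remains, even
            # a stub, so the tree cannot die before reaching its node target
            branch = self.n_nodes < self._node_target and (
                (not stub and self.rng.uniform() < p.bifurcation_probability)
                or len(cones) == 0
            )
            if branch:
                self.n_nodes += 1
                self._record_segment(owned, False, "arboreal", ocf, osh)
                axis = _unit(np.cross(edir, self.rng.normal(size=3)))
                spread = self.rng.uniform(0.80, 1.45)
                # roughly half the side daughters are short stubs that end
                # after one more segment, skewing the tree toward the
                # chain-like topology of real arbors
                side_stub = self.rng.uniform() < 0.50
                for k, sign in enumerate((1.0, -1.0)):
                    nd = _unit(edir + sign * spread * axis)
                    if k == 0:
                        ndiam = floor + (end_d - floor) * p.daughter_taper_main
                    else:
                        sf = 0.75 * floor
                        ndiam = sf + (end_d - sf) * p.daughter_taper_side
                    cones.append((end, epos, nd, ndiam, ocf + 1,
                                  osh + (0 if k == 0 else 1),
                                  side_stub and k == 1))
            else:
                self._record_segment(owned, True, "arboreal", ocf, osh)

    # -- whole cell ---------------------------------------------------------

    def grow(self, node_target: int | None = None) -> tuple[Morphology, GroundTruth]:
        p = self.p
        lo, hi = p.node_target_range
        self._node_target = node_target if node_target is not None else int(self.rng.integers(lo, hi + 1))
        rng = self.rng

        # primary dendrites: one apical plus lobular stems
        n_stems = 1 + int(rng.choice(len(p.n_stems_weights), p=np.asarray(p.n_stems_weights) / sum(p.n_stems_weights)))
        n_stems = min(n_stems, 9)
        self.gt.n_stems = n_stems

        # apical shaft: descend from the soma through sublamina a, emitting a
        # lobular branch at every apical node so that intermediate branch
        # orders are all populated
        split_y = rng.uniform(22.0, 26.0)
        start = np.array([rng.uniform(-0.5, 0.5), 3.4, rng.uniform(-0.5, 0.5)])
        root = self.b.add(start, p.apical_diameter / 2.0, -1, int(PointLabel.APICAL))
        pos, d = start, _unit(np.array([rng.uniform(-0.15, 0.15), 1.0, rng.uniform(-0.15, 0.15)]))
        idx = root
        diam = p.apical_diameter
        order = 1
        guard = 0
        while pos[1] < split_y - 2.0:
            guard += 1
            if guard > 30:
                raise GenerationError("apical shaft failed to reach the split depth")
            # restoring bias: the shaft always descends toward the IPL
            d = _unit(np.array([rng.normal(0, 0.18), 1.0, rng.normal(0, 0.18)]))
            end_d = diam * p.apical_taper
            idx, pos, d, owned = self._polyline(idx, pos, d, self._seg_length(),
                                                diam, end_d, int(PointLabel.APICAL),
                                                wiggle=0.12)
            diam = end_d
            self.n_nodes += 1
            self._record_segment(owned, False, "apical", order, 1)
            if pos[1] <= 20.0:
                self.lobular_branch(idx, pos, order + 1, 2, budget_ok=True)
                self.lobular_branch(idx, pos, order + 1, 2, budget_ok=True)
                if pos[1] > 10.0 and rng.uniform() < 0.6:
                    self.lobular_branch(idx, pos, order + 1, 2, budget_ok=True)
            else:
                self.lobular_branch(idx, pos, order + 1, 2, budget_ok=True)
            order += 1
        # short apical extension to a dedicated split node, then the conical
        # arboreal arborization
        end_d = diam * p.apical_taper
        idx, pos, d, owned = self._polyline(idx, pos, d, self._seg_length(),
                                            diam, end_d, int(PointLabel.APICAL), wiggle=0.12)
        diam = end_d
        self.n_nodes += 1
        self._record_segment(owned, False, "apical", order, 1)
        order += 1
        n_daughters = 2 if rng.uniform() < 0.7 else 3
        axis = _unit(np.cross(d, rng.normal(size=3)))
        for k in range(n_daughters):
            ang = 0.5 + 0.25 * k
            sign = 1.0 if k % 2 == 0 else -1.0
            nd = _unit(d + sign * ang * axis + 0.2 * rng.normal(size=3))
            taper = p.daughter_taper_main if k == 0 else p.daughter_taper_side
            self.grow_arboreal(idx, pos, nd, max(diam * 0.55 * taper, p.min_diameter),
                               order, 1 if k == 0 else 2)

        # extra lobular stems directly from the soma
        for _ in range(n_stems - 1):
            phi = rng.uniform(0, 2 * math.pi)
            sstart = np.array([3.2 * math.cos(phi), rng.uniform(1.5, 3.2), 3.0 * math.sin(phi)])
            sroot = self.b.add(sstart, rng.uniform(0.45, 0.6), -1, int(PointLabel.LOBULAR))
            self.lobular_branch(sroot, sstart, 1, 1, budget_ok=True)

        morph = self.b.morphology(soma=self.soma(), layers=p.layers,
                                  metadata={"generator": "arbormetry.synthetic"})
        self.gt.n_nodes = self.n_nodes
        return morph, self.gt


# ---------------------------------------------------------------------------
# Varicosity insertion
# ---------------------------------------------------------------------------

def _insert_varicosities(morph: Morphology, gt: GroundTruth, grower: _Grower,
                         rng: np.random.Generator, params: GeneratorParams) -> None:
    p = params
    total_length = morph.total_path_length()
    gt.total_length = total_length
    n_target = int(round(p.varicosity_rate * total_length))
    lo_d, hi_d = p.varicosity_diameter_range
    diam = morph.diameters
    layers = params.layers

    # path neighbours: the morphology's own parent links give the proximal
    # neighbour; the distal neighbour is the next owned point in the segment
    parents = morph.parents
    sites: list[tuple[int, list[int], bool]] = []   # (point, path neighbours, terminal)
    taken: set[int] = set()

    # terminal appendages first: lobular tips almost always swell
    for owned, terminal, kind in zip(grower.segment_points, grower.segment_terminal,
                                     grower.segment_layerish):
        if not terminal or not owned:
            continue
        prob = 0.85 if kind == "lobular" else 0.30
        if rng.uniform() < prob and len(owned) >= 2:
            tip = owned[-1]
            sites.append((tip, [int(parents[tip])], True))
            taken.update((int(parents[tip]), tip))

    # interior swellings, at least one plain point away from each other and
    # from segment ends so the flanks stay clear
    pool: list[tuple[int, int]] = []
    for owned in grower.segment_points:
        if len(owned) >= 4:
            pool.extend((pt, nxt) for pt, nxt in zip(owned[1:-2], owned[2:-1]))
    rng.shuffle(pool)
    for pt, nxt in pool:
        if len(sites) >= n_target:
            break
        prev = int(parents[pt])
        if taken & {prev, pt, nxt}:
            continue
        sites.append((pt, [prev, nxt], False))
        taken.update((prev, pt, nxt))

    radius = morph.radius.copy()
    for pt, neighbors_idx, terminal in sites:
        base = max(diam[j] for j in neighbors_idx)
        draw = float(np.exp(rng.normal(p.varicosity_log_mu, p.varicosity_log_sigma)))
        if layers.bin_depths(np.array([morph.xyz[pt, 1]]))[0] in (1, 2):  # S1–S2
            draw *= p.varicosity_lobular_boost
        draw = min(max(draw, lo_d), hi_d)
        needed = p.varicosity_min_ratio * base
        if needed > hi_d:
            continue
        d_final = max(draw, needed)
        radius[pt] = d_final / 2.0
        gt.varicosities.append(
            InsertedVaricosity(
                point_index=int(pt),
                x=float(morph.xyz[pt, 0]),
                y=float(morph.xyz[pt, 1]),
                z=float(morph.xyz[pt, 2]),
                diameter=float(d_final),
                terminal=bool(terminal),
            )
        )
    morph.radius = radius


def _split_areas(morph: Morphology, y_split: float) -> tuple[float, float]:
    """Generator-side surface accounting at the split plane (soma included
    on its own side)."""
    distal = proximal = 0.0
    pi_arr, ci_arr = morph.edges()
    for a, b2 in zip(pi_arr, ci_arr):
        p0, p1 = morph.xyz[a], morph.xyz[b2]
        r0, r1 = morph.radius[a], morph.radius[b2]
        length = float(np.linalg.norm(p1 - p0))
        if length == 0:
            continue
        y0, y1 = p0[1], p1[1]
        if (y0 <= y_split) == (y1 <= y_split):
            area = frustum_lateral_area(r0, r1, length)
            if y0 <= y_split:
                distal += area
            else:
                proximal += area
        else:
            t = (y_split - y0) / (y1 - y0)
            rm = r0 + t * (r1 - r0)
            a0 = frustum_lateral_area(r0, rm, length * t)
            a1 = frustum_lateral_area(rm, r1, length * (1 - t))
            if y0 <= y_split:
                distal += a0
                proximal += a1
            else:
                proximal += a0
                distal += a1
    if morph.soma is not None:
        areas = np.array([c.area for c in morph.soma.contours])
        perims = np.array([c.perimeter for c in morph.soma.contours])
        dz = np.abs(np.diff(morph.soma.depths))
        r_eff = np.sqrt(areas / math.pi)
        lateral = float(((perims[:-1] + perims[1:]) / 2.0 * np.sqrt(dz**2 + np.diff(r_eff) ** 2)).sum())
        soma_area = lateral + float(areas[0] + areas[-1])
        if morph.soma.centroid()[1] <= y_split:
            distal += soma_area
        else:
            proximal += soma_area
    return distal, proximal


# ---------------------------------------------------------------------------
# Public generator API
# ---------------------------------------------------------------------------

def generate_aii(params: GeneratorParams | None = None, seed: int | np.random.Generator = 0,
                 node_target: int | None = None) -> tuple[Morphology, GroundTruth]:
    """Generate one bistratified AII-like cell with complete ground truth.

    Reproducible: the same seed yields byte-identical serialized output.
    """
    params = params or GeneratorParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for attempt in range(3):
        try:
            grower = _Grower(params, rng)
            morph, gt = grower.grow(node_target=node_target)
            break
        except GenerationError:
            if attempt == 2:
                raise
    _insert_varicosities(morph, gt, grower, rng, params)
    gt.distal_area, gt.proximal_area = _split_areas(morph, params.y_split)
    return morph, gt


def densify(morph: Morphology, grower_like_rng: np.random.Generator,
            params: GeneratorParams, target_length: float) -> Morphology:
    """Add short terminal twigs inside the existing arboreal field until the
    total dendritic length reaches ``target_length`` (used for planting the
    density–territory scaling relation without moving the hull)."""
    rng = grower_like_rng
    b = _Builder()
    b.xyz = morph.xyz.tolist()
    b.radius = morph.radius.tolist()
    b.labels = morph.labels.tolist()
    b.parents = morph.parents.tolist()
    current = morph.total_path_length()
    arboreal = np.flatnonzero(morph.labels == int(PointLabel.ARBOREAL))
    if len(arboreal) == 0:
        arboreal = np.arange(morph.n_points)
    center_r = params.arboreal_radius * params.size_scale
    guard = 0
    while current < target_length:
        guard += 1
        if guard > 20000:
            raise GenerationError("densification did not converge")
        anchor = int(rng.choice(arboreal))
        apos = np.asarray(b.xyz[anchor])
        lat = math.hypot(apos[0], apos[2])
        if lat > 0.6 * center_r or not (params.y_inl_ipl + 20 < apos[1] < params.y_ipl_gcl - 1):
            continue
        direction = _unit(np.array([rng.normal(), rng.normal() * 0.3, rng.normal()]))
        if lat > 1e-6:
            outward = np.array([apos[0], 0, apos[2]]) / lat
            direction = _unit(direction - 0.5 * outward)
        length = float(min(max(rng.normal(params.mean_segment_length, params.segment_length_sd), 1.4), 6.5))
        n_steps = max(int(round(length / params.point_spacing)), 1)
        step = length / n_steps
        prev = anchor
        d0 = max(2 * b.radius[anchor] * 0.8, params.min_diameter)
        pos = apos.copy()
        for i in range(1, n_steps + 1):
            direction = _unit(direction + 0.25 * rng.normal(size=3))
            pos = pos + step * direction
            frac = i / n_steps
            diam = max(d0 * (1 - 0.2 * frac), params.min_diameter)
            prev = b.add(pos, diam / 2.0, prev, int(PointLabel.ARBOREAL))
        current += length
    return b.morphology(soma=morph.soma, layers=morph.layers, metadata=dict(morph.metadata))


def generate_population(
    params: GeneratorParams | None = None,
    n: int = 43,
    seed: int = 0,
    plant_scaling: tuple[float, float, float] | None = None,
    volume_range: tuple[float, float] = (9e3, 9e4),
) -> list[tuple[Morphology, GroundTruth]]:
    """Generate a population of cells with sizes spread over a stated
    territory-volume range.

    With ``plant_scaling = (slope, intercept, noise_sd)`` the total dendritic
    length of each cell is planted on the log10 density–volume line
    ``log10(L/V) = intercept + slope * log10(V)`` (plus Gaussian noise in
    log10 density), using the measured convex-hull volume of the grown cell.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        rng = np.random.default_rng(child)
        if plant_scaling is None:
            scale = float(np.exp(rng.uniform(math.log(0.72), math.log(1.38))))
            cell_params = replace(params, size_scale=scale,
                                  arboreal_radius=params.arboreal_radius)
            node_target = int(np.clip(rng.integers(*params.node_target_range) * scale**2, 50, 300))
            out.append(generate_aii(cell_params, rng, node_target=node_target))
            continue
        slope, intercept, noise_sd = plant_scaling
        v_target = float(np.exp(rng.uniform(math.log(volume_range[0]), math.log(volume_range[1]))))
        # hull volume scales roughly with the squared field radius (fixed depth)
        scale = math.sqrt(v_target / 15500.0)
        cell_params = replace(params, size_scale=scale)
        l_pred = 10**intercept * v_target ** (1 + slope)
        node_base = max(20, int(0.30 * l_pred / (2 * params.mean_segment_length)))
        morph, gt = generate_aii(cell_params, rng, node_target=node_base)
        from scipy.spatial import ConvexHull

        noise = 10 ** rng.normal(0.0, noise_sd)
        # densification expands the hull slightly, so re-measure and top up
        for _ in range(2):
            v_actual = float(ConvexHull(morph.xyz[morph.neurite_mask()]).volume)
            l_target = 10**intercept * v_actual ** (1 + slope) * noise
            if morph.total_path_length() < l_target:
                morph = densify(morph, rng, cell_params, l_target)
        gt.total_length = morph.total_path_length()
        out.append((morph, gt))
    return out


def write_population(cells: list[tuple[Morphology, GroundTruth]], directory,
                     seed: int | None = None) -> dict:
    """Write SWC + sidecar + ground-truth CSV per cell plus a manifest."""
    import json

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "n_cells": len(cells), "cells": []}
    rows = []
    for i, (morph, gt) in enumerate(cells):
        stem = f"cell_{i:03d}"
        write_swc(morph, directory / f"{stem}.swc")
        write_annotation(morph, directory / f"{stem}.json")
        for v in gt.varicosities:
            rows.append(
                {
                    "cell": stem, "point_index": v.point_index, "x": v.x, "y": v.y,
                    "z": v.z, "diameter": v.diameter, "terminal": v.terminal,
                }
            )
        manifest["cells"].append(
            {
                "stem": stem,
                "n_varicosities": gt.n_varicosities,
                "n_nodes": gt.n_nodes,
                "distal_fraction": gt.distal_fraction,
                "total_length": gt.total_length,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "ground_truth_varicosities.csv", index=False)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n",
                                             encoding="utf-8", newline="\n")
    return manifest


# ---------------------------------------------------------------------------
# Planted factor structure (for PCA recovery studies)
# ---------------------------------------------------------------------------

def planted_factor_matrix(
    n_cells: int = 40,
    n_metrics: int = 26,
    n_factors: int = 2,
    loading: float = 0.65,
    n_noise_metrics: int = 2,
    seed: int = 0,
):
    """A cells × metrics table with a known number of latent factors.

    Each non-noise metric loads on exactly one factor with the given loading
    ``a``: x = a f + sqrt(1 − a²) ε, with f and ε standard normal, so loaded
    metrics within a block correlate at a².  Returns a DataFrame.
    """
    import pandas as pd

    if n_factors < 1 or n_metrics <= n_noise_metrics:
        raise ValueError("invalid factor-structure shape")
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_cells, n_factors))
    n_loaded = n_metrics - n_noise_metrics
    cols = {}
    for j in range(n_metrics):
        name = f"metric_{j:02d}"
        if j < n_loaded:
            k = j % n_factors
            cols[name] = loading * factors[:, k] + math.sqrt(1 - loading**2) * rng.normal(size=n_cells)
        else:
            cols[name] = rng.normal(size=n_cells)
    return pd.DataFrame(cols)
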