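"""Automated varicosity detection and varicosity statistics.

A varicosity is a spatially discrete swelling whose maximum diameter is at
least 80% larger (peak/flank ratio >= 1.8) than the diameter immediately
before and after the swelling.  The detector runs on the reconstructed
radius profiles along every root-to-tip path: a candidate is a local
diameter maximum; its flank reference on each side is the minimum diameter
reached while the profile keeps decreasing away from the peak, capped at a
path-distance window.  Terminal swellings waive the distal flank.  Detection
is scale invariant (only diameter ratios matter).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .branches import SegmentDecomposition, assign_branch_orders, decompose_segments
from .morphology import LAYER_BINS, LayerModel, Morphology


@dataclass
class Varicosity:
    """A detected dendritic swelling."""

    point_index: int
    x: float
    y: float
    z: float
    diameter: float
    segment: int
    terminal: bool
    order_centrifugal: int | None = None
    order_shaft: int | None = None
    layer: str | None = None

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def _root_to_tip_paths(morph: Morphology) -> list[list[int]]:
    children = morph.children_lists()
    paths: list[list[int]] = []
    for r in morph.root_indices():
        stack = [(r, [r])]
        while stack:
            node, path = stack.pop()
            ch = children[node]
            if not ch:
                if len(path) > 1:
                    paths.append(path)
                continue
            for c in reversed(ch):
                stack.append((c, path + [c]))
    return paths


def detect_varicosities(
    morph: Morphology,
    ratio: float = 1.8,
    flank_window: float = 5.0,
    decomp: SegmentDecomposition | None = None,
    layers: LayerModel | None = None,
) -> list[Varicosity]:
    """Detect varicosities on the radius profile of every root-to-tip path.

    One varicosity per contiguous swelling; the varicosity's diameter and
    location are those of the point of maximal diameter.  Swellings at
    branch points belong to the parent segment (point ownership already
    assigns node points to their parent segment).
    """
    decomp = decomp or decompose_segments(morph)
    layers = layers or morph.layers
    orders_cf = assign_branch_orders(morph, decomp, "centrifugal")
    orders_sh = assign_branch_orders(morph, decomp, "central_shaft")
    diam = morph.diameters
    xyz = morph.xyz

    accepted: dict[int, Varicosity] = {}
    for path in _root_to_tip_paths(morph):
        idx = np.asarray(path)
        d = diam[idx]
        s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xyz[idx], axis=0), axis=1))])
        n = len(idx)
        i = 1
        while i < n:
            # candidate: start of a (possibly flat) run that is a local maximum
            if d[i] <= d[i - 1]:
                i += 1
                continue
            j = i
            while j + 1 < n and d[j + 1] == d[j]:
                j += 1
            if j + 1 < n and d[j + 1] > d[j]:
                i = j + 1
                continue
            # peak run i..j; peak point = first point of the run
            peak = i
            # proximal flank: walk back while non-increasing away from peak
            left_ref = d[peak - 1]
            k = peak - 1
            while k - 1 >= 0 and d[k - 1] <= d[k] and s[peak] - s[k - 1] <= flank_window:
                k -= 1
                left_ref = min(left_ref, d[k])
            # distal flank: walk forward from the end of the run
            terminal = False
            if j == n - 1:
                terminal = True
                right_ref = None
            else:
                right_ref = d[j + 1]
                k = j + 1
                while k + 1 < n and d[k + 1] <= d[k] and s[k + 1] - s[peak] <= flank_window:
                    k += 1
                    right_ref = min(right_ref, d[k])
            # tolerant comparison so a profile at exactly the threshold
            # ratio is accepted despite floating-point rounding
            eps = 1e-9
            ok = left_ref > 0 and d[peak] >= ratio * left_ref * (1 - eps)
            if not terminal:
                ok = ok and right_ref > 0 and d[peak] >= ratio * right_ref * (1 - eps)
            if ok:
                p = int(idx[peak])
                if p not in accepted:
                    seg = int(decomp.point_segment[p])
                    accepted[p] = Varicosity(
                        point_index=p,
                        x=float(xyz[p, 0]),
                        y=float(xyz[p, 1]),
                        z=float(xyz[p, 2]),
                        diameter=float(d[peak]),
                        segment=seg,
                        terminal=bool(terminal),
                        order_centrifugal=int(orders_cf[seg]) if seg >= 0 else None,
                        order_shaft=int(orders_sh[seg]) if seg >= 0 else None,
                        layer=str(layers.bin_names([xyz[p, 1]])[0]) if layers else None,
                    )
            i = j + 1
    return sorted(accepted.values(), key=lambda v: v.point_index)


def varicosity_stats(varicosities: list[Varicosity]) -> dict:
    """Count, diameter statistics, and 3D nearest-neighbour distances.

    Nearest-neighbour statistics require at least two varicosities and are
    reported as None otherwise.
    """
    n = len(varicosities)
    out: dict = {
        "count": n,
        "diameter_mean": None,
        "diameter_sd": None,
        "diameter_min": None,
        "diameter_max": None,
        "nn_mean": None,
        "nn_min": None,
        "nn_max": None,
    }
    if n == 0:
        return out
    diam = np.array([v.diameter for v in varicosities])
    out["diameter_mean"] = float(diam.mean())
    out["diameter_sd"] = float(diam.std())
    out["diameter_min"] = float(diam.min())
    out["diameter_max"] = float(diam.max())
    if n >= 2:
        pts = np.array([v.location for v in varicosities])
        dist, _ = cKDTree(pts).query(pts, k=2)
        nn = dist[:, 1]
        out["nn_mean"] = float(nn.mean())
        out["nn_min"] = float(nn.min())
        out["nn_max"] = float(nn.max())
    return out


def varicosity_profiles(
    morph: Morphology,
    varicosities: list[Varicosity],
    decomp: SegmentDecomposition | None = None,
    scheme: str = "central_shaft",
    layers: LayerModel | None = None,
    sholl_step: float | None = None,
):
    """Per-branch-order, per-layer and (optionally) per-Sholl-shell
    varicosity statistics.

    Per order: count, density (count / total segment length of that order,
    in varicosities/µm; absent for zero-length orders) and mean diameter.
    Layer/shell assignment uses the varicosity location.
    """
    import pandas as pd

    from .branches import all_segment_geometry

    decomp = decomp or decompose_segments(morph)
    layers = layers or morph.layers
    orders = assign_branch_orders(morph, decomp, scheme)  # type: ignore[arg-type]
    geoms = all_segment_geometry(morph, decomp)

    var_orders = np.array(
        [orders[v.segment] if v.segment >= 0 else 0 for v in varicosities], dtype=int
    )
    diam = np.array([v.diameter for v in varicosities])
    rows = []
    for order in range(1, int(orders.max()) + 1 if len(orders) else 1):
        length = sum(g["path_length"] for g, o in zip(geoms, orders) if o == order)
        sel = var_orders == order
        rows.append(
            {
                "order": order,
                "count": int(sel.sum()),
                "density": (sel.sum() / length) if length > 0 else None,
                "diameter_mean": float(diam[sel].mean()) if sel.any() else None,
            }
        )
    by_order = pd.DataFrame(rows).set_index("order")

    by_layer = None
    if layers is not None:
        names = layers.bin_names([v.y for v in varicosities]) if varicosities else np.empty(0, object)
        rows = []
        for bin_name in LAYER_BINS:
            sel = names == bin_name
            rows.append(
                {
                    "layer": bin_name,
                    "count": int(sel.sum()),
                    "diameter_mean": float(diam[sel].mean()) if sel.any() else None,
                    "diameter_max": float(diam[sel].max()) if sel.any() else None,
                }
            )
        by_layer = pd.DataFrame(rows).set_index("layer")

    by_shell = None
    if sholl_step is not None:
        center = morph.soma_centroid()
        d = np.array([np.linalg.norm(v.location - center) for v in varicosities])
        shell_idx = np.maximum(np.ceil(d / sholl_step - 1e-12).astype(int) - 1, 0) if len(d) else np.empty(0, int)
        n_shells = int(shell_idx.max()) + 1 if len(shell_idx) else 0
        rows = [
            {"shell": k, "radius": (k + 1) * sholl_step, "count": int((shell_idx == k).sum())}
            for k in range(n_shells)
        ]
        by_shell = pd.DataFrame(rows).set_index("shell")

    return {"by_order": by_order, "by_layer": by_layer, "by_shell": by_shell}
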