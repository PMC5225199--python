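"""Population statistics: metric-matrix construction and normalization,
redundancy exclusion, correlation-matrix PCA with two eigenvalue null
models, bootstrap coefficient z-scores with sign correction, regressions of
excluded metrics on component scores, Ward clustering, and the analytic /
Monte-Carlo random-branching angle baselines.

PCA operates on metrics centred on their means and normalized to their SD,
i.e. on the correlation matrix, so the eigenvalues sum to the number of
included metrics and the variance fraction of a component is its eigenvalue
divided by that number.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

# ---------------------------------------------------------------------------
# Metric matrix
# ---------------------------------------------------------------------------

#: The default 27-metric inclusion set: per-layer dendritic lengths together
#: with the non-redundant cell metrics (the complement of
#: DEFAULT_EXCLUSION_CANDIDATES among the usual metric table columns).
DEFAULT_INCLUDED_METRICS = (
    "soma_surface_area",
    "soma_feret_max",
    "n_primary_dendrites",
    "main_primary_length",
    "main_primary_max_diameter",
    "length_INL", "length_S1", "length_S2", "length_S3", "length_S4",
    "length_S5", "length_GCL",
    "dendritic_surface_area",
    "average_diameter",
    "average_segment_path_length",
    "max_order_shaft",
    "average_partition_asymmetry",
    "n_nodes",
    "hull2d_arboreal_feret_max",
    "hull2d_arboreal_feret_min",
    "hull2d_lobular_feret_max",
    "hull2d_lobular_feret_min",
    "hull3d_volume",
    "euclidean_distance_mean",
    "euclidean_distance_max",
    "contraction",
    "fractal_dimension",
)

#: Metrics with a clear geometrical relation to a retained metric; excluded
#: when they also correlate with one at |r| above the threshold.
DEFAULT_EXCLUSION_CANDIDATES = (
    "soma_volume", "soma_projection_area", "soma_projection_perimeter",
    "soma_feret_min",
    "dendritic_length", "dendritic_volume",
    "max_order_centrifugal",
    "n_endings", "n_segments", "n_varicosities",
    "hull2d_arboreal_area", "hull2d_arboreal_perimeter",
    "hull2d_lobular_area", "hull2d_lobular_perimeter",
    "hull3d_surface_area",
    "capacitance",
)


@dataclass
class MetricMatrix:
    """Cells × metrics table with normalization state and exclusion log."""

    data: pd.DataFrame                     # raw values
    normalized: pd.DataFrame               # z-scored included metrics
    means: pd.Series
    sds: pd.Series
    exclusions: dict[str, str] = field(default_factory=dict)   # metric -> reason

    @property
    def included(self) -> list[str]:
        return list(self.normalized.columns)

    @property
    def n_included(self) -> int:
        return len(self.normalized.columns)


def build_metric_matrix(rows, laminar_lengths: pd.DataFrame | None = None,
                        drop_incomplete: bool = True) -> pd.DataFrame:
    """Assemble the raw cells × metrics table.

    ``rows`` is a list of per-cell metric dicts (or a DataFrame); the
    optional ``laminar_lengths`` table (cells × layer bins) is joined as
    ``length_INL`` ... ``length_GCL``.  Cells with missing values are
    dropped with a warning recorded in ``DataFrame.attrs``.
    """
    df = pd.DataFrame(rows) if not isinstance(rows, pd.DataFrame) else rows.copy()
    if len(df) < 3:
        raise ValueError("population analysis needs >= 3 cells")
    if laminar_lengths is not None:
        lam = laminar_lengths.rename(columns=lambda c: c if str(c).startswith("length_") else f"length_{c}")
        df = pd.concat([df.reset_index(drop=True), lam.reset_index(drop=True)], axis=1)
    df = df.apply(pd.to_numeric, errors="coerce")
    dropped = []
    if drop_incomplete:
        keep = df.notna().all(axis=1)
        dropped = df.index[~keep].tolist()
        df = df[keep]
    df.attrs["dropped_cells"] = dropped
    if len(df) < 3:
        raise ValueError("fewer than 3 complete cells after dropping missing values")
    return df


def normalize_and_exclude(
    df: pd.DataFrame,
    r_threshold: float = 0.80,
    manual_exclusions=None,
    near_constant_cv: float = 1e-3,
) -> MetricMatrix:
    """Normalize metrics and exclude redundant / near-constant ones.

    A metric is excluded as redundant when it is listed as geometrically
    related to another metric (``manual_exclusions``; defaults to the
    shipped candidate list) *and* its |Pearson r| with some retained metric
    exceeds ``r_threshold``.  Metrics whose coefficient of variation falls
    below ``near_constant_cv`` (or with zero spread) are excluded as
    near-constant.  Raises if nothing survives.
    """
    if manual_exclusions is None:
        manual_exclusions = DEFAULT_EXCLUSION_CANDIDATES
    exclusions: dict[str, str] = {}
    cols = list(df.columns)

    sds = df.std(ddof=1)
    means = df.mean()
    for c in cols:
        cv = sds[c] / abs(means[c]) if means[c] != 0 else math.inf
        if sds[c] == 0 or sds[c] < 1e-12 or cv < near_constant_cv:
            exclusions[c] = "near-constant"

    retained = [c for c in cols if c not in exclusions]
    corr = df[retained].corr()
    for c in [c for c in retained if c in set(manual_exclusions)]:
        others = [o for o in retained if o != c and o not in exclusions]
        if others and (corr.loc[c, others].abs() > r_threshold).any():
            exclusions[c] = "redundant"
    included = [c for c in cols if c not in exclusions]
    if not included:
        raise ValueError("all metrics excluded")
    sub = df[included]
    means_i, sds_i = sub.mean(), sub.std(ddof=1)
    normalized = (sub - means_i) / sds_i
    return MetricMatrix(data=df, normalized=normalized, means=means_i, sds=sds_i,
                        exclusions=exclusions)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA of the normalized metric matrix.

    ``components`` holds unit coefficient vectors (metrics × PCs, column
    ``PC1`` first); ``variance_fractions`` are eigenvalue / n_metrics.
    """

    eigenvalues: np.ndarray
    components: pd.DataFrame
    scores: pd.DataFrame
    n_metrics: int
    significant: np.ndarray | None = None
    bootstrap_z: pd.DataFrame | None = None

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.n_metrics


def variance_fraction(eigenvalue: float, n_metrics: int) -> float:
    """Share of total variance carried by one component of a
    correlation-matrix PCA: eigenvalue / number of included metrics."""
    return eigenvalue / n_metrics


def run_pca(matrix: MetricMatrix | pd.DataFrame) -> PCAResult:
    """Eigen-decomposition of the correlation matrix of the normalized data."""
    z = matrix.normalized if isinstance(matrix, MetricMatrix) else matrix
    zv = np.asarray(z, dtype=float)
    n, p = zv.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >= 2 cells and >= 2 metrics")
    corr = zv.T @ zv / (n - 1)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = np.maximum(w[order], 0.0), v[:, order]
    # deterministic sign: largest-magnitude coefficient positive
    for k in range(p):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    pcs = [f"PC{k+1}" for k in range(p)]
    components = pd.DataFrame(v, index=z.columns, columns=pcs)
    scores = pd.DataFrame(zv @ v, index=z.index, columns=pcs)
    return PCAResult(eigenvalues=w, components=components, scores=scores, n_metrics=p)


def broken_stick_thresholds(n_metrics: int) -> np.ndarray:
    """Broken-stick expected eigenvalues b_k = sum_{i=k..p} 1/i."""
    return np.array([sum(1.0 / i for i in range(k, n_metrics + 1)) for k in range(1, n_metrics + 1)])


def significant_components(
    result: PCAResult,
    n_cells: int | None = None,
    method: str = "random_data_mc",
    n_null: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Flag components whose eigenvalue exceeds the chance level.

    ``random_data_mc``: component k is significant when its eigenvalue
    exceeds the (1 − alpha) quantile of the k-th eigenvalue over ``n_null``
    standard-normal datasets of identical shape.  ``broken_stick``: the
    eigenvalue exceeds the broken-stick expectation sum_{i>=k} 1/i.
    """
    p = result.n_metrics
    if method == "broken_stick":
        flags = result.eigenvalues > broken_stick_thresholds(p)
    elif method == "random_data_mc":
        if n_null < 100:
            raise ValueError("Monte-Carlo null needs n_null >= 100")
        if n_cells is None:
            n_cells = len(result.scores)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = np.empty((n_null, p))
        for b in range(n_null):
            x = rng.standard_normal((n_cells, p))
            x = (x - x.mean(0)) / x.std(0, ddof=1)
            w = np.linalg.eigvalsh(x.T @ x / (n_cells - 1))
            null[b] = w[::-1]
        thresholds = np.quantile(null, 1 - alpha, axis=0)
        flags = result.eigenvalues > thresholds
    else:
        raise ValueError(f"unknown significance method {method!r}")
    # components are significant only down to the first failure, matching the
    # sequential reading of eigenvalue null tests
    out = np.zeros(p, dtype=bool)
    for k in range(p):
        if flags[k]:
            out[k] = True
        else:
            break
    result.significant = out
    return out


def bootstrap_coefficients(
    matrix: MetricMatrix,
    result: PCAResult | None = None,
    n_boot: int = 10000,
    n_components: int = 2,
    seed: int | np.random.Generator = 0,
    z_threshold: float = 2.0,
) -> dict:
    """Bootstrap z-scores for each (metric, PC) coefficient.

    Cells are resampled with replacement; each replicate is re-normalized
    and decomposed; replicate component signs are corrected by multiplying
    with the signs of the scalar products with the original components
    (guaranteeing non-negative scalar products), and replicates whose
    leading eigenvalue order swaps are counted (not reordered).  The z-score
    is |original coefficient| / bootstrap SD; z > ``z_threshold`` (default
    2, i.e. p < 0.05 uncorrected) flags a significant coefficient.
    Degenerate replicates (a metric constant within the resample) are
    skipped and counted.
    """
    result = result or run_pca(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = matrix.data[matrix.included].to_numpy(dtype=float)
    n, p = raw.shape
    k = min(n_components, p)
    orig = result.components.to_numpy()[:, :k]
    coefs = np.empty((n_boot, p, k))
    n_skipped = 0
    n_order_swaps = 0
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > 20 * n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        x = raw[idx]
        sd = x.std(0, ddof=1)
        if (sd < 1e-12).any():
            n_skipped += 1
            continue
        z = (x - x.mean(0)) / sd
        w, v = np.linalg.eigh(z.T @ z / (n - 1))
        order = np.argsort(w)[::-1]
        v = v[:, order][:, :k]
        dots = orig.T @ v   # k × k scalar products original · bootstrapped
        if k >= 2 and (abs(dots[0, 1]) > abs(dots[0, 0]) or abs(dots[1, 0]) > abs(dots[1, 1])):
            n_order_swaps += 1
        signs = np.sign(np.diag(dots))
        signs[signs == 0] = 1.0
        coefs[b] = v * signs
        b += 1
    sds = coefs.std(axis=0, ddof=1)
    zscores = np.abs(orig) / np.where(sds > 0, sds, np.inf)
    zdf = pd.DataFrame(zscores, index=matrix.included,
                       columns=[f"PC{i+1}" for i in range(k)])
    result.bootstrap_z = zdf
    return {
        "z": zdf,
        "significant": zdf > z_threshold,
        "n_skipped": n_skipped,
        "n_order_swaps": n_order_swaps,
    }


def regress_excluded(
    matrix: MetricMatrix,
    result: PCAResult,
    n_components: int = 2,
    r2_threshold: float = 0.40,
) -> pd.DataFrame:
    """Simple linear regressions of each excluded metric on each leading
    PC's scores; rows with R² above ``r2_threshold`` are flagged."""
    rows = []
    excluded = [m for m, reason in matrix.exclusions.items()
                if reason == "redundant" and m in matrix.data.columns]
    for m in excluded:
        yv = matrix.data[m].to_numpy(dtype=float)
        for k in range(min(n_components, result.n_metrics)):
            x = result.scores[f"PC{k+1}"].to_numpy()
            fit = stats.linregress(x, yv)
            rows.append(
                {
                    "metric": m,
                    "pc": f"PC{k+1}",
                    "coefficient": fit.slope,
                    "r2": fit.rvalue**2,
                    "flagged": fit.rvalue**2 > r2_threshold,
                }
            )
    return pd.DataFrame(rows, columns=["metric", "pc", "coefficient", "r2", "flagged"])


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    n_clusters: int | None       # None = no separable clusters
    labels: np.ndarray
    best_gap: float
    gap_threshold: float

    def to_newick(self, leaf_names=None) -> str:
        """Serialize the linkage tree to Newick text."""
        n = self.linkage.shape[0] + 1
        names = list(map(str, leaf_names)) if leaf_names is not None else [f"c{i}" for i in range(n)]

        def build(i: int) -> tuple[str, float]:
            if i < n:
                return names[i], 0.0
            a, bb, h, _ = self.linkage[i - n]
            sa, ha = build(int(a))
            sb, hb = build(int(bb))
            return f"({sa}:{max(h - ha, 0.0):.6g},{sb}:{max(h - hb, 0.0):.6g})", h

        s, _ = build(2 * n - 2)
        return s + ";"


def ward_clustering(
    matrix: MetricMatrix | pd.DataFrame,
    gap_threshold: float = 2.0,
    max_clusters: int = 10,
) -> ClusterResult:
    """Ward linkage on the normalized data with a separability assessment.

    Separability criterion: the largest relative gap between consecutive
    top merge heights.  Cutting below a merge whose height exceeds the next
    lower height by at least ``gap_threshold``-fold yields that many
    clusters; otherwise no separable clusters are reported (all cells in
    one cluster).
    """
    z = matrix.normalized if isinstance(matrix, MetricMatrix) else matrix
    zv = np.asarray(z, dtype=float)
    n = len(zv)
    if n < 3:
        raise ValueError("clustering needs >= 3 cells")
    link = hierarchy.linkage(zv, method="ward")
    heights = link[:, 2]
    best_gap, best_k = 0.0, None
    for k in range(2, min(max_clusters, n - 1) + 1):
        hi = heights[n - k]        # height of the merge that closes k-1 clusters
        lo = heights[n - k - 1]
        gap = hi / lo if lo > 0 else math.inf
        if gap > best_gap:
            best_gap, best_k = gap, k
    if best_k is not None and best_gap >= gap_threshold:
        labels = hierarchy.fcluster(link, t=best_k, criterion="maxclust")
        n_clusters = best_k
    else:
        labels = np.ones(n, dtype=int)
        n_clusters = None
    return ClusterResult(linkage=link, n_clusters=n_clusters, labels=labels,
                         best_gap=float(best_gap), gap_threshold=gap_threshold)


# ---------------------------------------------------------------------------
# Random-branching angle baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleBaseline:
    """Pair-angle and min-of-two tilt statistics for directions distributed
    uniformly over the sphere (degrees)."""

    pair_angle_mean: float
    pair_angle_sd: float
    tilt_mean: float
    tilt_sd: float
    mode: str
    n_samples: int | None = None
    seed: int | None = None


def _analytic_baseline() -> AngleBaseline:
    # angle between two uniform directions: density sin(θ)/2 on [0, π]
    pair_mean = math.pi / 2
    pair_sd = math.sqrt(math.pi**2 / 4 - 2)
    # min of two independent such angles (survival ((1+cos t)/2)^2)
    tilt_mean = 3 * math.pi / 8
    tilt_sd = math.sqrt(3 * math.pi**2 / 8 - 2 - tilt_mean**2)
    return AngleBaseline(
        pair_angle_mean=math.degrees(pair_mean),
        pair_angle_sd=math.degrees(pair_sd),
        tilt_mean=math.degrees(tilt_mean),
        tilt_sd=math.degrees(tilt_sd),
        mode="analytic",
    )


def random_branching_baselines(
    mode: str = "analytic",
    n_samples: int = 10**6,
    seed: int = 0,
) -> AngleBaseline:
    """Expected bifurcation angle and tilt under uniform random branching.

    The pair angle (between two directions drawn uniformly on the sphere)
    has mean 90° and SD ≈ 39°; the min-of-two tilt (the more backward of two
    such directions measured from a fixed axis) has mean 67.5° and
    SD ≈ 32°.
    """
    if mode == "analytic":
        return _analytic_baseline()
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if n_samples < 10**3:
        raise ValueError("Monte-Carlo baseline needs n_samples >= 1000")
    rng = np.random.default_rng(seed)
    # uniform directions via uniform cos(θ)
    cos1 = rng.uniform(-1, 1, size=n_samples)
    cos2 = rng.uniform(-1, 1, size=n_samples)
    phi = rng.uniform(0, 2 * math.pi, size=n_samples)
    # pair angle: fix one direction along +z by symmetry, rotate the other
    pair = np.degrees(np.arccos(cos1))
    # tilt: both daughters measured from the fixed backward axis
    t1 = np.degrees(np.arccos(cos1))
    t2 = np.degrees(np.arccos(cos2))
    del phi
    tilt = np.minimum(t1, t2)
    return AngleBaseline(
        pair_angle_mean=float(pair.mean()),
        pair_angle_sd=float(pair.std()),
        tilt_mean=float(tilt.mean()),
        tilt_sd=float(tilt.std()),
        mode="monte_carlo",
        n_samples=n_samples,
        seed=seed,
    )
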