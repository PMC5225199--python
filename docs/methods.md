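# Methods

This note records the models, conventions and numerical choices behind
arbormetry, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinate frame and data model

`X` is the lateral slice axis, `Y` is retinal depth increasing from the
inner nuclear layer (INL) toward the ganglion cell layer (GCL), and `Z` is
the optical axis.  The "XZ plane" is therefore parallel to the retinal
surface, and all dendritic-field projections are onto XZ.  Soma contours
are closed polygons traced at focal planes (constant Z) with vertices in
XY; the soma projection used for area/perimeter/Feret is the union of the
contour polygons in XY.  All coordinates and radii are µm.

Reconstructions are SWC trees (id, type, x, y, z, radius, parent).  Type
codes: 1 = soma anchor, 2 = apical, 3 = lobular, 4 = arboreal,
0 = unspecified.  The JSON sidecar carries the layer boundaries
(`y_inl_ipl`, `y_ipl_gcl`) and the soma contour stack.  A tree is
considered attached to the soma when its root lies within 2 µm of a soma
contour (configurable).

A tree root is never counted as a branch node: a root with several
children simply starts that many stems.  With this convention
`n_segments = n_nodes + n_endings` holds for every cell, and for a single
purely bifurcating tree `n_endings = n_nodes + 1`.

## Layer model

The IPL between the two boundary depths is divided into five equally thick
strata S1–S5; S1–S2 form sublamina *a*, S3–S5 sublamina *b*.  A point
exactly on a boundary is assigned to the bin on the INL side (so the
S1/S2 boundary bins S1, and the INL/IPL boundary itself bins INL); this is
an arbitrary but deterministic tie-break.  Edges crossing a boundary are
clipped by linear interpolation of position (and radius, where surface or
volume is being split).

## Alignment

`align_major_axis` rotates the point cloud so its principal axis (largest
eigenvector of the coordinate covariance) is parallel to the depth axis,
using a rotation about Z (XY plane) followed by a rotation about X (YZ
plane), about the soma centroid.  The contour stack is left unrotated: a
YZ-plane rotation would destroy the constant-Z planarity of focal-plane
contours, and because the rotation fixes the soma centroid, all
soma-relative distances are unchanged.  Collinear clouds have no stable
major axis and are rejected.

## Branch metrics

* **Segment geometry.**  Each edge is a conical frustum: lateral surface
  π(r₀+r₁)·slant with slant = √(L² + (r₁−r₀)²), volume πL/3·(r₀²+r₀r₁+r₁²).
  Zero-length edges are skipped.  Contraction is the Euclidean chord over
  the path length of a segment, in (0, 1].
* **Ordering.**  Centrifugal: stems are order 1 and each branch point
  increments both daughters.  Central shaft: the continuing daughter keeps
  the parent's order.  The continuing daughter is the one with the larger
  radius at its first own point; ties fall back to the smaller deviation
  angle from the parent direction, then to the larger subtree length.
  Trifurcations are one node: all daughters increment under centrifugal
  ordering, exactly one continues under shaft ordering.
* **Partition asymmetry.**  Per bifurcation |n₁−n₂|/(n₁+n₂−2) over the
  daughter subtrees' tip counts, defined as 0 when both daughters are
  single terminal branches ("tip bifurcation"); a "stub bifurcation" (one
  terminal daughter, the other subtree branching further) evaluates to 1.
  Multifurcations contribute the mean over daughter pairs.  The cell value
  is the unweighted mean over bifurcations.
* **Angles.**  The remote bifurcation amplitude is the angle between the
  chords from the branch point to each daughter segment's end.  The remote
  tilt measures each daughter chord against the backward direction of the
  parent's last edge — 0° means doubling back, 180° continuing straight —
  and reports the smaller (most backward) daughter per bifurcation.
  Per-cell SDs are population SDs over that cell's bifurcations.  Under
  directions drawn uniformly on the sphere the pair angle has mean π/2 and
  SD √(π²/4 − 2) (90.0°, 39.2°), and the min-of-two tilt has mean 3π/8 and
  SD √(3π²/8 − 2 − (3π/8)²) (67.5°, 32.0°); both closed forms follow from
  the sin θ/2 density of the angle to a fixed axis, and the Monte-Carlo
  mode reproduces them as 1/√n.
* **Fractal dimension.**  Per branch, the log–log relation between
  cumulative path length and Euclidean distance from the branch start.
  The regression is of log distance on log path length (the monotone,
  noise-free variable) and the slope is inverted, so a straight branch
  gives exactly 1 and a random walk 2 without attenuation bias.  Branches
  with fewer than three points are skipped; the cell value is the
  unweighted mean over branches.  Contraction and fractal dimension are
  unweighted (not length-weighted) means.
* **Helicity.**  For three consecutive edge vectors,
  (v₁×v₂)·v₃/(|v₁||v₂||v₃|), averaged over all windows; the sign encodes
  handedness and planar paths give 0.
* **Soma.**  Volume is the trapezoid integral of contour areas along the
  stack; the lateral surface treats consecutive contours as frusta of
  their perimeters (slant from spacing and equivalent-radius change) plus
  the two end-cap areas.  This is a stated approximation to the (unpublished)
  commercial tracing software's algorithm; on a sphere sampled by 50
  contours it is accurate to well under 2 %.
* **Diameter correction.**  The mean diameter of the 10 thinnest points on
  10 unique segments is shifted to 0.23 µm — the electron-microscopic
  calibre of the finest processes of this cell type, below the light
  microscope's resolution limit — by adding one constant to every process
  diameter.  The postcondition holds exactly and the operation is
  idempotent; soma contours are untouched.  Note that an additive diameter
  shift is *not* neutral for the varicosity criterion (a ratio), so
  detection should be run at a consistent stage; the package applies it to
  whatever morphology it is given.
* **Capacitance.**  Total surface (soma + dendrites) × 0.01 pF/µm².

## Varicosity detection

A varicosity is a local diameter maximum along a root-to-tip path whose
peak is at least `ratio` (default 1.8, i.e. a ≥ 80 % increase) times the
flank reference on both sides.  The flank reference on each side is the
minimum diameter reached while the profile keeps decreasing away from the
peak, capped at a 5 µm path window — a bounded reading of "immediately
before and after".  Terminal swellings waive the distal flank.  One
varicosity is reported per contiguous swelling, located at the point of
maximal diameter; swellings at branch points belong to the parent segment.
Detection is scale invariant, and comparisons use a 1e−9 relative epsilon
so profiles at exactly the threshold ratio are accepted.  The detector
works on reconstructed radius profiles (which were measured in the imaging
plane), not on image-space circles.

## Spatial profiles

Sholl spheres are nested at a fixed step (default 1 µm) around the
volume-weighted soma centroid.  Intersections count every geometric
crossing (an edge may cross one sphere twice; a tangency counts zero; a
vertex exactly on a sphere counts once).  Shell quantities clip edges at
sphere radii and are exactly conserved; point-like quantities bin a point
exactly on a sphere into the inner shell.  The 2D field hulls use every
reconstruction point of the field projected onto XZ; Feret minimum is
computed exactly by rotating calipers over hull edges.  The field split
plane is chosen by the analyst (the published workflow sets it by eye); an
automatic default takes the waist of the depth-density profile.  Surface
shares assign the soma to the side containing its centroid.  The
density–territory fit is an ordinary least-squares line through
(log₁₀ hull volume, log₁₀ length/volume); the reference line with slope
−0.55 and intercept 0.45 from the broad multi-type neuron survey is
available for comparison.

## Population analysis

Metrics are centred and scaled to unit SD, so the PCA is of the
correlation matrix: eigenvalues sum to the number of included metrics and
a component's variance fraction is its eigenvalue over that number.
Redundancy exclusion needs both |Pearson r| > 0.80 *with a retained
metric* and membership in a declared list of geometrically related metrics
(shipped default mirrors the usual 27-metric inclusion set: per-layer
lengths plus the non-derivable cell metrics); near-constant metrics
(coefficient of variation < 1e−3) are dropped automatically.  Component
significance uses, by default, the Monte-Carlo random-data null — the
(1−α) quantile of the k-th eigenvalue over standard-normal datasets of the
same shape, α = 0.05, read sequentially from the first component — with
the classical broken-stick thresholds Σ_{i≥k} 1/i as the named
alternative.  Bootstrap z-scores resample cells with replacement,
re-normalize and re-decompose each replicate, correct component signs by
the scalar products with the original components (guaranteeing
non-negative products), count rather than silently reorder
eigenvalue-order swaps, and define z = |coefficient| / bootstrap SD with
z > 2 flagged (uncorrected for multiple comparisons, by design).  Ward
clustering runs on the normalized matrix; separability is the largest
relative gap between consecutive top merge heights, with a default
threshold of 2 — below it the module reports "no separable clusters"
rather than forcing a partition.

## The synthetic generator

The generator produces the study conditions, not a biophysical growth
model.  A spheroidal soma sits at the origin with the IPL spanning depths
2–52 µm.  The apical shaft descends through sublamina *a* in ~3.2 µm
segments, emitting one or more lobular caterpillars per apical node that
drift toward mid-S2, spread laterally, and end in large terminal
appendages.  At 22–26 µm depth the shaft splits into arboreal daughters
that sink through S3 with sparse branching, then branch densely
(bifurcation probability 0.78, about half the side daughters short stubs)
while spreading tangentially through S4–S5 inside a confining field
radius.  Segment meander is a per-segment constant-curvature arc plus
small white jitter — this keeps contraction realistic (~0.92) without
inflating the fractal dimension the way white noise would.  Diameters
taper asymptotically toward a floor, the thick daughter remains strictly
thicker than the side daughter at every node, and the first point of every
segment carries its exact start diameter, so the ground-truth branch
orders under both schemes are reproduced exactly by the analysis code.

Defaults reproduce the published population ranges for AII amacrine cells:
500–1630 µm total length, 46–311 nodes, 1–9 stems, mean segment path
length ≈ 3.2 µm, arboreal field areas of several hundred µm², a bimodal
laminar profile peaking in S2 and S4–S5 with more spill-over into the GCL
than the INL, and ~0.12 varicosities/µm with lognormal diameters clipped
to 0.39–2.7 µm and boosted ×1.35 in S1–S2 (lobular appendages).
Varicosities are planted by scaling a single point's radius to at least
2.1× its path neighbours — comfortably clear of the 1.8 detection
threshold — with at least one plain point between insertions, so
noise-free detection recovers them with precision = recall = 1.  Because
insertion must clear that ratio over the local baseline, the smallest
planted diameters sit near 0.6 µm rather than the 0.39 µm lower bound of
the published range; all planted diameters stay inside the range.

For population studies the per-cell size scale spreads territory volumes
several-fold.  With `plant_scaling=(slope, intercept, noise_sd)` the
total dendritic length of each cell is planted on the log–log
density–volume line using the measured convex-hull volume of the grown
cell, topping up length with short interior twigs (re-measuring the hull
once, since densification inflates it slightly).  A planted slope of
−0.37 over a ~10× volume range is recovered by the fit within ±0.05.

What passing tests on synthetic cells do *not* show: robustness to tracing
errors (spurious or missing nodes, diameter noise beyond ±1.5 %, z-axis
smearing), tissue distortion, real lobular appendage shapes (planted
swellings are single-point peaks; real appendages are extended and
irregular), or realistic inter-metric correlation structure beyond what
the growth model induces.  The varicosity detector's perfect recovery is a
property of noise-free insertions, not a claim about real reconstructions,
where the flank-window choice and diameter noise will matter.

## Numerical choices and problem sizes

Random draws all come from one seeded `numpy` generator threaded through
every step; identical seeds give byte-identical SWC output.  Hull
computations use Qhull via scipy; degenerate (collinear/coplanar) inputs
raise rather than return approximations.  Test-suite problem sizes — 50
cells for the segment-length band, 40 cells for the scaling fit, 20 seeds
× 1000 null datasets for the PCA recovery check, 10⁶ samples for the
Monte-Carlo angle baselines, 200 random walks of 10⁴ steps for the
fractal-dimension oracle — were chosen so each check has comfortable
statistical margin while the whole suite runs in well under a minute.

## Known limitations

* The soma surface formula is a frusta-of-perimeters approximation; highly
  non-convex contours will be less accurate than the sphere benchmark.
* "Length of the main primary dendrite" is read as the path length of the
  thickest stem up to its first bifurcation; the alternative reading (up
  to the entry into sublamina *b*) is not implemented.
* The flank window of the varicosity detector ("immediately before and
  after") has no published spatial extent; 5 µm is a declared choice and
  is exposed as a parameter.
* The Monte-Carlo eigenvalue null's α is configurable because no published
  value exists; 0.05 is the default.
* Helicity is evaluated within segments; windows spanning branch points
  are not formed.
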