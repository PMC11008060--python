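# Methods

This note records the models, conventions and numerical choices behind
`mandair`, and what the phantom-based validation does and does not show.

## Measurement model

The pipeline assumes: (i) the cranium above the surgical site is rigid and
unchanged between scans, so pre/post scans can be superimposed on it; (ii)
each condyle is rigid (its shape is unchanged; only its pose changes); (iii)
the symphysis may change shape entirely (native bone replaced by fibula), so
its position is compared only through the centre point of its midsagittal
section; (iv) the airway lumen is a closed surface whose segment boundaries
are defined by four reference planes given in the skull frame.

### Superimposition (masked ICP)

Point-to-point ICP with exact closest-point-on-triangle correspondences
(KD-tree over face centroids proposes candidates; the exact projection picks
the winner). The moving surface is sampled uniformly by area with a fixed
seed, so registration is deterministic. The mask (box or sphere in scan
coordinates) restricts both meshes to the surgically unchanged cranium —
which subregion to use is deliberately configuration, not code: the right
choice depends on the resection.

Convergence: relative RMS change < 1e-10, absolute RMS < 1e-10 mm, or 1000
iterations. Point-to-point ICP converges linearly (contraction factor
≈ 0.95 per iteration on the blob-like phantom regions), so several hundred
cheap iterations are needed to reach the 0.01 mm / 0.01° regime on
noise-free data; with vertex noise the RMS plateaus at the noise scale and
the relative-change criterion stops early. Divergence (RMS > 1.5× its
running minimum for 10 iterations) raises an error carrying the RMS trace.

### Skull frame

Built from five named landmarks: `origin`, `anterior` (fixing +X), and an
axial triple whose plane normal — oriented by the triple's ordering
convention — is +Z (cranial). Y = Z × X is left-lateral; the frame is
orthonormal and right-handed by construction and asserted on every build.
Landmark configs replace the interactive orientation step of CAD workflows
and make the pipeline reproducible.

### Condyle metrics

The rigid fit maps the pre-operative condylar crop onto the post-operative
one. Translations are reported as the displacement of the **area-weighted
surface centroid of the pre-operative crop** — a canonical, tessellation-
robust reference point. Euler angles use the intrinsic X–Y–Z convention
(R = Rx(φ)·Ry(θ)·Rz(ψ)), fixed and regression-tested against
`scipy.spatial.transform`; any fixed convention serves, since the three
rotations are reported jointly. At gimbal lock (|θ| within 1e-6° of 90°)
φ is set to 0, the coupled angle is folded into ψ, and the output is
flagged. Axis deviations are signed; plane (dXY, dXZ, dYZ) and Euclidean
(dXYZ) deviations are magnitudes. A residual fit RMS above a configurable
threshold (default 0.5 mm) warns that the rigid-shape assumption is suspect
(e.g. condylar remodelling).

### Symphysis metric

Both symphysis crops are intersected with the midsagittal plane; the
**area centroid of the enclosed region** (even-odd hole semantics, not the
vertex mean) is the centre point S. S_dX and S_dZ are the signed post − pre
differences on the frame axes; anterior and cranial are positive, so a
setback is a negative S_dX.

### Airway metrics

Segments are clipped between consecutive planes with the cut sections
capped, so signed-tetrahedron volumes are valid; segment volumes partition
the clipped whole to 1e-6 relative. CSA profiles sample planes **parallel
to the E-plane** at fixed spacing (default 1 mm, positive cranial):
the oropharynx at offsets strictly between the E-plane and the naso/oro
plane, the hypopharynx at offset 0 and caudally, strictly above the bottom
plane (half-open at the far planes, so boundary planes are never counted
twice). Offset 0 is book-kept with the hypopharynx but also competes for
the oropharyngeal minimum; both minima are reported with their offsets so
the convention is auditable. Loop areas use the shoelace formula in plane
coordinates; nested loops alternate sign (a lumen with an island must not
overcount); "largest" mode is available where a single dominant lumen is
wanted. An empty section at an interior offset records area 0 with a
collapsed-lumen warning rather than failing the patient.

### Statistics

ICC(A,1) — single-rating, absolute-agreement, two-way mixed — from the
two-way mean squares, with the McGraw–Wong F-based 95% interval
(Satterthwaite degrees of freedom). Zero between-subject variance is
flagged as degenerate. One-tailed Spearman tests use average ranks for
ties; the p-value is the exact permutation probability over all n!
orderings for n ≤ 9 (the permutation statistic Σ rx·ry is an affine image
of rho, so sums are compared) and the t-approximation above. Quantiles use
linear interpolation. Shapiro–Wilk / Kruskal–Wallis / Mann–Whitney screens
are thin wrappers over scipy, surfaced only in cohort reports. No
multiple-testing correction is applied by default; Benjamini–Hochberg is
available as an explicit switch.

## Geometric core

* STL is float32 on disk; all computation is float64. At load, vertices
  within 1e-6 mm are merged and duplicate/degenerate (< 1e-12 mm²) faces
  dropped, with counts logged. Truncated binary STL reports the offending
  byte offset.
* Section loops are chained from triangle/plane crossing segments with a
  1e-6 mm endpoint-matching tolerance (well below CT voxel scale); open
  chains (cutting a non-watertight surface) are an error for volume paths.
* Slab clipping slices with each plane and closes the cut with a
  centroid-fan cap. The fan is topologically closed and — because fan
  triangle areas are signed — volume-exact for planar cuts even when the
  section polygon is non-convex.
* Volume computations demand watertight input and report the count of
  boundary edges otherwise; pure sectioning tolerates open meshes.

## Phantoms: what they emulate, what they do not

Phantom shapes are schematic, not anatomical: a spherical cranium (the
registration anchor, identical at both time points), condylar blobs
(ellipsoids with a mild asymmetric taper so their pose is uniquely
recoverable — a plain ellipsoid has 180° self-symmetries), a symphyseal
arch (capped partial torus whose midsagittal section is an exact circle
with an analytically known centroid), and airway tubes of revolution with
baseline radius 6 mm and an optional Gaussian waist. Parts are spaced so
every region crop keeps ≥ 20 mm of translation headroom; mesh resolution
defaults to 128 circumferential segments, which puts inscribed-polygon area
error (~0.025%) far below the 0.5–1% test tolerances. Tube rings sit at
half-multiples of the ring spacing so profile planes never pass exactly
through vertex rings. Optional Gaussian vertex noise emulates bone
segmentation jitter; the lumen stays exact because the airway truth is its
radius profile.

Passing these tests demonstrates that the measurement chain is correct and
stable — not that it is robust to real segmentation artifacts, soft-tissue
change, patient positioning, or anatomical ambiguity in region cropping.
Those require real data.

## Cohort simulation

A study-scale cohort (default n = 35) draws the sagittal symphysis shift
s_dX ~ N(−7, 4²) mm (predominantly posterior, with s_dZ ~ N(0, 2²)), small
residual condylar pose changes (rotations N(0, 3°), translations
N(0, 1.5 mm) per axis), and a hypopharyngeal minCSA percentage change that
is log-normal with median ≈ 90% (log-scale 0.2). The shift and the latent
driving the post-operative waist radius are jointly Gaussian with Pearson
correlation ρ_p = 2 sin(π·ρ_s/6), the exact inverse of the bivariate-normal
rank correlation, so the population Spearman correlation equals the
requested coupling; the monotone link (post waist radius =
pre × √(pct/100)) preserves ranks through the measurement. Independent
nuisance noise attenuates the correlation by 1/√(1+σ²); the generator
compensates exactly and raises, quoting the attainable bound, when the
target is unreachable.

Power and type-I studies measure each subject through the real sectioning
operations (midsagittal centroid; hypopharyngeal CSA profile) at reduced
resolution — 64 circumferential segments, hypopharynx-only profiling, and
the shared pre-operative template measured once per cohort — sizes chosen
to keep a 150-cohort study in the minutes range while the discretisation
error (≈ 0.3% of area, rank-preserving) stays negligible against the
between-subject spread. Full-resolution, full-chain recovery is validated
separately on single phantoms.

## Known limitations

* The reference planes are placeholders: planes orthogonal to frame Z
  through configured offsets. Anatomically derived plane definitions
  (landmarks, tilts) must be supplied by configuration.
* Point-to-point ICP has no trimming or robust kernel; outlier-contaminated
  or partially overlapping masks are not handled.
* Crop regions are axis-aligned boxes or spheres in frame coordinates;
  there is no automatic condyle/symphysis detection.
* The volume QC compares whole-mesh volumes by default; choosing stable
  subregions (and the tolerance) is left to configuration.
* Cross-sections are plane-parallel to the E-plane, not orthogonal to an
  airway centreline; minCSA is therefore a plane-convention quantity.
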