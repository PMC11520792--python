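# Methods

This package reproduces, on synthetic data, the accuracy-assessment
computation used to qualify CBCT-derived tooth replicas for surgical
planning: a CBCT volume of a donor tooth is segmented into a surface
model, a replica is fabricated from that model, and both are compared to
an optical surface scan of the natural tooth by surface-based rigid
registration followed by per-vertex deviation mapping. All coordinates
and distances are millimetres; volumes carry Hounsfield-like units (HU).

## Synthetic tooth phantoms

No reference teeth are distributed with studies of this kind, so every
stage runs against parametric phantoms with exact ground truth. A tooth
is the smooth union (polynomial smooth-min, blend width 0.8 mm) of a
superellipsoid crown (exponent 2.5) and one or two sphere-swept tapered
cones for roots. Three fixed archetypes are provided: a premolar and a
canine with a single tilted root, and a molar with two diverging, unequal
roots forming a furcation saddle. Crowns carry low-order angular lobes
(two cusps on the premolar, a dominant labial ridge on the canine, four
cusps on the molar) and root cross-sections are mesiodistally compressed
(factor 0.78). These features are anatomically motivated, and they also
make rigid registration well-posed: a smooth crown on a round root is
nearly a surface of revolution, which no real tooth is, and registration
about that axis would otherwise be ill-conditioned.

The implicit field is polygonized by marching cubes at a configurable
pitch (default 0.15 mm, finer than the CBCT voxel; studies in this
repository use 0.2 mm, which keeps the ground-truth chordal error near
5 µm while halving runtimes). The result is a closed, outward-oriented,
genus-0 mesh. Geometry is a pure function of the tooth kind; the seed
feeds only the stochastic stages below, so identical inputs regenerate
bit-identical outputs.

### Voxelization

Solid voxelization classifies voxel centers by z-column crossing parity,
vectorized over triangles; a fixed sub-micrometre generic-position offset
of the mesh removes edge-grazing ties. Interior voxels receive the
hard-tissue HU, cylindrical channels along the root axes (ending 1.5 mm
short of the apex, hence enclosed) receive the canal HU, and the
remainder the background HU. Defaults: hard tissue 2000 HU, canal
300 HU, background 0 HU — chosen to straddle the 1600 HU segmentation
threshold with dentin-like contrast. The scanner is emulated by a
Gaussian point-spread blur (default σ 0.1 mm ≈ half a voxel) and additive
Gaussian HU noise (default 30 HU), both stated assumptions: the source
protocol (90 kV, 6.3 mA, 200 µm voxels) reports no noise
characterization. With this contrast the blurred edge crosses 1600 HU at
+0.84 σ inside the true surface, so the segmented model is systematically
a few hundredths of a millimetre *smaller* than the natural tooth — the
same sign structure the physical pipeline exhibits.

### Deformities and fabrication noise

Localized deviations are injected with a cosine-tapered radial bump:
vertices within radius R of a site move along their outward normals by
a·(1+cos(πd/R))/2, so the center moves exactly a and the support boundary
not at all; negative a gives a dent. Named sites (root tip, furcation
saddle, a buccal crown patch) are located on the ground-truth surface
from the phantom parameters.

Two geometric limits matter when choosing scenarios. A dent deeper than
the local feature thickness is not realizable by normal displacement
(opposing walls of a thin root tip would cross), and the closest-point
metric *saturates* on deformities that are deep relative to their
support — in a concave furcation an outward bump simply approaches the
opposing root flank, and even a wide dent cannot separate farther than
min_r √(r² + a²w(r)²). The shipped deviation-recovery scenario therefore
places the band-checked amplitudes (0.5, 1.0, 1.9 mm) as outward bumps at
root tips (the 1.9 mm one with a 3.5 mm support so the extension stays
blunt) and represents the furcation failure as a −0.8 mm dent, checked
through the normal metric — which is also how the physical studies
characterize furcation error.

Replica fabrication is emulated by i.i.d. Gaussian vertex displacement
along normals (default sd 0.05 mm) followed by one mild Laplacian
smoothing pass (λ = 0.5), since a milling tool cannot realize per-vertex
jitter; the optical scan of the natural tooth gets the same displacement
model at sd 0.01 mm without smoothing. Both defaults are assumptions
exposed in the configuration.

## Segmentation

The reconstruction chain is: strict threshold (value > 1600 HU;
exact-boundary voxels are background), cavity filling, largest
26-connected component, marching cubes at iso 0.5 in physical
coordinates. Cavity filling is a boundary flood fill (6-connected
background, the standard complement of 26-connected foreground) followed
by a ball closing (radius 3 voxels) and a second flood fill, so both
enclosed canals and canals opening at the apex are sealed; the operation
is extensive. The root-canal-filling algorithm of the reference pipeline
is unspecified, so this minimal morphological variant is a documented
stand-in.

Marching cubes on a raw {0,1} field produces a staircased surface whose
area is biased high by ≈ 8% even though its volume and position are
accurate. The mask is therefore mollified with a 0.8-voxel Gaussian
before polygonization (iso level unchanged at 0.5). For a flat interface
this is unbiased; measured on a 5 mm sphere at 0.2 mm voxels it leaves
area within 0.2% and volume within 1% of the analytic values, and
phantom reconstructions deviate at most ≈ 0.11 mm from ground truth
(voxel diagonal 0.346 mm). Features only a few voxels across could be
mollified below the iso level entirely; in that case the raw binary
field is used for that volume. No mesh-level smoothing is applied by
default.

## Rigid registration

`best_rigid` is the weighted Kabsch solution (SVD of the cross-covariance
with determinant correction), always returning a proper rotation;
rank-deficient configurations raise. ICP iterates exact
closest-point-on-surface correspondence (point-to-triangle via the
package's certified k-d-tree broadphase), optional cutoff/fraction
trimming, and the closed-form fit, solving each iteration for the
absolute transform from the original source positions. Only
face-referenced vertices participate (partial meshes may share a larger
vertex array).

Initialization matches centroids and principal axes; the four proper
axis-sign assignments plus the identity and a centroid-only shift are
scored by sampled closest-point RMS. Because a near-symmetric shape can
score a flipped frame *better* than the true-but-misaligned pose, the top
three candidates are each refined for up to eight ICP iterations and the
best continues to convergence (multi-start). Convergence is an absolute
change of the correspondence RMS below 1e-6 mm (robust near zero RMS);
ICP's linear convergence along weakly-constrained directions is
accelerated by geometric-sequence extrapolation of the transform
parameters (rotation vector + translation), accepted only when it does
not raise the RMS — so the recorded RMS history remains monotonically
non-increasing whenever trimming is off. With trimming, the stopping rule
watches the kept-correspondence RMS and monotonicity is not guaranteed.
With subsampling (uniform random, seeded), a final full-vertex
correspondence/solve polish runs after convergence.

Merging two partial scans is a different problem: fixed-fraction trimming
provably "swallows" — vertices beyond the overlap band find closest
points near the cut rim and drag the fit along the surface (13–14°
divergence measured on a split phantom root). `merge_half_scans` instead
assumes the halves arrive roughly pre-aligned (within `overlap_margin`,
default 1 mm), rejects correspondences whose closest point lies within
that margin of the fixed half's rim (the zippering rule) or farther than
the margin from the source point, and applies the same extrapolation
accelerator; afterwards triangle sets are concatenated and vertices
welded at 1e-6 mm. Registrations whose post-fit overlap covers < 10% of
vertices are rejected — a genuine overlap band is an area, while disjoint
cuts snapped together touch only along a curve.

## Deviation metrics

Both metrics are computed per vertex of a chosen basis mesh after
registration:

* **Euclidean** — exact unsigned distance to the closest point anywhere
  on the other surface. The broadphase escalates k-nearest-vertex
  candidates until the certification r_k ≥ d_cand + max triangle
  diameter holds, so results equal the brute-force all-triangles minimum
  to floating-point precision.
* **Normal** — a bidirectional ray cast along the vertex's outward
  area-weighted normal; the nearest intersection within `max_range`
  (default 5 mm) wins, its sign taken from the ray direction. Vertices
  with no hit are flagged missing and excluded from summaries (the basis
  must be closed and outward-oriented). In every report the sign is
  arranged so *positive means the natural tooth is locally larger* than
  the compared model; when the basis is the natural scan the raw outward
  sign is therefore inverted.

The Euclidean value lower-bounds |normal| wherever a hit exists. The
basis is the reconstruction model for CBCT comparisons and the natural
scan for replica comparisons, matching the visualization conventions of
the reference workflow. One caveat of the bidirectional nearest-hit rule:
for a basis vertex lying *inside* a thin protrusion of the other surface,
both walls are close and the per-vertex sign can flip; on the natural
basis this ambiguity does not arise, which is where the test suite reads
sign conventions.

Summaries report min/max/mean/median over valid values (midpoint median
for even counts) plus absolute-value variants for signed fields, with
missing counts. Reports print three significant figures; deviation maps
use a linear dark-blue (#00008B) to bright-yellow (#FFFF00) ramp with
missing vertices in neutral gray, written as ASCII PLY with per-vertex
RGB and optionally rendered to PNG (display-only face decimation).

## Study driver and determinism

`run_study` executes, per tooth kind: phantom → natural scan (scanner
noise + configured deformities) and phantom → voxelize → segment → CBCT
model → simulated replica; then both comparisons, all artifacts
(volumes, STLs, transforms, per-vertex CSV fields, stats JSON, colored
PLYs, report CSV) under one output directory. Per-stage seeds derive from
the single study seed via `SeedSequence`, a failing tooth does not abort
the others, and report CSVs contain no timestamps, so identical
configurations reproduce byte-identical reports.

Problem sizes used by the shipped tests and the acceptance script:
ground-truth pitch 0.2 mm for end-to-end studies (≈ 15–30 k vertices per
mesh), 0.3–0.45 mm for unit tests, ICP subsampling at 800–2000 points —
sizes at which every stage's error is far from the tolerances being
asserted.

## Known limitations

* No X-ray physics: blur + noise stand in for partial volume and
  detector noise; no beam hardening, scatter, or adjacent-bone contact.
  Passing tests show the *computational* chain recovers known geometry;
  they cannot validate scanner- or material-specific error sources.
* The phantom archetypes are parametric idealizations, not anatomical
  atlases; absolute deviation magnitudes on real teeth depend on anatomy
  the generator does not model (enamel/dentin contrast, curved canals,
  fillings).
* Point-to-point ICP only (point-to-plane is not implemented); merging
  assumes roughly pre-aligned halves.
* The normal metric's bidirectional nearest-hit rule is ambiguous inside
  thin protrusions of the compared surface (see above).
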