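# Methods

This note documents the models, estimators and numerical choices behind
the package, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Synthetic vascular phantoms

The generator (`vesselquant.phantom`) builds an ellipsoidal "lung"
(default semi-axes 60 × 50 × 40 mm, ≈0.5 L — a deliberately reduced
lung so a full subject runs in well under a minute) filled with
recursive binary vessel trees.  Each segment is a straight chord plus a
single half-period sinusoidal transverse perturbation; for relative
amplitude `a` the distance metric is

    DM(a) = ∫₀¹ √(1 + (aπ cos πt)²) dt,

independent of chord length, and is inverted by 1-D root finding so
per-segment DM targets are hit exactly in the ground truth.  Per-segment
targets are drawn from a shifted lognormal, `DM = 1 + m·exp(σZ)`, whose
median (default 1.029) and 15th–85th percentile width (default 0.058)
are the controls; `σ = asinh(w / 2m) / z₀.₈₅` in closed form.  Circular
arcs (half circle: DM = π/2; quarter circle: DM = (π/4)√2) provide
independent closed-form controls.

Tree growth is breadth-first inside the ellipsoid with per-branch
directions in a cone (half-angle 40°) around the parent, lengths and
radii decaying per generation, and collision clearance between the tube
envelopes of *different* trees (same-tree proximity near a shared
branch point is allowed).  Defaults target the cohort-scale study
conditions: 13 trees × 14 segments ≈ 362 segments/L, and a single
global radius-scale calibration sets total tube volume to 3.6% of the
analytic lung volume (with a floor keeping every diameter above the
2 mm gate).  Each arterial tree (58% of trees) carries a parallel
airway tube at a fixed offset of 1.5 vessel radii with 0.45× radius —
the minimal structure the bronchus-proximity labelling rule needs.

Rasterization paints anti-aliased tubes (linear partial-volume ramp
over one voxel) at 0.7 mm isotropic spacing by default, applies a
0.5-voxel Gaussian for acquisition blur and adds 20 HU Gaussian noise.
HU levels are conventional non-contrast values (vessel +50, parenchyma
−850, airway −1000, background −1024).  Anti-aliasing matters: with
binary painting, tubes of 1.15 and 1.30 mm radius rasterize
identically at 0.7 mm and sub-voxel radiometry becomes impossible.

What the phantoms do **not** emulate: lobes and fissures, fibrosis
texture, non-binary branching, vessel taper within a segment,
respiratory/cardiac motion, scanner reconstruction kernels, and contact
between unrelated vessels.  Passing phantom tests therefore
demonstrates geometric correctness of the measurement chain, not
clinical segmentation quality on real CT.

The cohort generator draws per-subject metric vectors from a correlated
truncated Gaussian (volume–density and tortuosity–heterogeneity
correlated at 0.9, matching the reported strong couplings) and builds
pulmonary-function columns as explicit linear functions of the metrics
plus Gaussian noise; the noise SD is derived in closed form from a
target population R² (e.g. 0.45 between normalized vessel volume and
TLC).  Resampling (not clipping) at physical bounds keeps the moments
on target.

## Vessel extraction

**Vesselness.** Frangi-type Hessian eigenvalue analysis at scales
{1, 1.5, 2, 3, 4, 5} mm with γ=2 normalisation, α=β=0.5 and the
structureness scale c set to half the per-scale maximum Frobenius norm.
The per-voxel maximum over scales gives the response; the eigenvector
of the smallest-magnitude eigenvalue gives the tube axis.  Because the
pleural edge mimics a tube of radius ≈σ where it curves, each scale
responds only deeper than σ + 2 mm from the lung boundary (computed by
a Euclidean distance transform).  Eigendecomposition is restricted to
voxels with non-trivial second-order structure, which keeps a
0.5 L subject under ~20 s.

**Tracing.** Seeds are block-maxima of the response above 0.05 of the
global peak, processed strongest first.  Traces march bidirectionally
in half-voxel steps, blending the local Hessian axis with the previous
direction (0.7/0.3), re-centring each point on the response ridge
(parabolic refinement in the normal plane) and additionally on the HU
lumen centre (half-weight correction from opposite-ray crossing
asymmetry — this pins the trace to the tube axis when the ridge wanders
under noise).  A trace stops on: lung exit; response below 0.01 of
peak; entering another trace's claimed territory (the contact path id
is recorded for fusion); persistent loss of HU contrast (the physical
tube end — robust against large filter scales extending the response
past a tip); a persistent radius collapse (tube cap); or an unphysical
turning rate (>35° per 1 mm displacement baseline — jitter-proof
because it uses displacements, not per-step directions).  After a turn
or response stop, a straight probe pushes up to 6 mm through bright
lumen looking for claimed territory (closing the low-response
no-man's-land of bifurcations); if the probe crosses in open lumen the
march resumes ("coasting").

**Radius.**  Initialised by half-contrast crossings along 8 rays in the
normal plane, then refined by the cross-section area integral
`A = ∫ (HU − P)/(V − P) dA` over a polar grid (blur-invariant, which
matters below two voxels of radius where the crossing estimate
quantises).  Rays require ≥300 HU of local contrast so that the
parenchyma–background edge (≈170 HU) can never masquerade as a vessel
wall.  Free path ends are trimmed where the measured radius collapses
below 0.95 of the local reference, plus the geometric cap allowance
`r√(1−0.95²)` and a ~⅓-voxel blur slack — this localises a tube end to
roughly ±0.3 mm at 0.5 mm voxels.

**Trees.**  Path endpoints fuse to the path whose territory stopped
them, or to a nearby path point that *continues the tip direction*
(minimum-lateral-kink attachment, so fusion adds no spurious
tortuosity); junction identity is union-find over the attachment events
themselves rather than positional tolerance.  Skeleton branch points of
the thresholded response add split evidence.  Remaining loose tips are
closed against nearby edge polylines when the bridge stays in bright
lumen (crossing parenchyma means separate vessels — this is what keeps
distinct trees from merging).  Cycles are broken by a maximum spanning
forest weighted by arc × response, so short weak bridges are dropped,
never real branches.  Degree-2 nodes from trace fragmentation are
contracted; edges are then split at curvature kinks (>20° on a 1.2 mm
baseline) and at combined turn + radius-bump signatures of unresolved
junctions; dangling stubs shorter than ~2 radii at a junction are
pruned; and edge geometry within 2 local radii of any node is
linearised (the centreline inside a merged junction lumen carries no
tortuosity information).  The extraction runs internally in a canonical
axis order derived from grid shape/spacing/content, making world-space
outputs exactly invariant to how the input grid is laid out.

Each final edge is one segment: arc length, chord, DM, arc-weighted
mean diameter, and conical-frustum volume.  Only segments with mean
diameter in [2, 10] mm (inclusive) are retained.

## Artery/vein labelling

Per-segment evidence `e = |cos θ| · exp(−d / 2r)` against the
skeletonised airway centrelines (distance d, local vessel radius r),
volume-averaged per tree; trees label as a whole.  With the canonical
1.5-radius bronchus offset the arterial evidence plateaus near
exp(−0.75) ≈ 0.47 while airway-free veins score near zero, so the
default threshold is 0.3 (between the two modes; a threshold of 0.5
would sit above the arterial plateau and mislabel every artery).  The
uniformity prior flips the weakest-scoring trees in any lung octant
whose arterial volume fraction leaves [0.2, 0.8], but only in octants
holding at least 4 trees — with fewer, the fraction is 0 or 1 by
construction and carries no information.

## Morphometry, QC, statistics

Zones are thirds of equal lung volume along the cranio-caudal axis
(cut planes at the cumulative-volume crossings of ⅓ and ⅔); segments
belong to the zone of their arc-length midpoint, ties going caudal.
Percentiles use linear interpolation between order statistics
throughout.  Total and zonal lung volumes include vessel voxels (the
mask before vessel removal), consistent with normalizing vessel volume
to a volume that contains the vessels; mean lung attenuation excludes
vessel and airway voxels.  Undefined quantities (no segments, single
segment for a width) are NaN, never silent zeros.

QC fractions are volume-weighted against a reference mask:
spurious = extracted-not-reference / extracted, missed =
reference-not-extracted / reference; exclusion at strictly >10%
(either fraction) and additionally strictly >20% artery/vein
mislabelled volume for AV analyses.  The statistics layer is ordinary
least squares (statsmodels) with t-based 95% CIs, complete-case per
model, no multiple-testing correction by default (Holm available),
Student's t / chi-square / Mann–Whitney for group differences, and a
pairwise-R² collinearity guard at 0.5.

## Problem sizes and determinism

Default validation problem sizes: control tubes/arcs at 0.5 mm voxels
(sub-voxel end localisation needs it; at 0.7 mm the half-circle DM
error budget is exhausted by end effects alone), topology and cohort
phantoms at 0.7 mm, cohort-parameter recovery averaged over three
0.5 L phantom subjects (≈30 s each), and regression recovery over five
cohorts of 131 subjects.  All randomness flows from explicit integer
seeds; identical seed and spec give bit-identical phantoms and
deterministic pipeline output.

## Known limitations

- **Heterogeneity is over-estimated on dense phantoms.**  About 15–20%
  of extracted segments at cohort density are junction-affected —
  chains crossing bifurcations whose third branch did not connect, or
  junction-zone geometry — with DM errors up to ±0.1.  The tortuosity
  *median* is robust to this tail (recovered to ±0.003), but the
  15th–85th percentile *width* is not: measured ≈0.09 against a
  generative 0.058.  The kink/bump splitting and junction-zone
  linearisation reduce but do not eliminate the tail.
- Vessels below ~1.5 voxels in radius carry larger radius uncertainty;
  volumes are accurate to a few percent only above that.
- The artery/vein rule assumes airway-paired arteries; mislabelling on
  phantoms averages ~5–10% of vessel volume, dominated by trees whose
  paired airway is poorly resolved.
- The lung/airway fallbacks are phantom-grade; clinical use should
  supply external masks.
- Only axis-aligned image orientations are accepted; rotated direction
  matrices are rejected rather than resampled.
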