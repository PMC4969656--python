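# Methods

## Image model and conventions

A PET volume is a 3-D grid of SUV values with voxel spacing (default
4.0 × 4.0 × 2.0 mm, one voxel = 0.032 ml) and a physical origin.  Grid
indices are 0-based; voxel (i, j, k) sits at `origin + index × spacing`,
and every geometric operation (polygon rasterization, sphere membership,
ellipsoid voxelization) uses voxel-center semantics.  SUV values are
stored already converted; decay correction is assumed to have been
applied upstream by the scanner, per clinical convention, and the SUV
formula uses total body weight in grams (lean-body-mass variants are out
of scope).  Volumes persist as NIfTI plus a JSON sidecar; the sidecar
carries spacing/origin at full float64 precision because NIfTI headers
store affines in float32.

## Delineation

**VOIs.**  Per-slice polygons are rasterized by the even-odd rule on
pixel centers, with centers exactly on the boundary counted inside;
polygons must be simple (validated via their planar geometry).  The
3-D VOI is the union of the per-slice masks.

**Thresholds.**  Both threshold methods use inclusive comparison (≥).
"Strictly greater" would make q = 100% empty and create floating-point
ambiguity on plateaus; inclusive keeps every boundary case deterministic.
No connectivity filter is applied by default — an absolute threshold
above the lesion's SUVmax legitimately yields zero volume, which the
cohort statistics must see as 0 ml, not as missing.  An optional
`connected_only` flag keeps only the component containing the hottest
voxel.

**Adaptive region growing (ARG).**  Growth starts at the hottest VOI
voxel (lexicographic tie-break) and repeatedly examines the hottest
frontier voxel (again lexicographic on ties), admitting it while
`value ≥ running-region-mean × fraction`, with the mean updated after
every admission.  Because the frontier priority does not depend on the
fraction, the admission sequence is shared by all fractions: one flood
to 0% records, for each admitted voxel, the ratio value/mean at
admission, and the region at fraction f is the longest admission prefix
whose ratios all stay ≥ f.  This makes the 100% → 0% sweep (1% steps by
default) a single O(N log N) pass and guarantees the volume curve is
monotone non-decreasing as the fraction falls.  Neighborhood
connectivity is 6 (face neighbors) by default — conservative on
anisotropic voxels — configurable to 26.

The tumor boundary is the *knee* of the volume–fraction curve: the index
maximizing the consecutive-volume ratio `V[i+1]/V[i]` (first occurrence
on ties), accepted only if that maximum is at least `min_jump = 2.0`;
otherwise the case is flagged unsuccessful rather than silently
segmented.  The region reported is the one just above the jump.  Growth
is bounded by the VOI bounding box with each axis doubled (padded by
half its length per side, clipped to the grid): wide enough that the
boundary never depends on the drawn VOI shape — only the seed voxel
does, which is why repeated and inter-operator ARG measurements agree
exactly — yet bounded, so a failed knee cannot flood the whole scan.

*Known limitation:* on small, noisy, low-contrast lesions the top of the
sweep is quantized (1 voxel → a few voxels is already a ratio ≥ 2), and
the max-ratio rule can report that quantization step as the knee,
yielding a very small region; conversely the method systematically
overestimates volume on blurred lesions because growth stops only at the
background flood.  Both behaviors are inherent to the published
procedure; a post-hoc volume correction is deliberately not applied.

## Quantification

MTV = voxel count × voxel volume (ml); SUVmean = mean SUV over the
segmented voxels, reported as NaN (never 0) for empty segmentations so
downstream statistics can exclude those cases explicitly; TLG =
MTV × SUVmean (0 for empty regions).  TLG is recorded in ml·SUV; the
literature's "g" unit assumes tissue density 1 g/ml.  SUVpeak (mean over
voxels whose centers lie within a 12-mm-diameter, ~1 ml sphere centered
on the hottest VOI voxel, clipped with a warning at the grid edge) is
computed for completeness but not included in the default report tables.

## Statistics

The default ICC is the two-way random-effects, absolute-agreement,
single-measures form ICC(2,1), computed from the ANOVA mean squares of
the subjects × raters table; one-way (ICC(1,1)) and consistency
(ICC(3,1)) forms are selectable and the model used is recorded in every
report row, since published reproducibility tables rarely state the
form.  Identical non-constant vectors return exactly 1; zero
between-subject variance is flagged degenerate rather than reported.
Reproducibility tables carry the two intra-operator pairings
(Op1Ob1–Op1Ob2, Op2Ob1–Op2Ob2) and four inter-operator pairings.

Phase comparisons use one observation per subject (Op1Ob1 by default).
The D/E column is the ratio of phase means, not the mean of per-subject
ratios — the convention that reproduces published dual-time-point tables
from their printed phase means.  Paired t-tests are Holm-adjusted with
the 17 parameters of one run treated as a single family; a comparison
whose paired differences are all equal (including identical phases) is
flagged degenerate instead of being assigned a p-value.  Bland–Altman
output records per-subject (mean, difference) pairs and
mean ± 1.96 SD limits of agreement.

## Synthetic cohort

`make_phantom` builds a piecewise-constant compartment image — lung
background (SUV 0.5), a central mediastinal slab (SUV 1.0, half-width
24 mm), and an ellipsoidal lesion — scales each compartment per phase,
convolves with a Gaussian PSF (8.4 mm FWHM), adds Gaussian noise in SUV
space (SD 0.15), and clips at zero.  Defaults for the dual-time-point
kinetics: lesion ×1.22 (anchored to the typical delayed/early SUVmax
ratio of malignant lesions), lung ×0.85, mediastinum ×0.90.  Additive
Gaussian noise stands in for reconstruction noise; sinogram-level
simulation, respiratory motion and attenuation effects are explicitly
not modeled, so passing tests demonstrate the delineation/statistics
machinery and the direction of uptake-time effects, not scanner-grade
realism.  Ground truth is the voxelized (center-inside) ellipsoid, so
recovery checks on blur-free, noise-free phantoms are exact rather than
approximate.

Cohorts (default grid 64 × 64 × 64 at 4 × 4 × 2 mm) draw lesion volumes
log-uniformly from 1–60 ml, unblurred lesion SUV log-uniformly from
4–20, mild shape anisotropy, and per-subject uptake factors from
N(1.22, 0.05) clipped to [1.02, 1.45]; lesions are placed in the lung
fields clear of the mediastinum and grid edges.  Scan metadata uses a
224 MBq injection and 56 kg body weight, the cohort-typical values, at
60/120 min uptake times.

Simulated operators draw one polygon per slice over the lesion's axial
extent plus one FWHM, with the outline taken from the widest geometric
cross-section within one FWHM of the slice (what the blurred image
shows), dilated by one FWHM plus a per-slice margin drawn uniformly from
8–16 mm.  A drawn VOI must contain the entire true lesion and every
nearby voxel at or above the smallest analysis threshold (SUV 2.0);
violations raise an error rather than degrade the data silently.  With
these defaults the four observations per lesion select identical
supra-threshold voxel sets, so the deterministic methods reach ICC = 1
by construction — the mechanism behind near-perfect published
inter-operator agreement.

One modeled mechanism deserves emphasis: because the whole lesion is
scaled by a single uptake factor, the %SUVmax segmentations (invariant
under global rescaling) move only through the small background wash-out
term at the blurred rim, while absolute thresholds feel the full 22%
uptake rise.  The simulated cohort therefore reproduces the *signs* of
the published uptake-time effects (MTV_q% down, MTV_ARG and all TLG up,
absolute-threshold sensitivity growing with p) but not the published
*magnitude* of the %SUVmax decrease, which in patients is driven by
spatially heterogeneous uptake change (the hottest core rising faster
than the rim) that a scalar lesion factor cannot express.

## Problem sizes and numerics

Default test and report runs use 50-subject cohorts on the 64³ grid
(seconds per full pipeline on one core; the region-growing kernel is
JIT-compiled).  The ARG sweep uses 1% steps; knee detection requires a
consecutive-volume ratio ≥ 2.0.  All ICC/t/Holm computations are plain
double-precision closed forms; ICC equality to 1 for identical inputs is
enforced exactly rather than left to floating-point cancellation.
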