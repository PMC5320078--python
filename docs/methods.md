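# Methods

This note records the model behind each stage, the tunable parameters and
their defaults, what the synthetic phantom does and does not emulate, and the
design choices made where the design was genuinely open.

## Input model and assumptions

The pipeline expects a non-contrast axial head-CT volume in Hounsfield units
with clinical stroke-protocol geometry (sub-millimetre in-plane pixels,
thick ~5 mm slices, a dozen or so slices).  It assumes: an intact skull ring
on every slice (bone ≥ 100 HU encloses the brain); ventricular CSF as the
darkest brain tissue (≈1–12 HU) against white matter (≈25–38 HU) and gray
matter (≈35–60 HU); and, when ischemic lesions are present, lesion
attenuation overlapping the upper part of the CSF band.  Hemorrhage, large
craniotomies and non-axial acquisitions are outside the model.

Arrays are indexed `[x, y, z]` (column, row, slice); all geometry lives in
voxel index space and physical spacing enters only for millimetre/millilitre
outputs.

## Alignment

Per-slice light-curve detection uses a vertical 7-tap Gaussian with variance
2 (`exp(-k²/4)`, normalised) followed by the horizontal zero-sum line mask
`[-0.5, 0, 1, 0, -0.5]` and an adaptive threshold at mean + 2.5 σ of the
response over a central rectangle of interest (half the brain bounding-box
width, full image height).  Detections are restricted to the brain eroded by
4 px — partial-volume bone bleed at the inner skull table otherwise fires
the line detector on curved skull arcs — and cleaned with a 26-connected 3D
size filter at 30 voxels.

The midsagittal plane is fitted as `x = a·y + b·z + c` by closed-form least
squares.  Two conventions differ deliberately from a literal reading of the
usual formulation: fitting `x` as the dependent variable (a plane fitted as
`z(x, y)` is degenerate for near-vertical sagittal planes), and a proper
rotation matrix for the per-slice correction (a matrix with two positive
off-diagonal sine terms has determinant cos 2θ and shears the image).

The raw point cloud legitimately contains more than the falx: the flanks of
the interhemispheric fissure and the medial ventricle walls are also
midline-symmetric near-vertical structures, and curved lateral ventricle
walls survive the size filter as well.  The fit is therefore robustified by
iterative residual trimming with a MAD-based scale (cut =
max(6 px, 2.5·σ_MAD), ≤5 rounds, stop below 30 points).  The 6 px floor must
span both fissure flanks (detections peak ~2–3 px either side of the exact
midline); a tighter floor can collapse the fit onto a single flank and
inherit its offset.  When no plausible plane emerges (|a| ≥ tan 30° or fewer
than 3 points) the aligner falls back to a vertical line through the brain
bounding-box centre and logs it.

Masks are transported to the aligned frame with nearest-neighbour sampling;
the final mask is mapped back to the original frame by lightly smoothing the
0/1 indicator (σ = 0.6 px in-plane), resampling linearly, and thresholding
at 0.5, which anti-aliases the voxel staircase.

## Ventricular intensity range

Brain voxels at most 80 HU (excluding bone partial volume) are split by 1D
2-means.  Lloyd iterations are run from three deterministic seedings (the
10/90, 1/99 and 0/100 percentile pairs) and the lowest-SSE solution wins; a
single 10/90 seeding demonstrably settles into a local optimum that splits
gray from white matter instead of CSF from parenchyma, because CSF holds
only a few percent of brain voxels.  The largest 26-connected component of
the low stratum is the candidate ventricle.

The per-HU histogram of the candidate (3-bin moving average) then yields:

* the **CSF mode** — the leftmost local maximum with prominence ≥ 15 % of
  the global peak (centre of mass of its near-peak bins).  CSF is the
  darkest brain tissue; a large attached lesion can outweigh the CSF bulk
  and move the *global* maximum without moving this leftmost peak;
* the **separator** `critical_intensity` — scanning upward from the mode,
  the first bin where the smoothed slope turns non-negative or flattens
  below 2 % of the peak, *accepted only where the histogram has dropped to
  ≤ 20 % of the peak* (a dip in front of an attached-lesion bump is densely
  populated and is skipped), and clamped to
  min(mode + 2.2 left-half-widths, 16 HU).  The left half-width is measured
  on the uncontaminated left flank of the CSF peak; the 16 HU ceiling
  encodes that periventricular partial volume and leukoaraiosis occupy
  roughly 18–25 HU and must stay outside the mask;
* `V_max = critical_intensity` and `V_min = max(0, 2·mode − critical)`,
  with `V_min` additionally capped at 4 HU (ventricular CSF reaches ~1 HU,
  so a higher floor would cut genuine CSF; it arises only when contamination
  drags the apparent mode upward).

If no valley is accepted inside the −5…25 HU sanity band the estimate falls
back to the domain range 1–12 HU with a logged warning.

## Segmentation and stroke exclusion

`f(t)` is the band threshold `{brain, V_min ≤ HU ≤ t}`.  The preliminary
segmentation is the largest 26-connected component of `f(V_max)`; ties in
component size resolve to the first label in raster order.

*Edge check.*  The brain-edge annulus is the per-slice band within
0.15·L_min of the brain boundary (L_min = smaller side of the scan-wide
brain bounding rectangle; erosion by a disk of that radius).  A stroke is
flagged when any slice's segmentation–annulus overlap strictly exceeds
20 px.

*Image difference.*  The detection predicate is monotone in `t` (raising the
threshold only adds voxels), so the largest clean threshold `T_critical` is
found by integer bisection — equivalent to, and verified against, an
exhaustive scan.  The benchmark ventricular mask is the segmentation
*result* at `T_critical` (threshold **plus** largest component): using the
raw threshold mask would let the closing rebuild sub-threshold lesion
speckle inside the lesion and shield it from subtraction.  The stroke mask
is `PA = f(V_max) − g(benchmark)` with `g` = per-slice closing (disk r = 2)
then dilation (r = 1), restricted to components that touch the annulus and
are at least 20 voxels (the bare morphology margin is not stroke tissue).
`g(PA)` is subtracted from the **full band mask** `f(V_max)`, not from the
preliminary largest component: when a disconnected lesion complex outweighs
the ventricle, the largest component *is* the lesion, and the ventricle must
remain recoverable by the final largest-component step.

*Adaptive template.*  Template levels are tried strict-to-permissive:
`V_min`, the 25th percentile of the candidate-component histogram (deep in
the CSF bulk, robust to attached-lesion contamination), then the band
midpoint; a level is accepted once it selects ≥ 100 voxels *and* ≥ 25 % of
the full-band mask, so the template genuinely covers the ventricle main
body.  The largest component is closed (r = 2) and dilated (r = 3)
per slice.  Applying the template keeps segmentation components that overlap
it; outside-template voxels of retained components are removed when their
per-slice 2D blob reaches 20 px (a lesion poking out) and kept when smaller
(true ventricle edge slightly exceeding the template).  Removing the large
blobs is what breaks lesion–ventricle bridges in 3D.

*Refinement.*  Largest component → per-slice closing (r = 2) → removal of
voxels brighter than `V_max` + 30 HU (calcifications pulled in by the
closing) → largest component.  Morphological smoothing is 2D per slice
throughout (5 mm slices make 3D structuring elements badly anisotropic);
connectivity analysis is 3D with 26-connectivity.

## Evaluation

Dice, sensitivity and specificity are voxel counts; the negative domain for
specificity defaults to the brain mask — full-frame negatives would inflate
specificity towards 1 regardless of segmentation quality.  Boundary RMSE
matches each predicted boundary pixel (8-adjacent to background within its
slice) to the closest reference boundary pixel in the same slice, in mm;
the match is one-directional (segmented → reference) and slices without a
reference boundary are skipped with a logged count.  Sub-pixel contours are
not used.  The reliability curve uses the strict inequality Dice > d; at
d equal to the best case's Dice it is therefore 0, not (n−k)/n.  Suite
tables report mean/SD (n−1)/min/max, and volume correlation is the Pearson
coefficient of paired volumes in mL.

## Synthetic phantom

The phantom reproduces the structure the algorithm relies on, on a
256×256×14 grid at 0.426/5.0 mm by default: an elliptical skull ring
(1000 HU, 3 mm thick) around a brain of white matter (truncated normal,
31.5 ± 2.2 HU) and gray matter (39 ± 2.5 HU); a mirrored pair of
comma-shaped lateral-ventricle lobes spanning the central six slices plus a
midline third-ventricle slit (together one 26-connected component, CSF
filled at 6.5 ± 1.8 HU, about 25 mL at scale 1 — typical for the elderly
stroke population); a ~1 px periventricular rim at 19.5 HU modelling the
ependymal/partial-volume transition observed on real CT; an
interhemispheric fissure (2 px CSF groove along the midline, anterior and
posterior of the ventricles, on every slice) with the falx cerebri as a
thin +8 HU membrane inside it on a Bernoulli(0.3) subset of slices;
optional spherical hypodense lesions with softly blended margins, placed
either in the brain-edge band (centre within 0.15·L_min of the boundary) or
against a ventricle wall; rigid in-plane tilt/shift; an in-plane Gaussian
PSF (σ = 1 px); and additive Gaussian noise (SD 3 HU).

Tissue fills are concentrated *inside* the nominal population HU ranges:
rendering them iid-uniform over the full ranges would make parenchyma
bimodal and texture-dominated, which real non-contrast CT is not, and both
the 2-class clustering and the line detector would then fail for reasons
that have nothing to do with real data.  Pose is applied analytically —
anatomy is evaluated on inverse-rotated coordinates — so truth masks are
exact rasterisations with no resampling jitter, and ground truth is defined
before blur and noise (the PSF models the scanner, not the anatomy).

The reference suite (30 cases) varies tilt U(−15°, 15°), in-plane shift
U(−10, 10) px per axis, ventricle scale U(0.85, 1.2) (patient ventricle
volumes vary strongly; without this the volume correlation would be
degenerate), lesion radius U(5, 25) mm for edge lesions and U(4, 9) mm for
periventricular ones, and lesion HU bands `[lo, lo+6]` with
lo ~ U(6.5, 9.5).  That band squarely overlaps the ventricular range while
modelling *acute* ischemic hypodensity: chronic, CSF-identical lesions
(lo below ~6) defeat any intensity-based template — a limitation of the
method itself — and lo above ~10 produces a detached histogram bump that is
trivially excluded.  Per-case draws are recorded in the suite manifest.

Not emulated: realistic CT physics (beam hardening, streaks), through-slice
partial volume, sulcal/subarachnoid CSF beyond the interhemispheric
fissure, hemorrhage, anatomical variants.  Passing on phantoms therefore
shows algorithmic correctness under the stated model, not clinical-grade
robustness.

## Reference-suite performance and known limitations

On the frozen 30-case reference suite the pipeline reaches mean Dice ≈
0.985, sensitivity ≈ 0.985, brain-restricted specificity ≈ 0.999,
reliability R(0.85) = 1.0, volume correlation ≈ 0.997, and mean boundary
RMSE ≈ 0.235 mm, with at most ~3 % of any lesion's volume surviving into a
final mask.  The boundary RMSE floor is set by HU-noise jitter of the
thresholded contour (noise SD 3 HU across a ≈5 HU/px partial-volume ramp is
≈0.5 px of point noise per case); the remaining case-level outliers are
contact-zone artifacts where a lesion hugs the ventricle wall — residual
lesion tongues kept by the template, or small subtraction bites — the same
residual-small-lesion behaviour the method is known for clinically.  The
suite is deliberately lesion-heavy (25 of 30 cases), so its aggregate
boundary error sits slightly above what a predominantly clean cohort
yields.

Determinism: every stage is deterministic given the input volume; phantom
generation is bit-reproducible for a fixed seed, and suites derive per-case
seeds from a single master seed.
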