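# Methods

## Model and procedure

The measurement problem: on fluid-sensitive knee MRI, bone marrow lesions
(BMLs) are hyperintense but ill-defined, and signal intensity (SI) is an
arbitrary unit that varies between examinations. Both pathways implemented
here therefore calibrate on the patient's own unaffected marrow: the reader
outlines reference regions in the *lateral* femoral condyle and tibial
plateau (assumed lesion-free), and the segmentation cutoff is

    T = mean_SI + k · SD_SI

with the sample (n−1) SD. The manual pathway (MS) uses k = 1 and one central
lateral slice; the computer-assisted pathway (CAS) uses k = 2 and pools two
adjacent central lateral slices into a single voxel population. These k
values reflect how each pathway interacts with the threshold: a manual
outline drawn around the visually coherent lesion matches the looser k = 1
cutoff, whereas pure voxel counting needs the stricter k = 2 cutoff to
suppress the Gaussian background tail (2.3% of normal marrow exceeds
mean + 2 SD by construction).

**CAS.** Within the medial target polygons, voxels with SI *strictly above*
T are selected; connected components of fewer than `min_size = 5` voxels are
removed as noise; per-slice lesion area is the voxel count × pixel area.

**MS.** The reader's drawn polygons are refined against the threshold (see
below) and measured as continuous shoelace areas (workstation planimetry).
Enclosed sub-threshold tissue counts, which is why MS measures systematically
more than CAS on lesions with heterogeneous cores — a property the test
suite reproduces on phantoms.

**Volumetry.** Per-slice areas are multiplied by the effective slice pitch
t + g (slice thickness + interslice gap; 4.0 + 0.4 mm in the reference
protocol — the gap tissue is attributed to the adjacent slice). The analysed
region volume uses the same pitch, so the relative involvement
`100 · V_lesion / V_region` is pitch-invariant. Relative involvement is
stored at full precision and rounded half-up to integer percent only at
report time; BLOKS size grades are 0 = none (exactly zero), 1 = <10%,
2 = 10–25% (closed bin; the printed "<10%" is strict so the boundary values
10 and 25 belong to grade 2), 3 = >25%. The end-to-end workflows grade the
*report-rounded* percent, so sub-0.5% residual noise on an otherwise clean
examination reads as grade 0, consistent with how a reported "0%" would be
graded.

**Agreement and change.** Bland–Altman statistics on paired measurements
(difference direction a−b: reader 1 − reader 2, CAS − MS): bias = mean
difference, 95% CI of the bias via the t quantile
(bias ± t₀.₉₇₅,ₙ₋₁·SD/√n), and 95% limits of agreement bias ± 1.96·SD of the
differences. The 1.96 normal multiplier (no small-sample correction) is the
conventional Bland–Altman choice; the CI of the bias is where the t
distribution enters. Baseline limits of agreement are used verbatim as the
minimal detectable change: a follow-up change strictly outside them is
progression/regression, anything inside (including exactly on a limit) is
stable. Spearman rank correlation (average ranks, two-sided p via the t
approximation) compares methods; reference thresholds are compared with the
classic pooled-variance Student t-test (not Welch). Degenerate zero-variance
comparisons return p = 1 with a warning rather than an error.

## Geometry and rasterization

Coordinates are physical millimetres (row, col) with the origin at the
center of voxel (slice 0, row 0, col 0); indexing is 0-based. A voxel
belongs to a polygon iff its *center* is inside (even-odd rule for the
simple polygons admitted), and a center exactly on an edge counts as inside.
The voxel-center rule is this package's choice — how the original
workstation treated sub-voxel boundaries is not documented — and the
rasterized area converges to the shoelace area as pixel spacing shrinks
(tested at 1.0 / 0.5 / 0.25 mm). Anatomical subregion geometry (posterior
2/3 femoral condyle, the 20 mm tibial cut, 3 mm offsets) is encoded by the
user's polygons, not detected automatically.

NIfTI stacks store data as (slice, row, col) with zooms
(pitch, row-spacing, col-spacing); the pitch is split into thickness + gap
using the configured gap (default 0.4 mm). TIFF stacks carry no reliable 3-D
geometry, so explicit geometry is mandatory there.

## Boundary refinement (MS)

The original description — scanning the drawn border with a 5 mm²
rectangular ROI and adjusting demarcation points where the SI crosses the
threshold — is qualitative, so the concrete algorithm is this package's
design:

- Each vertex carries a window of area 5 mm² *centred on the vertex*,
  aligned with the local boundary (tangential extent = area / depth,
  default depth 1 mm), sampled bilinearly.
- Window mean above T → move the vertex outward along its normal (lesion
  signal spills past the border); below T → inward; exactly at T → no move.
- The per-vertex step starts at half the in-plane pixel spacing and is
  halved on each direction reversal, so vertices settle on the threshold
  isocontour instead of oscillating; moves that would self-intersect the
  polygon are rejected; iteration stops at equilibrium or `max_iterations`
  (default 50).

A two-window variant ("just outside" / "just inside" the border) was
considered and rejected: its stopping condition (inside-window mean reaching
T) sits a fixed fraction of the window depth *outside* the true contour for
high-contrast lesions, biasing areas upward by ~10% at realistic lesion
radii. The centred window is unbiased to first order: its equilibrium is the
threshold crossing of the window mean. On a disc phantom the refined area
lands within ~3% of truth from either side (tested at ±2 mm initial error),
and a second refinement pass changes the area by well under 2%. Whether the
original method moved vertices or whole segments is unknown; per-vertex
movement is the choice here. All probe parameters are configurable.

## Synthetic phantoms

The generator emulates only what the segmentation chain is sensitive to:
a marrow background of i.i.d. Gaussian SI (default mean 185, SD 34 — the
regime of a healthy lateral reference region), ellipsoidal lesions raising
the signal by `offset_sd · SD` (default test phantoms use +5 SD) with a
linear edge taper of one in-plane voxel (~0.5 mm) to create ill-defined
margins, and rectangular reference/target ROIs on disjoint slices. Geometry
defaults follow the reference protocol (266 × 512 matrix over a 20 cm field
of view, 4.0 mm slices, 0.4 mm gap); tests crop the matrix to keep runtimes
in seconds without changing voxel geometry. Ground-truth lesion volume is
exact voxel-center counting against the analytic ellipsoid times the voxel
volume. Rician noise (magnitude of a complex Gaussian) is selectable since
STIR magnitude noise is Rician, but its mean/SD then deviate slightly from
the nominal background values; the Gaussian default keeps the calibration
arithmetic exact.

What the phantoms do **not** model: anatomy (bone contours, cartilage,
partial-volume soft tissue), spatially correlated noise, bias fields,
inter-sequence variation, or reader subjectivity in initial polygon
placement (only vertex jitter via `two_reader_perturbation`, truncated
Gaussian at 2 SD). Passing phantom tests therefore demonstrates the
correctness of the measurement chain, not clinical reader performance.

## Numerical choices and degenerate inputs

- Strict `>` thresholding: a voxel exactly at T is background.
- Cluster connectivity default `volumetric_26` (the method computes
  three-dimensional volumes); `in_slice_8` is selectable because the
  interslice gap makes cross-slice adjacency debatable. `min_size` is a
  parameter (default 5) for sensitivity analysis.
- Thresholds, areas and percents are never rounded internally; half-up
  integer rounding is applied only in reports. Printed worked examples that
  show integer thresholds arise from integer printed means/SDs; the
  implementation always computes mean + k·SD exactly.
- Empty masks quantify to volume 0 / 0% / grade 0; an empty reference union,
  mixed reference roles, targets with zero rasterized volume, inverted MDC
  limits, and sub-minimal sample sizes are errors. A polygon covering no
  voxel centers rasterizes to an empty mask with a warning.
- Degenerate (0, 0) limits of agreement are accepted by the change
  classifier: perfect baseline agreement makes any nonzero change
  significant.

## Known limitations

- Reference regions are asserted lesion-free by the user; no automatic
  detection of "unaffected" marrow.
- No partial-volume correction: boundary voxels are all-or-nothing, which
  together with the lesion edge taper drives the few-percent overestimate
  seen in phantom recovery.
- The boundary-refinement equilibrium depends mildly on lesion contrast
  (the window-mean crossing sits where the supra-threshold fraction of the
  window equals (T − background)/offset), an inherent property of
  finite-window probing.
- Patient-level clinical results cannot be reproduced without the original
  image set; validation rests on worked examples with fully printed inputs,
  property-based tests, and phantom parameter recovery.
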