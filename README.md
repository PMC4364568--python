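# bmlquant

Quantitative measurement of bone marrow lesions (BMLs) on knee MRI.

BMLs are ill-defined hyperintense areas in subchondral bone on fluid-sensitive
(STIR) sequences, associated with pain and structural progression in knee
osteoarthritis. Because MR signal intensity (SI) is an arbitrary unit, lesion
burden cannot be read off the image directly: each examination must be
calibrated against the patient's own unaffected marrow. `bmlquant` implements
two such calibrated segmentation pathways and the statistics used to compare
their reliability and sensitivity to change — aimed at readers and
methodologists evaluating quantitative BML measurement, e.g. for
disease-modifying osteoarthritis drug trials.

## Method

Both pathways start from reference statistics (mean SI and sample SD) of
lesion-free *lateral* femoral condyle / tibial plateau marrow, and a threshold

```
T = mean_SI + k · SD_SI
```

- **CAS** (computer-assisted segmentation, `k = 2`): voxels inside the medial
  target subregions with SI strictly above `T` are extracted; scattered
  clusters of fewer than 5 interconnected voxels are discarded as noise
  (26-connectivity by default); per-slice areas are voxel counts × pixel area.
- **MS** (manual segmentation, `k = 1`): the reader's drawn lesion polygons
  are refined against the threshold isocontour with a 5 mm² probe window and
  measured planimetrically (continuous shoelace areas), so enclosed
  sub-threshold tissue is included — MS systematically measures more than CAS
  on heterogeneous lesions.

Volumes multiply areas by the effective slice pitch `t + g` (slice thickness
plus interslice gap, 4.0 + 0.4 mm in the reference protocol). Lesion volume
relative to the analysed condyle/plateau volume (`% BML involvement`) is
binned into BLOKS size grades 0–3 (none, <10%, 10–25%, >25%). Reliability is
assessed by Bland–Altman analysis (bias, 95% CI, 95% limits of agreement);
the baseline limits of agreement serve as the minimal detectable change (MDC)
for classifying longitudinal change as regression / stable / progression.

A synthetic phantom generator (Gaussian marrow background, ellipsoidal
lesions of known voxelized volume, matching ROI files) makes the whole chain
testable without clinical data.

## Worked example

```python
import bmlquant as bq

spec = bq.PhantomSpec(
    shape=(8, 160, 240),
    lesions=(bq.Lesion(center_mm=(17.6, 60.0, 45.0),
                       semi_axes_mm=(6.0, 8.0, 6.5),
                       offset_sd=5.0),),
    seed=42,
)
grid, regions, truth = bq.generate_phantom(spec)
(result,) = bq.run_cas(grid, regions)

print(f"true lesion volume : {truth.lesion_volumes_mm3[0]:.0f} mm^3")
print(f"threshold          : {result.threshold.value:.1f} SI "
      f"(mean {result.stats.mean_si:.1f} + 2 x SD {result.stats.sd_si:.1f})")
print(f"CAS lesion volume  : {result.quant.total_volume:.0f} mm^3")
print(f"relative involvement: {result.quant.relative_percent:.1f}% "
      f"-> BLOKS grade {result.grade.grade}")
```

prints

```
true lesion volume : 1387 mm^3
threshold          : 253.4 SI (mean 184.1 + 2 x SD 34.6)
CAS lesion volume  : 1477 mm^3
relative involvement: 2.8% -> BLOKS grade 1
```

The phantom inserts a ~1.4 cm³ ellipsoidal lesion at +5 SD above a Gaussian
marrow background (mean 185, SD 34). Calibration on the lesion-free lateral
slices recovers those statistics, the k = 2 threshold lands at ≈253 SI, and
the full CAS chain (thresholding, noise-cluster filtering, pitch-based
volumetry) recovers the true volume within ~7%; the slight overestimate comes
from the tapered lesion margin and residual supra-threshold noise clusters.
The grade reflects the half-up integer-rounded percent.

A command-line interface mirrors the library:

```bash
bmlquant phantom --spec spec.yaml --out phantom/
bmlquant calibrate phantom/stack.nii.gz phantom/regions.json --k 2
bmlquant segment-cas phantom/stack.nii.gz phantom/regions.json --out results
bmlquant segment-ms  phantom/stack.nii.gz phantom/regions.json --out results_ms
bmlquant agreement baseline.csv followup.csv --out agreement.json
```

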