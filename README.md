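# ventriseg

Objective segmentation of the brain ventricles in non-contrast head CT of
ischemic-stroke patients.

Acute infarcts are hypodense and frequently touch or merge with the
ventricular system at similar Hounsfield values, which breaks naive
threshold segmentation exactly in the scans where ventricle volume matters
most (stroke CAD, midline-shift and hydrocephalus assessment). `ventriseg`
implements a fully automatic, training-free pipeline for this setting,
together with a synthetic head-CT phantom generator and a quantitative
evaluation suite, so the whole system can be exercised and validated without
clinical data.

## Method

For a head CT volume in HU the pipeline runs:

1. **Skull stripping** — bone at a fixed 100 HU threshold; the brain is the
   largest 3D region enclosed by the per-slice bone ring.
2. **Midsagittal alignment** — faint bright "light curves" (the falx cerebri
   and interhemispheric-fissure flanks) are detected per slice with a
   vertical 7-tap Gaussian (σ² = 2) followed by a horizontal zero-sum line
   mask `[-0.5, 0, 1, 0, -0.5]`, thresholded at mean + 2.5 σ, and cleaned by
   a 30-voxel 3D connected-component filter.  A least-squares plane
   `x = a·y + b·z + c` (with iterative residual trimming) is fitted through
   the surviving points and each slice is rigidly rotated/shifted so the
   midsagittal line coincides with the vertical centerline.
3. **Ventricular HU range** — 1D 2-means splits brain voxels into a low
   (CSF-like) and high (parenchyma) stratum; the largest 3D component of the
   low stratum is the candidate ventricle, and slope tracking of its per-HU
   histogram yields the CSF/white-matter separator `V_max` and the lower
   bound `V_min`.
4. **Stroke-excluding segmentation** — three schemes:
   * the largest 3D connected component of the band threshold
     `f(t) = {V_min ≤ HU ≤ t}` at `t = V_max` drops lesions not touching
     the ventricle;
   * a brain-edge annulus detector (width 0.15·L_min, 20 px area threshold)
     flags edge-adjacent infarcts; an integer bisection finds the largest
     *clean* threshold `T_critical`, and the image difference
     `PA ≈ f(V_max) − g(f(T_critical))` (g = per-slice closing + dilation)
     is subtracted;
   * an adaptive template — the ventricle main body at a strict threshold,
     closed and dilated — removes small periventricular lesions and breaks
     their 3D bridges to the ventricle.
   Refinement keeps the largest component, closes the contour per slice and
   removes calcifications.
5. **Evaluation** — Dice `2|V_s∩V_r| / (|V_s|+|V_r|)`, voxel
   sensitivity/specificity (negatives restricted to the brain), one-way
   boundary RMSE in mm (segmented → closest reference boundary point, per
   slice), the reliability curve `R(d)` = fraction of cases with Dice > d,
   and the Pearson correlation of segmented vs reference volumes.

The estimators follow scikit-learn conventions (`fit`, `predict`/`transform`,
`get_params`), with single-volume semantics: `fit` estimates the per-volume
parameters (midsagittal plane, HU range, `T_critical`), `predict` returns
the final mask in the original frame.

## Worked example

```python
from ventriseg import (PhantomSpec, LesionSpec, generate_phantom,
                       segment_ventricle, evaluate_case)

spec = PhantomSpec(tilt_deg=8.0, shift_px=(5.0, -3.0), seed=42,
                   stroke_spec=[LesionSpec(radius_mm=24.0, hu_range=(7.0, 13.0),
                                           placement="fixed", center_mm=(26.0, 2.0))])
vol, truth = generate_phantom(spec)

result = segment_ventricle(vol)
for line in result.log:
    print(line)

report = evaluate_case(result.final, truth.ventricle_mask, domain=truth.brain_mask)
print(f"dice={report.dice:.4f} sensitivity={report.sensitivity:.4f} "
      f"specificity={report.specificity:.4f} rmse_mm={report.rmse_mm:.3f}")
```

prints

```
alignment: tilt=7.83 deg, fallback=False, points=572
intensity: v_min=2.0, v_max=16.0, critical=16.0, fallback=False
edge check: detected=True
image difference: t_critical=7, PA voxels=40853
template: voxels=73686, seg after template=26614
final voxels=27051
dice=0.9654 sensitivity=0.9485 specificity=0.9989 rmse_mm=0.479
```

The phantom was tilted 8° with a large hypodense lesion (HU 7–13) fused to
the right lateral ventricle.  The aligner recovers the tilt to 0.2°, the
edge check fires, the threshold search finds `T_critical = 7` (below the
lesion band, so thresholding there disconnects the lesion), and the image
difference plus template remove it: only 0.2 % of the lesion volume survives
into the final mask, while the ventricle itself is recovered with Dice 0.97.

## Command line

```bash
ventriseg simulate --n 30 --seed 7 --out phantoms/ --stroke mixed
ventriseg segment phantoms/case000_ct.nii.gz --out mask.nii.gz --save-intermediates inter/
ventriseg evaluate mask.nii.gz phantoms/case000_ventricle.nii.gz \
          --domain phantoms/case000_brain.nii.gz --out report.csv
```

`segment` accepts NIfTI files or single-series DICOM directories (rescale
slope/intercept applied, slices sorted along the normal).

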