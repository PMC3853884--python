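# cbctprior

Planning-CT-based correction of cone-beam CT (CBCT) images for
quantitative use in radiotherapy, with a digital thorax/breast phantom so
the whole pipeline runs and is scored without any scan data.

## The problem

CBCT volumes acquired on the treatment machine are ideal for verifying
patient setup, but their Hounsfield units are unreliable: unmodelled
scatter produces a smooth *cupping* artifact, HU are biased in an
object-dependent way, partial-arc acquisitions (200° instead of 360°,
common in breast treatments where the gantry would collide with the
breast board) degrade image quality, and the reconstructed field of view
(FOV) often truncates the patient. All of this makes dose calculation on
the raw CBCT inaccurate. The patient's own planning CT, however, is
radiologically trustworthy and almost aligned — so it can serve as a
prior for fixing the CBCT.

## The method

Given a planning CT and a CBCT with rigid transform *T* (estimated by
mutual-information registration or supplied by the clinical system):

1. resample the CBCT onto the planning-CT grid through *T*;
2. segment both images into four classes — air, lung, soft tissue,
   bone — by HU thresholds inside a body mask;
3. per class *c*, on the attenuation-proportional scale
   μ = (HU + 1000) / 1000, form the ratio image

   R_c = μ_CT / μ_CBCT   on the voxels both segmentations assign to *c*;

4. low-pass filter each R_c (mask-normalized Gaussian, FWHM 20 mm) so
   only the smooth artifact field survives and no values bleed across
   class boundaries;
5. multiply the CBCT by the filtered ratio of its own class:
   μ_corr = R̃_c · μ_CBCT on each class mask;
6. recombine the four enhanced parts using the CBCT masks — the anatomy
   of the day;
7. complete the voxels outside the CBCT field of view from the planning
   CT.

The corrected CBCT keeps the treatment-day anatomy and the high spatial
frequencies of the CBCT, while its low-frequency intensity scale is
transferred from the planning CT.

## Worked example

```python
from cbctprior import (standard_fixture, correct_cbct, resample_to_grid,
                       hu_error_metrics)

fx = standard_fixture(0)                   # phantom + degraded CBCT + offset
result = correct_cbct(fx.ct, fx.cbct, fx.truth_transform)

cbct_on_ct, _ = resample_to_grid(fx.cbct, fx.ct.grid, fx.truth_transform)
masks = fx.truth_masks.copy(); masks.fov = result.fov
before = hu_error_metrics(cbct_on_ct, fx.ct, masks)
after  = hu_error_metrics(result.corrected, fx.ct, masks)
print(before.mae_hu, after.mae_hu)
```

prints (see `examples/03_correct_cbct.py` for the full script):

```
MAE over body-in-FOV:  144.4 HU ->   58.0 HU (60% reduction)
FOV completion: 727168 voxels copied from the CT (exact: True)
```

i.e. the correction removes 60 % of the HU error of the degraded CBCT,
and every voxel outside the CBCT support is completed from the planning
CT exactly. `examples/04_evaluate.py` adds the distribution and dose
surrogate views: the L1 histogram distance to the CT drops from 1.91 to
0.56 and the mean water-equivalent-path-length error from 56 mm to
2.5 mm of water.

The `examples/` scripts cover each capability (simulation, registration,
correction, evaluation); each prints the numbers it computes and a note
on what they mean.

## Command line

```
cbctprior simulate --out sim/ --seed 7        # phantom CT + synthetic CBCT
cbctprior register --fixed ct.nii.gz --moving cbct.nii.gz --out t.txt
cbctprior correct  --ct ct.nii.gz --cbct cbct.nii.gz --transform t.txt --out corr/
cbctprior evaluate --test corr/corrected.nii.gz --reference ct.nii.gz --out report.json
cbctprior run      --out run/ --seed 7        # the whole chain
```

Every output directory receives a JSON manifest with the effective
configuration, input checksums, and seeds. Parameters can be set in a
TOML file (`--config`); unknown keys are rejected.

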