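# annuseg

Automated measurement of the aortic annulus and prosthesis-size selection
for transcatheter aortic valve implantation (TAVI), from 2-D aortic
annular-plane CT images.

Sizing a TAVI prosthesis hinges on two numbers measured on the annular
plane — the cross-sectional **area** (mm²), which drives balloon-expandable
Edwards Sapien 3 sizing, and the **perimeter** (mm), which drives
self-expanding Medtronic Evolut sizing. Manual annotation of the annulus
contour is slow and operator-dependent. This package automates it:

1. **Preprocessing** — the annular plane is resampled to isotropic 1.0 mm
   and 0.5 mm grids by cubic-spline interpolation (preserving Hounsfield
   units) and clipped to 128 × 128 windows centred on the annulus.
2. **Segmentation** — one encoder–decoder residual network per resolution
   (U-shaped: downscaling path, upscaling path with skip connections, final
   sigmoid) emits a per-pixel annulus probability. The networks are
   implemented in pure NumPy with hand-written backpropagation and train on
   a single CPU core at phantom scale.
3. **Detection** — the two probability maps are fused (bilinear resampling
   of the coarse map onto the fine grid, mean, clamp to [0, 1]), the
   annulus contour is located by canny edge detection on the fused map, and
   area (shoelace formula) and perimeter (closed polyline length) are
   derived from the largest closed edge loop.
4. **Sizing** — measurements are looked up in contiguous, non-overlapping
   half-open sizing bands (area → Sapien 3, perimeter → Evolut); values
   outside the chart yield explicit out-of-range sentinels.
5. **Statistics** — Dice overlap, paired differences with the exact
   two-sided Wilcoxon signed-rank test, Pearson correlation, Shapiro–Wilk
   normality, Bland–Altman bias and limits of agreement
   (bias ± 1.96 σ), and the device-size agreement ratio.

Because clinical CT cohorts are private, the package ships a **phantom
generator**: contrast-CT-like annular planes (bright elliptical lumen,
darker wall ring, optional rim calcification, Gaussian noise) whose
contour, area `πab` and perimeter `4aE(e²)` are known analytically, so the
whole pipeline can be validated by parameter recovery.

## Worked example

Generate a small phantom cohort and look up device sizes for a
measurement:

```
$ annuseg phantom --n 4 --seed 7 --out demo_cohort
wrote 4 phantoms to demo_cohort

$ annuseg size --area 450 --perimeter 75
{
 "area_mm2": 450.0,
 "perimeter_mm": 75.0,
 "sapien3": "26",
 "evolut": "29"
}
```

An annulus of 450 mm² falls in the Sapien 3 "26" band (430–546 mm²), and a
perimeter of 75 mm in the Evolut "29" band (72.3–81.7 mm, the 23–26 mm
native-diameter window). The cohort directory contains per-case NIfTI
planes with JSON sidecars (spacing, origin, annulus centre), ground-truth
contour CSVs (`x_mm,y_mm`) and a `manifest.csv` with the drawn generator
parameters and analytic truths.

The full pipeline from the Python API:

```python
from annuseg import generate_cohort, prepare_sample, ModelConfig, build_model, train, detect

samples, specs = generate_cohort(200, seed=1001)
prepped = [prepare_sample(s.plane, s.truth_contour) for s in samples]
cfg = ModelConfig()  # depth 3, 4 base channels, 10 epochs, Adam 3e-3
m1 = train(build_model(cfg), [(p.plane_1mm, p.mask_1mm) for p in prepped[:170]],
           [(p.plane_1mm, p.mask_1mm) for p in prepped[170:]], cfg)
m05 = train(build_model(cfg), [(p.plane_05mm, p.mask_05mm) for p in prepped[:170]],
            [(p.plane_05mm, p.mask_05mm) for p in prepped[170:]], cfg)

test, _ = generate_cohort(50, seed=2002)
result = detect(test[0].plane, m1, m05)
print(result.measurement)
# Measurement(area=490.15233532350896, perimeter=79.41772444518244)
print(test[0].truth_area, test[0].truth_perimeter)
# 498.52240525182856 79.40061357784771
```

Here the first held-out phantom's analytic truth (498.5 mm², 79.40 mm) is
recovered to 1.7 % in area and 0.02 % in perimeter.

On a 200-phantom training cohort and 50 held-out phantoms this recovers
the analytic ground truth with a mean Dice of ≈ 0.99, mean absolute area
error ≈ 1.3 % and mean absolute perimeter error ≈ 1.0 %, with zero
detection failures; consecutive detections of the same plane are
bit-identical.

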