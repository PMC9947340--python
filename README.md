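# choroquant

Volumetric choroidal vascularity quantification for radial swept-source OCT
(SS-OCT) B-scan sets, with a ground-truth phantom generator and the paired
statistics of a dark/light-adaptation, glucose-vs-control study design.

## The problem

The choroid — the vascular layer between retina and sclera — supplies the
photoreceptors, whose oxygen demand peaks in darkness. Choroidal *thickness*
conflates vessels and connective tissue; the **choroidal vascularity index**

> CVI = LV / TCV

(luminal volume over total choroidal volume) separates the two compartments
and is robust to thickness confounds. This package implements the full
volumetric CVI pipeline for radial scan sets (18 B-scans at 10° through the
fovea; 12 mm × 3 mm at 2048 A-lines per scan):

1. **RPE detection and flattening** — the hyperreflective retinal pigment
   epithelium is traced by a slope-constrained minimum-cost path and each
   column is shifted so the RPE is level, removing acquisition tilt;
2. **choroid segmentation** — upper boundary at the RPE bottom edge, lower
   boundary at the choroid–sclera interface, both as minimum-cost paths
   through gradient cost images (externally produced boundaries can be
   injected instead);
3. **Niblack binarization** — local threshold `T = m + k·s` (31×31 window,
   k = −0.2, clipped borders, ROI-restricted statistics) splits the choroid
   band into hyporeflective lumen and hyperreflective stroma;
4. **polar volumetrics** — per-column compartment thickness is integrated
   over the radial sectors (`V = Σ h·r·Δr·Δθ`) into LV/SV/TCV and CVI over
   the 0–3, 3–6 and 0–6 mm macular rings, with lateral magnification
   corrected by Bennett's formula `q = 0.01306·(AL − 1.82)` relative to an
   emmetropic reference eye;
5. **adaptation statistics** — per-subject paired differences (glucose −
   control) of change-from-baseline, covariate-adjusted for axial length
   and age (reduces exactly to the paired t-test without covariates), laid
   out as a contrast grid with significance flags.

No clinical images are bundled: a **phantom generator** emulates the
acquisition (RPE band, undulating choroid with elliptical lumina at a
controlled luminal fraction, tilt, multiplicative speckle) with exact
ground truth for every stage, and a cohort simulator reproduces the paired
study design at the measurement level.

## Worked example

```python
from choroquant import PhantomParams, RunConfig, analyze_session, generate_phantom

scan_set, truth = generate_phantom(PhantomParams(seed=7))
volumes = analyze_session(scan_set, RunConfig())
print(f"true CVI(0-6mm) {truth.volumes[(0, 6)].cvi:.4f}")
print(f"recovered       {volumes[(0, 6)].cvi:.4f}")
print(volumes.to_frame().round(3).to_string(index=False))
```

prints

```
true CVI(0-6mm) 0.5959
recovered       0.5918
 ring_inner_mm  ring_outer_mm  LV_mm3  SV_mm3  TCV_mm3  CVI_pct
           0.0            3.0   1.165   0.820    1.985   58.682
           3.0            6.0   3.586   2.456    6.042   59.350
           0.0            6.0   4.750   3.276    8.026   59.185
```

i.e. for a phantom built at 59% true luminal fraction and ~0.3 mm choroid
(total choroidal volume π·3²·0.3 ≈ 8.5 mm³ over the 6 mm disc), the full
detection → flattening → segmentation → thresholding → integration chain
recovers CVI to better than a percentage point under 4-look speckle.

The same flow from the shell:

```bash
choroquant phantom  --out session/ --seed 7
choroquant quantify session/ --out volumes.csv
choroquant study    --out-dir study/ --n-subjects 8 --seed 1
```

Narrative drivers live under `analysis/` (phantom demo with figure, CVI
recovery sweep, cohort contrast report); each writes its tables under
`results/`.

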