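# pcatcalib

Pericoronary adipose tissue (PCAT) attenuation is a CCTA-derived imaging
biomarker of coronary inflammation: inflamed perivascular fat holds more
water and reads higher (less negative) in Hounsfield units. The measured
value, however, depends on the acquisition — tube voltage (kVp) shifts fat
HU through the beam spectrum, and iterative reconstruction (IR) shifts it
relative to filtered back projection (FBP) — which confounds multicenter
and longitudinal comparisons.

`pcatcalib` implements the full quantification-and-calibration workflow on
synthetic data, with no external inputs:

- **Synthetic heart phantom** — co-registered CT volumes emulating a
  contrast-injected ex vivo heart (iodinated lumen and left ventricle,
  myocardium, perivascular fat sheath, polystyrene-packed container)
  acquired at 80/100/120/140 kVp under FBP-like and IR-like noise regimes,
  with exact ground-truth tissue masks.
- **Tube VOI geometry** — vessel centerlines traced up to 40 mm, lumen
  segmentation and area-equivalent diameter estimation, and the
  perivascular tube VOI: all voxels within a radial distance of the artery
  equal to the vessel diameter, excluding the vessel itself.
- **PCAT measurement** — adipose voxels are those inside the VOI with HU in
  the closed window [−190, −30]; PCAT_MA is their arithmetic mean. One VOI,
  built on the 120 kVp IR volume, transfers by index identity to every
  co-registered acquisition.
- **Conversion-factor calibration** — per tube voltage *i*,

  ```
  k_i = PCAT_MA,i / PCAT_MA,120        (estimated from IR datasets)
  I_120 = I_i / k_i                    (correction to the 120 kVp reference)
  ```

  with per-scanner tables combined as mean ± standard error.
- **Study statistics** — one-way repeated-measures ANOVA for the
  tube-voltage effect (vessels as subjects), two-sided paired t tests for
  IR vs FBP, mean ± SE condition summaries, α = 0.05.

## Worked example

```python
from pcatcalib import RunConfig, run_pipeline

result = run_pipeline(RunConfig(out_dir="scratch/demo", n_vessels=3, seed=11))
print(result.report_text)
for kvp, (k, sd) in result.table.rounded().items():
    print(f"k_{kvp} = {k:.3f} +/- {sd:.3f}")
```

prints (seed 11, three vessels):

```
Tube-voltage effect (FBP): F(3, 6) = 1508.677, p = 5.07e-09
Tube-voltage effect (IR): F(3, 6) = 5592.251, p = 9.99e-11
IR vs FBP at 80 kVp: t(2) = 27.518, p = 0.00132, mean diff = +3.30 HU
IR vs FBP at 100 kVp: t(2) = 18.870, p = 0.0028, mean diff = +4.15 HU
IR vs FBP at 120 kVp: t(2) = 24.000, p = 0.00173, mean diff = +5.08 HU
IR vs FBP at 140 kVp: t(2) = 33.692, p = 0.00088, mean diff = +5.88 HU

Condition means (mean +/- SE, HU):
  80 kVp FBP: -90.82 +/- 0.78 (n = 3)
  80 kVp IR: -87.52 +/- 0.71 (n = 3)
  100 kVp FBP: -78.46 +/- 0.68 (n = 3)
  100 kVp IR: -74.31 +/- 0.49 (n = 3)
  120 kVp FBP: -73.72 +/- 0.61 (n = 3)
  120 kVp IR: -68.64 +/- 0.55 (n = 3)
  140 kVp FBP: -70.89 +/- 0.33 (n = 3)
  140 kVp IR: -65.01 +/- 0.43 (n = 3)
k_80 = 1.275 +/- 0.002
k_100 = 1.083 +/- 0.002
k_120 = 1.000 +/- 0.000
k_140 = 0.947 +/- 0.002
```

PCAT_MA rises with tube voltage; IR sits above FBP (the configured +3 HU
bias, widened at high kVp where the noisier FBP data lose more voxels at
the adipose window's upper edge); and the IR-derived conversion factors
recover the generator's configured fat-attenuation ratios. The same stages are scriptable from the shell via
`pcat-calib generate|measure|calibrate|convert|stats|run-all`.

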