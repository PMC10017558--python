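# Methods

## Problem and model

CT attenuation of adipose tissue is not an absolute quantity: the measured
Hounsfield units depend on the X-ray spectrum (set by tube voltage, kVp)
and on the reconstruction algorithm. For pericoronary adipose tissue
(PCAT) attenuation — the mean HU of fat voxels in a perivascular volume of
interest, used as an inflammation biomarker — this means values from scans
at different kVp or reconstruction settings are not directly comparable.

The package models the correction as a per-kVp multiplicative factor
relative to a 120 kVp reference:

    k_i   = PCAT_MA,i / PCAT_MA,120
    I_120 = I_i / k_i

Factors are estimated from iterative-reconstruction (IR) datasets, one
ratio per vessel, averaged with equal weight across vessels; tables from
different scanners are combined per kVp as the mean with a
standard-error-of-the-mean uncertainty. A scalar per-kVp ratio is the
entire harmonization model — no kernel, manufacturer, or patient covariate
terms.

## Synthetic phantom

The generator emulates a contrast-injected ex vivo heart preparation:
an iodinated lumen (and a parallel "left ventricle" cylinder) embedded in
a perivascular fat sheath and myocardium, inside a polystyrene-packed
cylindrical container, acquired at 80/100/120/140 kVp under two
reconstruction regimes. The emulation is statistical, not physical:

- **Tissue model.** Each tissue has a mean HU per kVp, a Gaussian noise SD
  per regime, and an additive IR bias. There is no sinogram, beam
  hardening, scatter, streak texture, or spatial noise correlation.
- **Geometry.** Voxels take the tissue containing their center; no
  partial-volume mixing. Vessel-attached tissues are capsule shells around
  the centerline polyline clipped by the end planes, so a straight
  vessel's lumen is an exact voxelized cylinder and analytic volume checks
  apply. Geometry depends only on the spec — never on kVp, regime, or the
  noise stream — so all volumes of one spec are co-registered by
  construction.
- **Randomness.** One root seed per spec; the stream for each (kVp,
  regime) pair is derived as `default_rng([seed, kvp, regime_code])`, so
  adding a condition never perturbs the others, and identical inputs give
  bit-identical volumes.

### Default parameters

| parameter | default | note |
|---|---|---|
| fat mean at 120 kVp | −75 HU | emulation default, not a measured value |
| fat means at 80/100/140 | −75 × (1.267, 1.080, 0.947) | the averaged conversion factors as true ratios |
| lumen/LV contrast | +560/+465/+400/+355 HU at 80/100/120/140 | iodine HU falls with kVp |
| myocardium / container / polystyrene / air | +45 / +100 / −950 / −1000 HU | constant across kVp |
| soft-tissue noise SD | 24 HU (FBP-like), 15 HU (IR-like) | placeholder regime levels; the emulated scanners' true noise at each kVp/mAs is unknown |
| IR bias on fat | +3 HU | direction (IR > FBP) is the modeled finding; magnitude is a config default |
| position bias | 0 HU | optional uniform offset emulating off-isocenter placement, qualitative only |
| voxel grids | 0.5859 × 0.5859 × 0.6 mm³ (wide-detector preset), 0.5352 × 0.5352 × 0.625 mm³ (dual-source preset) | grid shapes 64×64×92 and 70×70×90 — large enough for the 40 mm vessel plus fat sheath and container, kept far below clinical 512³ matrices to make simulation batteries cheap |
| cohort variation | lumen radius 1.25–1.9 mm, in-plane curvature ≤ 2 mm, fat baseline −80…−70 HU | fat *ratios* across kVp are shared (a beam property, not a vessel property) |

Because the IR bias is additive while the factors are ratios, the true
IR-derived ratio at 80 kVp is (−95.025 + 3)/(−75 + 3) ≈ 1.278, about 0.9 %
above the configured fat-mean ratio 1.267 — exactly the convention of
deriving factors from IR data. Parameter-recovery results are read against
the configured ratios with this in mind.

What passing tests on this generator do **not** show about real data:
robustness to structured noise, beam hardening near the iodinated lumen,
partial-volume contamination at the fat boundary, motion, or manual
tracing variability.

## VOI construction

- "Radial distance from the artery equal to the vessel diameter" is
  resolved as: inner boundary at the vessel radius measured from the
  *centerline*, outer boundary at radius + diameter; the segmented lumen is
  additionally excluded. The inner offset is configurable
  (`inner_offset_mm`) for the lumen-surface convention.
- Membership is half-open: a voxel center at distance d is in the tube when
  `inner < d <= inner + diameter`. Distance to the polyline is the minimum
  over segments (capsule union); no spline smoothing. This voxel-center
  rule makes an exact per-voxel brute-force oracle possible, and the test
  suite holds the implementation to set equality against it.
- Centerlines are truncated at 40 mm arc length with an interpolated final
  point, mirroring the tracing protocol.
- Lumen segmentation is a threshold (+200 HU default) plus face-connected
  component through the traced points, restricted to a 5 mm cylinder around
  the centerline; failure raises the same "no measurable vessel" condition
  as a failed contrast filling.
- Diameter is the median across ≥ 10 arc-length stations of the
  area-equivalent diameter 2·√(area/π); each station's cross-section area
  is measured by trilinear sampling of the mask on a 2D grid in the plane
  normal to the local tangent (central-difference tangents), with the ≥ 0.5
  iso-level as the boundary. The median is robust to end effects and
  tapering.
- VOI transfer across volumes is index identity; it requires grids equal to
  within 10⁻⁶ mm (spacing/origin) and exact shape. Anything else is a
  registration problem, out of scope.

## Measurement

Adipose voxels are VOI voxels with HU in the **closed** interval
[−190, −30] (the boundary values count as adipose; the convention in the
fat-attenuation literature). The window is re-applied per volume after
transfer, so the adipose voxel set may differ across kVp even though the
VOI is fixed. HU values are used as stored. An empty adipose set raises —
the per-vessel feasibility accounting — rather than returning NaN.

One measurable consequence of windowing under noise: with a noisier
regime, more fat voxels spill past the −30 HU edge and are dropped,
pushing the regime's mean down. This widens the IR−FBP contrast at high
kVp beyond the configured +3 HU bias. It is a property of the windowed
mean, not an artifact of the implementation.

## Calibration uncertainties

The uncertainty attached to each factor is an interpretation (the exact
formula behind the emulated tables is not recoverable); three labelled
options are implemented:

- `propagation` (default): first-order delta-method SD of the ratio of
  across-vessel means, including the covariance between the numerator and
  the reference (vessels are paired).
- `sample`: sample SD of the per-vessel ratios.
- `bootstrap`: SD of the mean ratio over seeded vessel resamples.

For combining per-scanner tables there is no ambiguity: the SE-of-means
rule reproduces the combined row of the reference table to all printed
digits, so `average_tables` uses it. Factors are reported to 3 decimals
using decimal half-away-from-zero rounding (a binary-representation guard
keeps decimal ties like 1.2665 rounding up); full precision is retained
internally.

## Statistics

`rm_anova` is the one-way within-subjects decomposition computed from the
closed-form sums of squares (F = MS_treat/MS_error, df = (k−1, (n−1)(k−1)))
and `paired_t` the difference-score t statistic; both are cross-checked in
the test suite against statsmodels/scipy and a hand-computed small case.
Design choices, matching the study conventions:

- No sphericity correction by default; Greenhouse–Geisser is available
  behind a flag (epsilon cross-checked against pingouin).
- Post hoc p values reported raw; Bonferroni behind a flag, default off.
- Incomplete subjects dropped listwise, with a logged count.
- Zero error variance (exactly collinear responses, e.g. noise-free
  phantoms) is flagged degenerate and reported at the p = 0 boundary
  instead of crashing; a zero treatment effect reports F = 0, p = 1.
- The reconstruction comparison is run as separate per-regime ANOVAs plus
  per-kVp paired t tests (not a two-factor model): the two regimes are
  analysed as parallel measurement conditions of the same vessels.

## Pipeline and reproducibility

`run_pipeline` follows the study workflow: vessels are "traced" on the
120 kVp IR volume (the synthetic stand-in for manual tracing is the known
vessel path), the VOI is built there and transferred everywhere, factors
are estimated from IR data, measurements corrected, statistics run. All
CSVs are written with fixed float formatting, so a fixed seed reproduces
them byte for byte; a provenance JSON records config, seeds, versions and
a config hash. Volumes are written as int16 NIfTI-1 (scl_slope = 1) with a
JSON sidecar carrying kVp/regime (NIfTI has no such fields); DICOM series
input reads the KVP tag and rescale slope/intercept.

## Simulation batteries

- Factor recovery: 20 replicates × 6 vessels (fresh cohorts: new geometry,
  baselines, noise), IR datasets at all four kVp, full VOI pipeline. The
  mean recovered factor per kVp is compared to the configured ratios at
  1 %; each replicate also checks the monotone PCAT_MA-vs-kVp trend.
- IR vs FBP: one fixed cohort geometry re-scanned with fresh noise 100
  times; per re-scan, a paired t across the 6 vessels at 120 kVp. These
  sizes keep the full battery in a few minutes on one CPU while leaving
  the statistical conclusions unambiguous.

## Known limitations

- Noise is i.i.d. Gaussian per voxel; reconstruction regimes are (SD,
  bias) pairs. Real FBP/IR differences (texture, nonlinearity,
  kernel-dependent resolution) are not modeled, so the IR results say
  nothing about any specific vendor algorithm.
- The scalar-ratio correction is exact only if acquisition rescales fat
  attenuation multiplicatively; additive components (e.g. the IR bias)
  leave a sub-percent residual in the recovered factors.
- Per-position conversion factors are not modeled beyond the optional
  uniform position bias.
- Diameter estimation inherits the voxelization bias of the lumen mask
  (up to ~5–15 % area at coarse grids and unlucky lattice alignments);
  this only dilates the VOI slightly and does not touch the windowed mean
  on synthetic tissue.
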