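# Methods

## The measurement

Perivascular adipose tissue (PVAT) attenuation on CT is a marker of local
fat inflammation: inflamed fat is less lipid-rich and more oedematous, so
its Hounsfield-unit (HU) values drift upward within the adipose window.
`pvatscope` quantifies this around the stented aorta with a radial
gradient design.  From a binary aortic mask (lumen + wall) it computes the
Euclidean distance transform of the background — the distance, in physical
millimetres under anisotropic voxel spacing, from each voxel center to the
nearest mask-voxel center — and thresholds it into two concentric rings at
radial offsets 2–5 mm (proximal) and 10–12 mm (distal).  Within each ring,
adipose voxels are retained by the inclusive fat window −180 … −30 HU, and
two indices are derived from the ring means:

    HU_delta = HU_close − HU_distant
    HU_ratio = HU_close / HU_distant

High HU_delta (fat near the wall denser than fat further out) and low
HU_ratio mark an adverse perivascular profile.  The downstream question is
whether these indices predict a residual (still-perfused) false lumen
after thoracic endovascular repair (TEVAR) of type B aortic dissection.

### Conventions and numerical choices

- **Distance convention.** Ring membership is decided per voxel *center*
  against the nearest mask voxel *center*; there is no sub-voxel surface
  model and partial-volume effects are ignored.  This convention is
  reproducible and admits an exact brute-force oracle (verified on
  lattices up to 16³ in the test suite).  Note it shifts ring radii by up
  to half a voxel relative to a true surface-distance definition.
- **Interval inclusivity.** Both ring intervals are closed ([2, 5] and
  [10, 12] mm); the 5–10 mm gap is deliberately unassigned.  If a spec is
  constructed with touching intervals, the shared boundary belongs to the
  close ring.
- **Fat means are fat-only.** HU_close / HU_distant average the
  fat-filtered voxels, never the whole ring — non-adipose ring voxels
  (vessels, atelectasis, stent) do not contribute.
- **Thickness QC.** Subjects with under 0.3 cm of PVAT in either ring are
  unreliable to measure.  "Thickness" is not otherwise pinned down for an
  irregular annulus, so it is defined volumetrically: ring fat volume
  (mm³) divided by the outer surface area of the aortic mask (mm²),
  counted as exposed voxel faces weighted by face area.  Faces on the
  lattice boundary (e.g. the cut ends of a cropped volume) are not
  counted, since no fat can lie beyond the imaged volume there.  The
  threshold is ≥ 3.0 mm to pass; both thicknesses are recorded so users
  can re-filter.
- **Grid model.** Axis-aligned grids only; NIfTI affines with off-diagonal
  rotation above 10⁻³ (relative) are rejected rather than silently
  resampled.  HU are held as float64 even for integer-typed files so ring
  means are not quantised.  Alignment checks use a 10⁻⁴ mm spacing
  tolerance.
- **Analysis range.** The quantitative segment along the aorta is cropped
  by arc-length along a centerline taken as the polyline of per-slice mask
  centroids — a documented approximation standing in for dedicated
  centerline software; adequate for near-tubular masks, biased for
  strongly curved or branching ones.  Slices without mask voxels carry no
  arc-length coordinate and are dropped.  Whether rings should be
  restricted to a standardised anatomic range is not settled; the range is
  a parameter and defaults to the full mask extent.

## Synthetic data

No patient imaging or tabular data is distributed, so two generators
define the study conditions.

**Phantoms** (`pvatscope.phantom`) build a contrast-filled tube (lumen
≈ +300 HU, wall ≈ +40 HU) along a straight or helical centerline,
surrounded by two adipose shells (defaults −70 and −80 HU, inside the fat
window) embedded in soft tissue (≈ +20 HU), with optional additive
Gaussian HU noise.  The shells are painted using the *same* voxel-center
distance bands the quantification uses for its rings, which makes the
phantom an exact oracle: on a noiseless phantom the recovered ring means
equal the configured shell means to machine precision, and with noise σ
the recovery error shrinks as σ/√(voxel count).  What phantoms do *not*
emulate: dissection flap geometry, stent metal and streak artifacts, CT
texture, partial-volume blur.  Passing phantom tests therefore validates
the geometry and bookkeeping of the pipeline, not its robustness to
real-world artifacts.

**Cohorts** (`pvatscope.cohort`) draw per-patient covariates from the
published two-group summaries: 56 residual-false-lumen vs 76
closed-false-lumen patients; each continuous covariate is a truncated
Gaussian with the group's (mean, SD) and physiologic truncation bounds
(counts ≥ 0, HU_ratio ∈ (0, 2], …); categoricals are Bernoulli with the
group proportion.  Covariates are drawn *independently within group* — the
source tables report no covariance structure — so simulated cohorts
reproduce the marginal group separations but not any real between-covariate
correlation; selection-cascade results on them should be read as
calibration checks, not clinical replication.  Skewed labs (D-dimer) are
still simulated as truncated Gaussians because only mean ± SD is
available.  A separate marker-driven generator produces cohorts where the
outcome separates only HU_delta/HU_ratio and nuisance covariates are
correlated with HU_delta (ρ = 0.3) but carry no conditional signal; it
exercises the variable-selection cascade's ability to retain exactly the
true predictors.

Two quirks of the source tables are carried as-is rather than "fixed":
the stent-graft-material row's group columns are internally inconsistent
with the group sizes (counts 60/38 under n = 56/76; the printed column
percentages are used), and a table footnote describes HU_ratio as a
false/true-lumen attenuation ratio while the methods define it as
HU_close/HU_distant — this package follows the methods definition.

## Cohort statistics

- **Group comparisons.** Shapiro–Wilk per group at α = 0.05 (the gate's α
  is a package choice) routes each continuous covariate to Student's
  t-test or the Wilcoxon rank-sum test; binary covariates use the
  chi-squared test; all two-sided.  Constant covariates are flagged, not
  tested.
- **Pooled summaries.** The overall column is reproduced from per-group
  (n, mean, SD) by the sample-size-weighted mean and the law of total
  variance with ddof = 1 variances, which agrees exactly with summarising
  the concatenated raw samples.
- **Logistic cascade.** Univariate maximum-likelihood logistic fits per
  covariate; P < 0.05 advances.  Collinearity among the advancing set is
  screened with variance inflation factors (VIF = 1/(1−R²) from an OLS
  regression on the other covariates); the highest-VIF variable is dropped
  iteratively until all ≤ 10, with exact linear dependence (infinite VIF)
  removed first.  The multivariate model is a joint ML logistic fit with
  Wald 95% CIs (Newton iterations, log-likelihood tolerance 10⁻⁸, 100
  iteration cap).  Perfect or quasi-separation is detected (failed fit,
  non-convergence, or exploding standard errors) and flagged; such fits
  never advance silently.  No multiple-testing correction is applied
  anywhere, matching the screening character of the cascade.
- **ROC / Youden.** The empirical AUC equals the pairwise concordance
  probability with cross-class ties counted ½ (computed via the rank-sum
  identity, and identical to the trapezoidal area).  Candidate cut-points
  sit at midpoints between adjacent distinct scores plus open ends; among
  cut-points maximising Youden's J = sensitivity + specificity − 1, the
  one with the highest specificity is reported (neither convention is
  dictated by the source; both are package choices).  Markers where low
  values predict the event (HU_ratio) use `direction="lesser"`, with
  test-positive meaning score ≤ cutoff.  `binormal_auc` provides the
  closed-form Φ(Δμ/√(σ₁²+σ₂²)) bridge from two-group summaries to an AUC;
  from the published HU_delta summaries it gives 0.796, consistent with
  the published AUC of 0.79 — the package treats HU_delta as the primary
  bearer of that figure (its binormal value is the closer match) while
  reporting AUCs for both markers and the combined two-marker model.

## Visualization

Fat voxels are rendered slice by slice with a perceptually uniform
multi-hue colour-map (default `turbo`; configurable), colour scale fixed
to the fat window across all slices, a colour-bar, and the slice-mean fat
HU in the title; a CSV index carries per-slice mean and voxel count.
Static image export replaces an interactive slider by design.  The
Markdown report assembler is deterministic for identical inputs
(no timestamps) and marks absent stages instead of failing.

## Problem sizes and tolerances used in the checks

Phantoms are 80×80×40 voxels at 0.7×0.7×0.625 mm (shell populations
> 2×10⁴ voxels); noisy-recovery checks use σ = 10 HU over 50 seeds against
a 0.3 HU (≈ 3 SE) bound.  Replicated-cohort AUC uses 200 cohorts of
56 + 76; null calibration of the screen uses 500 cohorts × 6 noise
covariates; selection recovery uses 100 seeds with 4 nuisance covariates.
Brute-force distance oracles run on lattices ≤ 16³; exact identities
(pooled summary vs concatenation, AUC vs pairwise concordance, VIF closed
form) are asserted at 10⁻⁸–10⁻¹² after float rounding.

## Known limitations

- Centroid centerline, voxel-center distances and volumetric thickness are
  approximations; absolute ring statistics will shift slightly against
  tools using surface distances or anatomic centerlines.
- Simulated cohorts lack within-group covariate correlation and non-Gaussian
  lab distributions; power/type-I figures transfer to real data only to the
  extent those assumptions hold.
- Masks are consumed, never produced: segmentation quality is upstream of
  everything here.
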