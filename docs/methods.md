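# Methods

This note documents the models, parameters, and design choices behind
`marrowquant`, and what the synthetic-data tests do and do not establish
about behaviour on real scanner data.

## Signal model and ADC estimation

DWI signal is modelled mono-exponentially, S_b = S₀·exp(−b·ADC), with
b ∈ {0, 1000} s/mm², so the ADC map is ln(S₀/S₁₀₀₀)/1000 per voxel.  All
ADC values are carried in mm²/s throughout the library (1.0e-3, never the
display-scaled 1.0); only reporting layers print the ×10⁻³ convention.
Voxels with non-positive signal in either acquisition get ADC 0 (no
signal, never in the disease window), and negative estimates — signal
rising with b, pure noise — are clamped to 0.  Multi-b fitting and
computed (synthesized) b-values are not modelled.

## Lesion segmentation

The segmentation chain reproduces a semi-automated clinical workflow:

1. Coronal MIP of the b=1000 volume (maximum along the
   anterior–posterior axis; volumes are indexed superior–inferior ×
   left–right × anterior–posterior).
2. Min–max normalization of the MIP to a 0–255 scale, and background
   removal keeping pixels **strictly above 97**.  The original
   workstation's intensity scale is not knowable from the outside; 8-bit
   display scaling is the only scale on which a universal constant
   threshold is meaningful, so the value is applied on the normalized
   scale.  The threshold is a parameter (`background_threshold`) for
   scanners where 97 is inappropriate.
3. Otsu's discriminant threshold computed **on the surviving MIP pixels
   only** (background removed first).  Candidate thresholds are the
   histogram bin edges except the last; class 0 holds values ≤ t; the
   between-class variance ω₀ω₁(μ₀−μ₁)² is computed from exact class
   moments, and ties break to the lowest threshold.  256 bins by
   default.
4. The MIP-derived Otsu threshold is applied to the min–max-normalized
   3-D b=1000 volume, restricted to the coronal columns that survived
   background removal.  The source workflow thresholds a 2-D MIP yet
   extracts 3-D voxels; this column-transfer rule is this package's
   documented resolution of that ambiguity, since voxel-level ADC
   filtering requires a 3-D mask.
5. Non-skeletal high-signal structures (brain, bladder, bowel analogues)
   are removed by a user-supplied exclusion mask — the reproducible
   replacement for interactive manual editing.
6. T2 shine-through filter: keep voxels with ADC ≤ 2.0×10⁻³ mm²/s
   (inclusive).
7. tDV: surviving voxels with ADC > 0.55×10⁻³ mm²/s (strict).

Strictness conventions (background ">", shine-through "≤", tDV ">")
follow the workflow's wording exactly and are asserted by tests.  Each
stage's mask is a subset of the previous stage's; an empty tDV is
reported with a `no_lesion` flag rather than raised, because a marrow
study with no focal disease is a legitimate input.

## Per-patient indices

* tDV (ml) = voxel count × voxel volume (mm³) / 1000.
* Median ADC = exact sample median over tDV voxels (mean of the middle
  two for even counts); undefined when the tDV is empty.
* FF map (%) = 100·fat/in-phase, clipped to [0, 100] (noise can push the
  raw ratio outside the physical range); voxels with in-phase signal
  below 10⁻⁶ of its maximum are undefined (NaN).
* Mean FF = mean of the per-ROI means over all supplied rectangular
  midcoronal L1–L3 ROIs, with the number of ROIs used recorded.  Whether
  the clinical workflow averaged three vertebrae or used a single ROI is
  unclear from its description; averaging all supplied ROIs is the more
  general choice and degrades gracefully to one.  ROI areas outside the
  observed 270–485 mm² range warn rather than fail, since that range is
  an observation, not a rule.
* Mobilization class: poor iff total CD34⁺ yield < 4.0×10⁶ cells/kg.
  Equality is classed adequate: the defining inequality is strict on the
  poor side.
* ADC-based prediction: poor iff median ADC strictly exceeds the cutoff
  (default 1.18×10⁻³ mm²/s, the published ROC-derived value).

## Cohort statistics

* **Mann–Whitney U** (two-sided): exact null distribution when
  n₁+n₂ ≤ 20 with no ties, otherwise normal approximation with tie and
  continuity corrections (delegated to `scipy.stats.mannwhitneyu`; the
  test suite carries an independent full-enumeration oracle).
* **Fisher exact**: 2×2 via the probability-ordering two-sided rule;
  r×2 by full enumeration over tables with the observed margins under
  the multivariate hypergeometric null — feasible at clinical-cohort
  scale (tens of patients, ≤ ~6 categories).
* **Univariate screen**: numeric variables → Mann–Whitney, categorical →
  Fisher; constant variables are flagged with p = 1; variables with
  p < α (default 0.05) are selected.  No multiple-testing correction is
  applied, matching the screen-then-model convention of small
  exploratory cohorts.
* **Stepwise regression** (`StepwiseRegression`, sklearn-compatible):
  forward step adds the smallest-partial-p candidate if p < p_enter
  (default 0.05); backward step removes any retained predictor with
  p ≥ p_remove (default 0.10); iterate to a fixed point.  Those defaults
  are the conventional ones, configurable.  Collinear candidates
  (design condition number > 10⁸) are dropped with a warning.  The
  primary model is OLS on the continuous CD34⁺ yield; a logistic variant
  on the poor/adequate label is reported secondarily (small cohorts can
  quasi-separate, in which case the logistic stage records itself as
  skipped).  Confidence intervals are normal-approximation Wald bounds
  β ± 1.96·SE.  The M-protein category enters dichotomized as
  Bence-Jones-or-not.
* **ROC** (`roc_analysis`, `YoudenCutoffClassifier`): empirical curve
  over all distinct score cutoffs with "score > cutoff ⇒ predicted
  poor"; AUC by the trapezoidal rule, which equals U/(n₁n₂) with tied
  pairs counted ½ (asserted as an invariant); Youden cutoff = argmax of
  sensitivity + specificity − 1 with ties resolved to the lowest cutoff.
* **Binormal AUC**: Φ(|μ_p − μ_a|/√(σ_a² + σ_p²)) links the two
  group-wise ADC summaries to the expected discrimination — with the
  published group parameters this gives 0.786, consistent with the
  published empirical 0.784.
* `run_full_analysis` is complete-case: rows missing any analysed column
  are dropped with a recorded count, and at least two patients per class
  are required.

## Synthetic data

**Phantoms.**  A parametric skeleton (boxes/ellipsoids, mm coordinates)
holds marrow at ADC 0.4×10⁻³ mm²/s (fatty/normal marrow, deliberately
below the tDV window), FF 40%, and moderate DWI brightness (110 signal
units); spherical lesions carry prescribed ADC (default 1.0×10⁻³),
brightness 230, FF 5%; organ analogues outside the skeleton are brighter
still (240) and are covered by the ground-truth exclusion mask; air is
near-dark.  The b=0 volume is derived backwards through the signal
model, so with zero noise −ln(S₁₀₀₀/S₀)/1000 reconstructs the true ADC
to machine precision, and the b=1000 histogram is genuinely bimodal over
the foreground (marrow vs lesion/organ), which is the regime the Otsu
step assumes.  Gaussian noise (additive, clipped at 0) is optional, with
ADC then recomputed from the noisy signals as a scanner would.  Voxel
membership is by voxel-center inclusion.  This emulates the geometry and
contrast structure the workflow relies on — it does not emulate Rician
noise statistics, coil inhomogeneity, station stitching, distortion, or
partial-volume effects, so passing tests demonstrate correctness of the
algorithmic chain, not robustness to real scanner physics.

**Cohorts.**  Generation is group-conditional (class sizes fixed at
16 adequate / 22 poor by default, matching the study design), because
the published parameters are per-group.  Per-group draws:

* median ADC — normal (0.96 ± 0.24 vs 1.24 ± 0.26, ×10⁻³ mm²/s),
  truncated below at 0.1×10⁻³ to stay physical;
* tDV — gamma with the group mean/sd (95.3 ± 81.0 vs 57.8 ± 59.1 ml):
  non-negative support with exactly the published moments, and the
  right skew such sd≈mean burden markers imply;
* FF — scaled beta on [0, 100] with the group mean/sd (34.3 ± 23.1 vs
  45.6 ± 25.6%), again moment-exact on a physical support;
* M protein — categorical with Bence-Jones probability 0 in the adequate
  group and 7/22 in the poor group (the published 0/16 vs 7/22 split);
* clinical covariates — group-independent normals at the published
  whole-cohort summaries (they showed no group differences).

CD34⁺ yield follows a linear-with-floor link,
yield = max(0, a − b·ADC + ε): no quantitative ADC–yield relationship is
published, only monotonicity, so the simplest monotone model is used and
every parameter is configurable.  Defaults a = 9.9×10⁶ cells/kg,
b = 5.0×10⁹ cells/kg per mm²/s place the zero-noise crossing of the
4.0×10⁶ adequacy cutoff at ADC 1.18×10⁻³ mm²/s (the published ROC
cutoff) and reproduce the two published worked examples
(0.78×10⁻³ → adequate, 1.53×10⁻³ → poor); ε has sd 1.0×10⁶.  The noise
draw is rejection-sampled onto the group-consistent side of the cutoff
so that the class recorded from the yield always agrees with the sampled
group (otherwise label noise would contradict the group-conditional
marker draws, e.g. Bence-Jones patients leaking into the adequate
class).

Seeding is hierarchical (`SeedSequence.spawn`): one substream per
patient, so enlarging a cohort never changes earlier patients.

## Numerical choices and degenerate inputs

* Otsu on an all-equal sample returns that value (σ_b² ≡ 0); empty input
  is an error.
* A constant image normalizes to all zeros (no 0/0).
* Empty tDV → flagged, downstream median/prediction refuse with clear
  errors rather than emitting NaNs.
* Exact-test path switches (exact ↔ asymptotic) are decided by sample
  size and tie structure, never by the observed p.
* All simulation entry points take explicit seeds; pipeline runs are
  byte-reproducible, including NIfTI outputs.

## Problem sizes used in validation

Validation runs use sizes at which the relevant Monte-Carlo error is
well below the tested tolerances: 10,000 replicate cohorts for the mean
empirical AUC (MC standard error ≈ 0.0007), 1,000 random inputs for each
oracle-equivalence sweep, exhaustive enumeration for all exact-test
inputs with n ≤ 12, 2,000 label permutations for screen calibration
(binomial SE ≈ 0.005 at the 0.05 level), and 64³-voxel phantoms, at
which voxel discretization of a 10-mm sphere is ~2%, well inside the 10%
volume tolerance.

## Known limitations

* The 2-D→3-D Otsu transfer rule and the 0–255 normalization are
  documented reconstructions of an under-specified clinical workflow,
  not validated against the original vendor software.
* The ADC–yield link is a modelling device for synthesis and testing; it
  is not an estimate of any real dose–response relationship.
* Published regression coefficients from the source cohort are not
  reproducible without the underlying patient data; the statistical
  machinery is instead validated on synthetic cohorts with known truth
  and against enumeration oracles.
* No registration, bias-field correction, DICOM ingestion, or
  per-vertebra localization; ROIs are supplied as coordinates.
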