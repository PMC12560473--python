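# Methods

## Signal model and metrics

All three metrics operate on a single co-registered multi-b-value DWI
series in arbitrary signal units. No normalization is applied by default:
the signal-difference metrics (SDC, DDVD) are defined on raw intensities
and therefore inherit the scanner's intensity scale. This assumes
scanner-side intensity normalization (e.g. prescan-based coil
normalization); values are not comparable across scanners or receive
chains without it. An optional flag in the mapping layer divides all
volumes by the ROI-mean b=0 signal; it is clearly labelled as a variant
and is never the default.

- **SDC** `= [S(b₁) − S(b₂)]/(b₂ − b₁)`, defaults b₁=500, b₂=750 s/mm².
  By b = 500 the perfusion (pseudo-diffusion) compartment has decayed to
  numerical zero, so the difference quotient indexes the slow (tissue)
  diffusion pool. The conventional unit label is au/s (dimensionally the
  quantity is au·mm²/s, since b carries s/mm²; the field's label is kept).
- **DDVD** `= mean_ROI S(b=0) − mean_ROI S(b=10)` in au/pixel. Between
  b = 0 and a very low b, signal loss is dominated by flowing blood, so
  the per-pixel drop acts as a microvascular-perfusion surrogate. The
  pixelwise map is `S_b0 − S_b10`; because both volumes share one mask,
  the ROI scalar equals the ROI mean of the map exactly, which is tested
  as an identity.
- **ADC** `= ln(S(b₁)/S(b₂))/(b₂ − b₁)`, defaults 0/1000 s/mm², mm²/s.

Maps are computed whole-volume; the ROI enters only at aggregation. The
aggregation statistic is the mean of valid in-mask voxels: the DDVD scalar
is itself a ROI mean, and using one statistic keeps the three metrics
commensurate. Negative SDC/DDVD voxels (noise) are retained — clipping
would bias group means upward. ADC voxels with a non-positive signal are
NaN, excluded from aggregation, and counted per metric; a ROI whose voxels
are all invalid for a metric is an error, not a silent zero.

The per-lesion result is a `(SDC, DDVD, ADC)` triplet. ADC carries a
mandatory unit tag (`mm2/s` or `1e-4 mm2/s`): the genotype model consumes
ADC in 10⁻⁴ mm²/s and a silent factor-10⁴ error is the most likely misuse,
so conversion happens exactly once through the tag and mismatches are
refused.

## Genotype probability model

The reference logistic model
`p = 1/(1 + exp(−(8.941·SDC − 0.124·DDVD + 0.034·ADC − 1.229)))`
(SDC au/s, DDVD au/pixel, ADC 10⁻⁴ mm²/s) ships as an immutable named
instance (`glioma-idh-2025-reference`); refitting never overwrites it.
Refitting uses IRLS to the unpenalized maximum-likelihood solution
(statsmodels GLM/binomial; tolerance 1e-8 on the objective, at most 100
iterations). Complete separation is detected (all fitted probabilities
numerically saturated) and raised as an error instead of returning
divergent coefficients. The fit report carries per-coefficient standard
errors, convergence status and the in-sample AUC of the fitted
probabilities. A probability exactly at the classification threshold is
classified positive (documented tie rule). Partial-positive
immunohistochemistry cases form their own level (0.5) and are dropped —
never merged — when an analysis excludes them.

## Cohort statistics

- **Mann-Whitney U** (two-sided): exact enumeration of the permutation
  distribution of the midrank U for combined samples of at most 20 values
  (ties handled naturally by the enumeration); otherwise the tie-corrected
  normal approximation with continuity correction, matching common
  commercial-software behaviour. The continuity correction can be disabled;
  without it the k=2 Kruskal-Wallis p is identical to the Mann-Whitney
  normal p, an identity held to 1e-6 in the tests.
- **Kruskal-Wallis**: tie-corrected H with a chi-square reference (k−1 df).
  All-identical data across groups is H=0, p=1, not an error.
- **Pearson correlation**: r with a Fisher-z 95% interval and t-based
  p-value (n−2 df).
- **Inter-reader ICC**: two-way random effects, absolute agreement, single
  measurement (ICC(A,1)) from the two-way ANOVA decomposition, with the
  F-based McGraw-Wong interval (Satterthwaite degrees of freedom). This
  form is the standard choice for reliability of one continuous
  measurement per reader; the implementation is cross-checked against an
  independent library in the tests.
- No multiple-testing correction is applied anywhere.

## ROC and cutoff tables

The empirical ROC uses all distinct thresholds; AUC is the trapezoidal
area and equals the Mann-Whitney U/(n₁n₂) rank statistic (ties contribute
½) — verified against a brute-force pairwise oracle. The positive-class
orientation is an explicit flag (default: higher values ⇒ positive) and is
never auto-flipped. Cutoff tables use the strict "> threshold" rule;
candidate thresholds are the midpoints between consecutive distinct
observed values. Sensitivity and specificity are exact count fractions;
the positive likelihood ratio `sens/(1 − spec)` is computed on the exact
fractions before any display rounding (rounded-percentage inputs would
distort small-denominator rows). Specificity 1 yields an explicit
infinity.

Proportion intervals are Wilson score intervals. A hybrid variant applies
the Brown–Cai–DasGupta boundary modification: when the success or failure
count is at most 2, the near-boundary limit is replaced by the one-sided
Poisson bound `χ²(α; 2c)/(2n)` (or its mirror). This hybrid is what
widely-deployed commercial packages print for extreme rows such as 32/33
or 34/35; it differs from plain Wilson only there. The cutover at count 2
is pinned by the reproduced tables: a 3/33 failure row is plain Wilson,
a 1/33 row is not. AUC confidence intervals (DeLong) are provided for
completeness.

## Synthetic data

The generators define the test bed; their defaults are the study
conditions the analyses assume.

**Phantom.** Voxel signals follow the bi-exponential intravoxel-incoherent-
motion (IVIM) decay `S(b) = S0·[f·e^(−b·D*) + (1−f)·e^(−b·D_t)]` with
Rician noise (magnitude reconstruction of complex Gaussian noise, scale
S0/snr); Gaussian noise is available for analytic checks, and snr=∞ gives
the noiseless closed form used as an oracle. The default phantom is
32×32×8 voxels with three regions — normal background (S0=800, f=0.05,
D*=20e-3, D_t=0.8e-3 mm²/s), a "wildtype-like" insert (S0=1000, f=0.18,
D*=50e-3, D_t=0.7e-3: hypervascular and densely cellular) and a
"mutant-like" insert (S0=1000, f=0.06, D*=50e-3, D_t=1.1e-3) — so that the
inserts separate in the clinically observed directions (wildtype-like:
lower SDC, higher DDVD, lower ADC). These tissue parameters are
illustrative values on the physiological scale, not measurements of glioma
tissue. The phantom does not model scanner artifacts, motion,
susceptibility distortion, coil inhomogeneity or T2/TE-dependent decay;
passing phantom tests therefore demonstrates correctness of the metric
arithmetic and noise behaviour, not robustness to real-acquisition
confounds.

**Cohort.** Per-group metric triplets are multivariate normal on the
reporting scale, truncated at zero for SDC and ADC (a mean ± SD and median
summary is equally consistent with many shapes; the normal is the simplest
choice). Calibrated values: SDC 0.339 ± 0.055 au/s for 33 IDH-wildtype vs
0.437 ± 0.097 au/s for 30 IDH-mutant subjects; between-metric correlations
r(SDC,ADC) = +0.705, r(SDC,DDVD) = −0.212, with the unreported DDVD–ADC
correlation defaulting to 0 and the matrix projected to the nearest
positive-definite correlation if a user configuration requires it. DDVD
and ADC group means/SDs are not published at the group level; the defaults
(DDVD 40 ± 14 vs 28 ± 11 au/pixel; ADC 8.5 ± 1.6 vs 11.5 ± 2.4 ×10⁻⁴
mm²/s) are realistic tissue-scale values with the observed directions
(wildtype: higher perfusion surrogate, lower ADC). Ki-67 labeling index is
generated within each group as a linear function of the pre-truncation SDC
z-score plus independent noise, with within-group correlation −0.382,
clamped to [0, 100] % (clamping slightly attenuates the realized
magnitude, which the tests acknowledge with a band rather than equality).
Grade and three-level IHC labels are drawn categorically with the cohort's
composition (grades 19/6/33 plus 5 ungraded NEC; IHC 35 negative / 13
partial / 15 positive overall).

A grade-stratified variant generates SDC at the grade medians 0.472 /
0.441 / 0.364 au/s for n = 19/6/33. Within-grade SDs are 0.060 / 0.060 /
0.055: each grade stratum is more homogeneous than the pooled mutant
group, whose 0.097 spread spans grades; with these values the grade
contrast reproduces the expected strongly significant Kruskal-Wallis
trend in the large majority of replicate cohorts.

All generators are deterministic for a fixed seed (byte-identical
output).

## Problem sizes and numerical choices

Replicate-based checks use 1000 cohort replicates for the
separation-performance average and 200 replicates for the grade-trend
calibration; parameter-recovery checks use n = 5000 subjects for the
logistic refit and n = 10⁵ for generator moment recovery — sizes at which
the relevant standard errors are comfortably below the tolerances being
asserted. Exact Mann-Whitney enumeration is bounded at a combined n of 20
(C(20,10) ≈ 1.8×10⁵ assignments). Scale-covariance identities are asserted
bitwise with dyadic scale factors and at 1e-12 relative tolerance
otherwise, since floating-point multiplication is only exactly
distributive for powers of two.

## Known limitations

- Signal-difference metrics are intensity-scale dependent; cross-scanner
  comparability requires consistent scanner-side normalization.
- The reference coefficients were estimated on a single-center cohort of
  63 subjects; refitting is recommended for any new acquisition protocol.
- The synthetic cohort encodes distributional calibration targets, not
  patient-level structure (no lesion heterogeneity, no reader variance in
  the cohort table unless a second-reader column is supplied).
- No IVIM bi-exponential fitting, kurtosis modelling, or volumetric
  histogram/radiomic features: the design point is the minimal four-b
  acquisition.
- No registration or resampling: inputs must already share one voxel grid,
  and mismatches are rejected rather than corrected.
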