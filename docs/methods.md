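# Methods

## The analysis this package implements

`exopanel` models the discovery and evaluation of a small circulating
biomarker panel (plasma exosomal lncRNAs measured by qPCR) for separating
hepatocellular carcinoma (HCC) patients from chronic hepatitis (CH) patients
and healthy controls (NC), and metastatic (HCC-M) from non-metastatic
(HCC-N) disease. The design is multiphase: a small pilot screen, a Venn
intersection of per-contrast candidate lists, a training-set confirmation and
risk-model fit, a large validation set evaluated with the frozen model, and a
double-blind set classified before labels are consulted.

## Relative quantification

Expression is quantified by the comparative-Ct method against an exogenous
spike-in reference added to every sample:

* dCt[j,i] = Ct[j,i] − Ct[ref,i] — removes per-sample technical scale;
* ddCt[j,i] = dCt[j,i] − mean dCt[j, baseline samples], baseline = NC;
* relative expression = 2^−ddCt, so one cycle equals a two-fold change and
  the baseline group's per-marker geometric mean is exactly 1.

The baseline statistic is the arithmetic mean of dCt over baseline samples.
Because every downstream decision (t tests on log2 expression, fold changes,
threshold coding) is invariant to a per-marker multiplicative constant, the
choice of which NC samples enter the baseline mean does not affect
classifications; it only fixes the display scale.

**Nondetects.** Ct values at or above the quantification limit (35 cycles by
default) are censored. For dCt computation they are imputed *at the limit* —
the lowest expression consistent with the observation — and the censoring
flag is carried on every container so downstream summaries report the
censored counts they consumed. A censored cell always codes 0 in the risk
score (undetectable implies below any positive threshold). The
detection-rate filter in the screen is the guard against markers so heavily
censored that limit-imputation would distort inference. No model-based
imputation (e.g. censored-likelihood fits) is attempted.

## Screening filters and candidate selection

Per ordered contrast (NC→CH, CH→HCC-N, HCC-N→HCC-M), a marker passes when:

1. two-sample Student t test on log2 relative expression, p < 0.05
   (two-sided; direction is filtered separately);
2. up-regulated: positive log2 fold change (high group over low group);
3. mean raw Ct in the higher-expression group < 35 — the marker must be
   measurable where a biomarker needs to be measurable;
4. detection rate > 75% in **both** compared groups (the strictest reading;
   prevents one-sided censoring artifacts).

No multiple-testing correction is applied by default, mirroring the raw
p < .05 convention of the fingerprint-study tradition; Benjamini–Hochberg is
available (`multitest="fdr_bh"`). No fold-change magnitude filter is applied
by default (`min_abs_log2_fc` is exposed). Candidates are the three-way set
intersection of the per-contrast pass lists (markers informative for both
tumorigenesis and metastasis), ranked by the sum of −log10 p. Confirmation
re-tests panel markers in the training split with the same test; the
confirmed panel keeps markers confirmed in *all* screening contrasts,
consistent with the intersection logic.

**Pilot-screen power.** At the design's pilot size (3 samples/group) a
two-sample t test at α=0.05 has noncentral-t power ≈0.16 for a 1-SD shift,
so the three-way intersection retains such a marker with probability ≈4e-3.
A funnel with these filters at this pilot size recovers moderate-effect
markers only when effects are several SD, or when the screen is run on a
larger split; the pipeline therefore logs the complete filter funnel
(assays in, passing each filter, passing all) so users can audit exactly
where candidates die. This is an inherent property of the design being
modeled, not an implementation artifact.

## Risk-score model

For a fitted panel of J markers:

* θ_j = upper limit of the controls' 95% reference interval: the one-sided
  95th percentile of control relative expression, nonparametric with the
  linear-interpolation quantile convention (sample maximum at p=1). A
  parametric alternative exp(mean + 1.645·SD) on the log scale is available.
* s_ij = 1 if expr_ij > θ_j (strict), else 0; censored cells code 0.
* rsf_i = Σ_j W_j·s_ij. Default weights W_j = 1, making the score the count
  of positive markers — the standard construction in this family of
  fingerprint studies, where weights are named but never derived;
  |log2 fold change| weights are available by configuration.
* Cut-off c: on the training samples, scan the midpoints between adjacent
  distinct scores plus ±∞ and keep the candidate maximising
  sensitivity + specificity (classification rule rsf ≥ c → high risk). Ties
  break toward higher specificity, then smaller c, making the rule
  deterministic and order-invariant. A median-score cut-off is available by
  configuration for comparison with that older convention.
* AFP is optionally appended as a (J+1)-th coded marker: dichotomized at the
  controls' 95th AFP percentile, weight 1. The AFP-extended score has its
  own training cut-off. Single-marker and AFP-alone ROC variants use the
  continuous values directly as scores.

One `RiskModel` is fitted per diagnostic comparison (HCC vs NC, HCC vs CH,
HCC-M vs HCC-N) because the cut-off depends on the comparison; θ and W are
functions of the training controls only and thus shared by construction.
Models are frozen dataclasses carrying the fitting sample ids; evaluation on
any other split verifies the model is frozen and shares no samples with the
evaluation set (a `LeakageError` otherwise), so validation and blind phases
can never silently re-estimate θ, W or c.

**Threshold calibration is an in-sample statement.** By construction the
coding rate of the fitting controls is 5%; on *fresh* controls the rate has
extra variance from the sampling noise of the estimated percentile
(SD ≈ √(p(1−p)/n·(1+n/n_fit)) rather than the binomial √(p(1−p)/n)). The
calibration tests assert the in-sample property; users applying θ to new
cohorts should expect the wider band.

## ROC and evaluation

AUC is the Mann–Whitney statistic P(score_pos > score_neg) + ½P(tie). Curves
are built from the distinct observed thresholds without smoothing — a coded
J-marker score takes at most J+1 values and its honest ROC is a short
polyline. The area is computed by the trapezoidal rule on exact integer
TP/FP counts with a single final division, so it equals pair counting to the
last bit (tested exhaustively on small instances, and cross-checked against
scikit-learn on continuous scores). Scores are never direction-flipped: a
variant that ranks cases below controls reports its sub-0.5 AUC as-is.
Confusion summaries (sensitivity, specificity, PPV, NPV, accuracy) are
reported at the frozen training cut-off for the coded variants only;
confidence intervals are not attached by default.

Stability across specimen-handling conditions (time at room temperature,
freeze–thaw cycles) is assessed per marker by two-sided paired t tests on
log2 expression against the baseline condition, jointly with the worst-case
mean |log2 ratio|, because absence of significance alone is weak evidence of
equivalence. A marker is flagged stable when no condition is significant at
α=0.05; with k comparison conditions the null rate of that flag is 0.95^k,
while the per-condition non-significance rate is exactly 95%. Identical
replicates (all paired differences zero) report p=1 and ratio 0.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions every
simulation-based check runs under.

* Four ordered groups NC < CH < HCC-N < HCC-M; fixed splits of 3 / 20 / 180
  samples per group (screen / train / valid) plus 100 blind samples spread
  evenly across groups, mirroring the multiphase design.
* Expression acts through dCt: planted markers' mean dCt decreases by
  `delta_dct_per_stage` (default 1.0 Ct) per disease stage with constant
  within-group SD `sigma_dct` (default 1.0 Ct); null markers share one
  group-independent dCt distribution at mean 12 (marker Ct ≈ 32 given the
  reference, keeping the Ct-35 censoring mechanism live but rare). Effects
  shift location only, matching the 2^−ddCt analysis scale.
* The spike-in reference is exogenous: Ct ~ N(20, 0.25²), independent of
  group, never censored.
* Nondetection is right-censoring of the simulated Ct at the limit — a
  single mechanism whose marginal rate is provably monotone in the limit —
  not an independent dropout process.
* AFP is log-normal with group log-means (2.0, 2.3, 2.6, 2.9) and log-SD
  1.8, chosen so AFP alone achieves a mediocre HCC-vs-NC AUC (~0.62,
  binormal closed form Φ(Δμ/(σ√2))), consistent with AFP's known
  low-specificity profile; medians run ≈7→18 ng/mL across groups.
* One `numpy` Generator seeded from the config drives all draws in a fixed
  order, so equal seeds give byte-identical cohorts.

The source study reports no effect sizes or variances for its validated
markers (figures are log-scale means), so these defaults are exercised by
the tests, not claimed as estimates of the study's effects.

**What the generator does not emulate:** microarray probe-level intensities,
amplification-efficiency differences, batch effects between phases, RNA
degradation kinetics, correlated markers (null markers are independent), or
nondetects from amplification failure unrelated to abundance. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the stated model, not clinical performance on real plasma.

## Problem sizes used by the checks

Calibration checks use 1,000 markers × 20 seeds (null screen), 20 markers ×
1,000 controls (threshold coding), 2,000/group (binormal AUC), 10,000
samples (score identities), and 50-seed end-to-end runs at the full design
sizes — sizes chosen so binomial/Monte-Carlo error bands are decisively
narrower than the tolerances being asserted.

## Known limitations

* Limit-imputation biases fold changes toward zero for heavily censored
  markers; the detection-rate filter bounds, but does not remove, this.
* The coded score discards within-marker gradation; with very strong effects
  a single continuous marker can out-rank the coded panel on AUC.
* Thresholds, weights and cut-offs transfer across cohorts only insofar as
  the normalization (spike-in and baseline convention) transfers; no
  recalibration machinery is provided, by design.
* Equal-variance Student t tests are used throughout, matching the
  tradition being modeled; Welch corrections are not exposed.
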