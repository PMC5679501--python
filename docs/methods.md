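# Methods

This note documents the statistical model behind `mirpair`, the
parameter defaults and why they were chosen, the numerical conventions,
and the limits of what the synthetic cohorts can demonstrate.

## The pair statistic

qRT-PCR reports a cycle threshold Ct, a negative log2 measure of
concentration: one cycle ≈ one two-fold dilution.  For two miRNAs
measured in the same preparation, ΔCt = Ct_num − Ct_den estimates the
log2 concentration ratio, and preparation-level nuisances (RNA yield,
extraction efficiency, global instrument drift) cancel because they add
the same offset to both Ct values.  For display the ratio is expressed
as 2^(−ΔCt) × 100 and plotted on a log10 axis; a k-fold concentration
change corresponds to a −log2(k) Ct shift (8-fold → −3 Ct).

Each candidate pair is evaluated as a one-dimensional classifier:

- **Orientation.** The ratio and its reciprocal carry identical
  information (same p value, mirrored ROC), so each unordered pair is
  oriented so the ratio is larger in the case group.  Orientation is
  chosen by rank AUC (flip when AUC < 0.5), which guarantees the oriented
  AUC equals max(a, 1−a); an exact AUC tie falls back to comparing class
  medians, and a further tie keeps the lexicographic input orientation.
- **Rank AUC.** U/(n₁n₂) with half credit for ties — identical to the
  trapezoidal area under the empirical ROC and to the Mann-Whitney win
  probability.  The unit tests pin it against a brute-force O(n₁n₂)
  count and against an independent library implementation.
- **Mann-Whitney p.** Two-sided; exact by enumeration for tie-free
  problems with n₁n₂ ≤ 400, otherwise the normal approximation with tie
  and continuity corrections.
- **Best-accuracy cutoff.** All midpoints between adjacent sorted unique
  values (plus ±∞) are scanned; a sample is called a case when its value
  meets the cutoff (inclusive).  Accuracy ties are broken toward the
  larger Youden J, then toward the lowest cutoff, so the reported
  sensitivity/specificity are deterministic.  Cutoffs are reported on the
  ΔCt scale (case ⇔ ΔCt ≤ cutoff).

## Multiplicity

With 37 miRNAs there are 666 pairs and the naive Bonferroni threshold is
0.05/666 = 7.5×10⁻⁵.  Because pairs share miRNAs and the panel is
deliberately built from correlated, co-expressed species, the family of
tests is far from independent.  The implemented reduction clusters miRNA
Ct profiles by single linkage at Spearman ρ ≥ 0.8 (pairwise-complete
observations, computed across all loaded samples); with c clusters the
effective family size is c(c−1)/2 and the threshold becomes
0.05/(c(c−1)/2).  Constant profiles are excluded with a warning, and a
degenerate collapse to one cluster falls back to the nominal count
rather than dividing by zero.  Whether the reduction should be computed
once globally or per comparison is genuinely open; both scopes are
exposed (`multiplicity_scope`), with "global" the default.  Both the AUC
gate and the p gate are applied at selection; the p gate can be disabled
for descriptive screens.

Under the default synthetic study conditions (below) the 37-miRNA panel
collapses to 18 clusters → 153 effective pairs → threshold 3.3×10⁻⁴,
i.e. the "about 160" regime of a highly correlated panel.

## Classifiers

Selected pairs are combined by logistic regression on their oriented
−ΔCt scores — a linear model with no interaction or polynomial terms.
Forward selection starts from the highest-AUC pair and at each step adds
the candidate that maximizes the refitted training AUC, stopping at
`max_pairs` (default 3, matching the typical reported classifier size)
or when the gain falls below `min_gain` = 0.005 AUC; the stopping rule is
a package choice since only the model family is prescribed.  A
likelihood-ratio entry criterion (enter while p < 0.05) is available as
`criterion="lrt"` but is not the default.  Perfect separation or a
degenerate design (e.g. duplicated features) is detected as a perfectly
classified training set with vanishing log loss and handled by refitting
with a mild ridge penalty (strength 10⁻⁴) and flagging the fit, rather
than failing.  Metrics are the AUC of fitted probabilities plus
sensitivity/specificity/accuracy at the best-accuracy probability cutoff
(same tie rules as for pairs); acceptance gates are inclusive (≥).

Overfitting is probed with a bagged random forest: each tree is grown on
a bootstrap resample and the out-of-bag AUC is compared with the
in-sample AUC.  Tree ensembles interpolate their training data, so the
in-sample AUC is essentially 1 and the flag effectively keys on the OOB
AUC; the gap threshold is 0.10 AUC, a package default since no criterion
is prescribed.

## Covariates and strata

ΔCt is regressed by OLS on a diagnosis indicator plus one covariate (age
in years, or a female indicator), additive with no interaction; the two
coefficients and their p values are reported so discrimination driven by
demographic imbalance can be recognized.  Age adjustment fits the linear
age trend in a reference group (centred at its mean age) and subtracts
it from every sample; reference residuals are exactly age-uncorrelated
and the operation is idempotent.  Samples without an age cannot be
adjusted and become missing, with a warning.

Stratified analysis reruns the whole pair-selection + classifier
pipeline independently for all/male/female, each sex compared with its
sex-matched controls; strata under 5 cases or 5 controls are skipped
with a warning.  Within-group sex contrasts treat M vs F inside one
diagnosis group as the two classes of the same generic pipeline —
subgroup analyses reuse this path with subgroup labels, with no bespoke
code.

## Cohort handling

- **Replicates.** The RT step is performed in triplicate; the per-sample
  value is the median of the available replicates (robust to single
  dropouts; the summary rule is a package choice).  Aggregation is
  invariant to replicate order.
- **Detection limit.** Ct > 37 (strictly greater) becomes missing;
  masking is idempotent.  A pair is analyzable for a comparison only if
  ≥ 70% of each class has complete values.
- **QC.** Ubiquitous miR-16 and miR-27a are measured in every
  preparation; a sample passes iff both lie within mean ± 2 SD
  (inclusive) of the batch statistics, which are computed over all
  loaded samples of the batch before any exclusion, non-iteratively.  A
  batch is one input file unless a batch column says otherwise.  An
  optional per-batch affine Ct recalibration against a reference batch
  (slope/intercept from shared controls) is intentionally not applied by
  default.
- **Splitting.** Within each group and sex, samples are sorted by age
  and age-adjacent pairs are split one-to-each-side at random; leftover
  singletons alternate starting with training.  This guarantees each
  half matches the other in sex counts (±1) and age profile, and group
  halves differ by at most one sample (training gets the extra).

## The synthetic cohort model

Latent concentrations are log-normal, i.e. Gaussian on the Ct scale —
consistent with qPCR chemistry and the 2^(−ΔCt) transform.  Per sample,
latent Ct = baseline + correlated Gaussian noise + group/sex-restricted
shifts + optional age trends; triplicate replicates add independent
technical noise; replicate values above the detection limit are masked
(masking only, mirroring the analysis exclusion rule — not truncation);
QC-outlier preparations (rate 2%) receive a global +4 Ct offset on every
miRNA, emulating a failed extraction that the QC rule should catch.
Spearman targets for correlated blocks are converted to latent Pearson
correlations via the Gaussian copula relation ρ_P = 2 sin(πρ_S/6), and
the implied correlation matrix must pass a Cholesky check.

Ground truth is closed-form: a pair with case-minus-control mean shift d
and per-group ΔCt standard deviation σ has theoretical AUC Φ(d/(σ√2)).
The effective per-miRNA SD accounts for replicate aggregation
(median-of-3 variance ≈ 0.449 σ_rep²), and pair σ accounts for
within-block correlation.

**Defaults (the emulated study conditions).** 37-miRNA brain-enriched
panel; five groups of 50 (control, AD, PD, FTD, ALS) with the published
cohort's sex ratios and age distributions; between-sample SD 1.2 Ct
(midpoint of the printed QC-miRNA SDs, 1.40 and 1.01 — the true
between-sample spread is not published, so this is a flagged
assumption); replicate SD 0.25 Ct; detection limit 37.  Effects: 2–3
plasma-elevated miRNAs per disease at −1.4 to −2.4 Ct, the 8-fold
(−3 Ct) muscle-enriched miR-206 elevation in ALS, and one
female-restricted ALS effect to exercise the stratified analysis.
Correlation blocks (sizes 5+4+4+4+4+4 at Spearman 0.85) cover only
effect-free background miRNAs — a group shift on one block member would
dilute the pooled-sample correlation below the linkage threshold — and
produce the ~160-effective-pair regime of a highly correlated panel.

**What the generator does not emulate:** batch chemistry drift between
training and confirmation runs, hemolysis and other pre-analytic
artifacts, heavy-tailed or skewed Ct distributions, disease-subtype
mixtures within a group, and missingness that is informative beyond the
detection limit.  Passing simulation suites therefore demonstrate that
the pipeline recovers known structure under its own model assumptions —
not that any specific clinical pair or accuracy would replicate.

## Problem sizes and numerical conventions

Simulation suites are sized for reproducibility at interactive scale:
null calibration uses 500 zero-effect cohorts of 50+50 samples (tests)
or 200 (acceptance script); AUC recovery uses 200 cohorts per target
with a 3×(Hanley-McNeil SE) band; stepwise combination uses 40–50
cohorts against a numerical-integration oracle with a ±0.03 tolerance;
sex-dilution uses 200 cohorts.  Large simulation loops use an
axis-vectorized asymptotic Mann-Whitney path whose agreement with the
scalar operation is pinned by a unit test.  All sub-seeds are spawned
from a single master seed (kept below 2³¹), and a pipeline rerun with
the same seed reproduces every output file byte for byte.  p values are
clipped into (0, 1]; AUC ties carry exactly ½ credit; all gates are
inclusive on their stated side.
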