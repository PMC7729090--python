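# Methods

## The promoter-vs-other-regions score

Illumina 450K probes are assigned to genes and to region categories from the
`UCSC_RefGene_Group` vocabulary. Categories TSS1500, TSS200, 5'UTR and
1stExon are treated as "promoter"; Body and 3'UTR as "other". The platform
annotation never defines "promoter" beyond these tags, so the partition is a
package choice and is exposed as the `promoter_tags` parameter of
`build_gene_probe_groups`. Probes annotated to several genes contribute to
each of them, under the region tag they carry for that gene (the 450K
manifest is many-to-many); if a probe is promoter-annotated for a gene it is
never simultaneously counted as that gene's "other" probe. Gene symbols are
matched case-sensitively after whitespace trimming, with no alias
resolution.

For each gene, within each sample, the score is the pooled-variance
two-sample t-statistic of promoter vs other-region beta values, with
unbiased (n−1) sample variances; its null reference is t(m+n−2). The raw
t-value is the carried quantity — converting to p-values per sample would
discard the sign and magnitude structure the downstream analyses use.

Numerical conventions:

* groups with fewer than 2 usable values give a missing score (NaN);
* zero pooled variance with equal means gives 0; with unequal means, signed
  infinity (keeps downstream rankings well defined, and is logged);
* probes missing in a sample are dropped before computing that sample's
  means and variances, so m and n are effectively per-sample; the realised
  degrees of freedom are stored per (gene, sample) in `df_used`. The
  ≥5/≥5 eligibility filter, in contrast, is applied once on manifest-level
  counts, so a gene's eligibility does not flicker with missingness.

## Association testing

* **Age contrast.** Samples are split at 50 years — strictly greater than 50
  is "old", 50 or younger "middle" (a sample aged exactly 50 is middle).
  Per gene, a two-sample t-test compares scores between the groups; Welch's
  unequal-variance form is the default because per-gene score variances have
  no reason to match across age groups, with the pooled Student form
  available (`variant="student"`).
* **Cell proportions.** Per gene, Pearson or Spearman correlation of scores
  against one of the six whole-blood proportions (CD8T, CD4T, monocyte,
  granulocyte, NK, B) or the summed CD8T+CD4T composite. Spearman uses
  average ranks for ties; its p-value comes from the usual t-approximation
  for n>10 and from exact enumeration of all n! pairings for n≤10.
* **Adjustment.** Benjamini–Hochberg step-up by default, Bonferroni and
  "none" available. q ≤ 0.05 is the default significance threshold for
  declaring a gene associated; it is a parameter, not a constant.
* **Ranked-list intersection** takes the top-N (default 10) gene symbols of
  two significance-sorted result lists and intersects them — the mechanism
  for nominating genes tied to both aging and immune composition.
* **Enrichment** is a one-sided upper-tail hypergeometric test of a hit set
  against a user-supplied gene set within a stated universe; no web
  resources are queried.

## Survival analysis

Samples are split at the per-gene median score: strictly above the median is
"high", at or below is "low" (the top-50%/bottom-50% description leaves ties
unassigned; sending ties low is deterministic, and a seeded random tie rule
is available). Kaplan–Meier curves and the two-group log-rank test are
delegated to lifelines. The univariate Cox fit is a package-native
Newton–Raphson on the partial likelihood supporting both the Breslow
(default) and Efron tie conventions — keeping the tie convention explicit —
and is cross-checked against lifelines (whose fitter uses Efron ties) in the
test suite. The default Cox covariate is the continuous score — a hazard
ratio of that size reads "per unit of score" — with a median-split binary
mode available, since the two parameterisations answer slightly different
questions. Wald 95% intervals are reported on the hazard-ratio scale;
p < 0.05 is the conventional significance line.

## The amplicon classifier

EpiTyper-style input: samples × CpG-unit methylation fractions, with sex
(male=1/female=0), outcome (CRC=0/normal=1, the clinical coding) and pTNM
stage. Units not effectively detected in a sample are missing; model-input
samples must be complete cases across all units (the reader only *flags*
incompleteness — deciding which units are "effectively detected" is upstream
of this package).

Per-unit two-sample t-tests compare controls against stage-I/II cases or
stage-III cases, optionally within sex strata, reporting the signed
case-minus-control difference so a methylation *decrease* in cancer is
directly checkable.

The prediction model is unpenalised logistic regression on unit fractions
plus sex. Backward stepwise selection starts from the full model and removes
one feature at a time; the default criterion is AIC (remove the feature
whose removal lowers AIC most, stop when none does), with a Wald-p rule
(remove the largest p > 0.05) as an alternative, and lexicographic feature
ids as the tie-break so selection is order-invariant. Selection is performed
once on the full dataset and the selected model is then assessed by
leave-one-out cross-validation — the conventional ordering, which is
optimistic because the left-out sample influenced selection; a nested mode
(`selection="nested"`) repeats selection inside every fold for an honest
estimate, and the report carries both the LOOCV AUC and the apparent
(refit-on-all-data) AUC so the optimism is visible.

AUC uses the Mann–Whitney formulation (ties counted ½), identical to
trapezoidal integration of the full ROC. The operating threshold maximises
Youden's J on the LOOCV ROC by default (smallest threshold on ties; a fixed
threshold is available); sensitivity and specificity treat cancer as the
positive class, scored by risk = 1 − P(normal). The diagnostic odds ratio is
(TP·TN)/(FP·FN) with Haldane's +0.5 on all cells whenever any cell is zero.

## The synthetic cohorts

The generator exists so every stage is testable offline; its defaults are
the study designs the pipeline targets.

* **Array cohort** (default 656 samples, ages uniform on 19–101): per gene,
  promoter probes draw around a hypomethylated logit-mean (−1.6 ± 0.4) and
  other-region probes around a methylated one (+0.9 ± 0.4), each probe with
  its own offset (SD 0.5) and logit-normal per-value noise (SD 0.35;
  a truncated-Gaussian mode exists for analytic convenience). Cell
  proportions are Dirichlet draws around whole-blood composition
  (granulocytes ≈ 0.55, CD4T ≈ 0.15, …) with concentration 80, a seventh
  component absorbing the remainder so the six proportions sum to ≤1.
  Age effects add `slope × (age − mean age)` beta units to promoter probes
  (default study slope 0.002/year). Cell effects are specified as a *target
  correlation* between the gene's score and the proportion; because the
  t-score carries noise the planted shift does not control (chiefly the
  pooled-SD estimate fluctuating against the large promoter-vs-body baseline
  difference), the generator deflates those known channels by the delta
  method and plants a correspondingly larger latent correlation, so the
  target is hit on the score scale rather than attenuated by construction.
  Values are clipped to [0,1]; a clip fraction above 1% is logged.
* **Survival** (default design 60% events): exponential event times with
  hazard ∝ exp(log-HR × standardised score) on a 1000-day baseline scale,
  with independent exponential censoring whose rate is matched to the
  requested censored fraction via the mean hazard (approximate, accurate to
  a few percent at moderate hazard spread).
* **Amplicon cohort** (default 100 cases / 50 controls, 15 units): control
  unit means uniform on 0.35–0.75, Gaussian noise SD 0.08, case shifts per
  unit with a per-unit male multiplier (`sex_modulation`) so sex-specific
  effects are expressible; stages I/II vs III assigned 53:47; sex
  frequencies mirror the clinical design (cases two-thirds male, controls
  one-third); missingness completely at random. `unit_shifts_for_auc` sizes
  equal shifts on k units for a chosen Bayes-optimal population AUC via
  d' = √k·|δ|/σ and AUC = Φ(d'/√2).

One integer seed fans out to per-stage child streams through
`numpy.random.SeedSequence`, so identical configs are byte-identical and any
stage can be regenerated independently. Every planted effect is recorded in
a truth table; recovery tests consume the truth table only.

What the generator does **not** emulate: probe-probe spatial correlation,
batch and bead-chip effects, cell-composition confounding of individual
probes, non-exponential hazards, correlated amplicon units, and
non-random (detection-driven) missingness. Passing recovery tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to those real-data features.

## Validation studies and sizes

`simpo.evaluation` holds the desk-scale studies the acceptance script runs:
score-vs-oracle agreement (1000 random probe-group pairs), probe-filter
correctness against exhaustive counting (233-symbol universe, 103 with
probes), type-I calibration (one null cohort of 1000 genes × 200 samples),
age-effect recovery (20 replicates, 30 planted genes of 1000), Cox log-HR
recovery (20 replicates at n=300, true log-HR 0.7, 60% events) and log-rank
null calibration (1000 replicates at 50/50), LOOCV AUC against the binormal
closed form (20 replicates at n=150, target 0.85), the Mann–Whitney/
trapezoid identity (100 instances), and the end-to-end early-stage
classifier run (20 replicates of the 53-case/50-control design, planted
population AUC 0.83). These sizes keep a full run to a few minutes on one
CPU while leaving Monte-Carlo error well inside each study's decision band.

## Known limitations

* The score is undefined (missing) for genes/samples with fewer than two
  usable probes per group, and infinite under exact zero pooled variance;
  downstream tests drop non-finite scores pairwise.
* Headline counts from cohort reanalyses (numbers of significant genes at a
  given adjustment) depend on the adjustment convention and cohort; with
  user-supplied real matrices the pipeline runs end to end and emits ranked
  tables, but counts will move with those choices.
* The Efron tie solver is single-covariate (univariate screening is the
  package's scope); multivariate Cox with clinical covariates is out of
  scope.
* Stepwise selection + LOOCV in the default ordering is optimistic; use the
  nested mode when an unbiased performance estimate matters.
* Conversely, pooled LOOCV probabilities are *pessimistically* biased when
  there is no signal: each fold's training set is depleted of the left-out
  sample's class, so the intercept anti-ranks it, and with a near-zero slope
  this dominates. On shuffled labels the mean LOOCV AUC sits near 0.36
  rather than 0.5 at these sample sizes (reproduced independently with
  scikit-learn's LeaveOneOut). This is a known property of leave-one-out AUC
  pooling — it is why leave-pair-out variants exist — and is harmless
  wherever real signal is present, but a shuffled-label control run through
  this pipeline should be read against that biased null, not against 0.5.
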