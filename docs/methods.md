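# Methods

## The score and its derivation

The pipeline treats "hypoxia" as a gene-expression program: genes of a
curated hypoxia hallmark set that are reproducibly overexpressed in
tumor tissue. Derivation screens each tumor/normal study with a
per-gene Welch two-sample *t*-test on log2 values (unequal variances,
two-sided) and Benjamini–Hochberg adjustment across all tested genes,
keeps genes with fold-change > 2 and adjusted *p* < 0.05 (both
inequalities strict), and intersects the surviving sets across studies
and with the hallmark set. Conventions worth stating explicitly:

* **Fold-change scale.** Fold-change is 2^(mean log2 tumor − mean log2
  normal), a ratio of geometric means, so "fold-change > 2" is exactly
  "log2FC > 1" on log-scale input.
* **Test choice.** The Welch *t*-test is the standard two-group default
  for log-scale microarray contrasts and its calibration is directly
  checkable by simulation (the suite verifies ~5% raw *p* < 0.05 under
  the null). No moderated-variance (empirical-Bayes) test is offered.
* **Unpaired analysis.** Studies are treated as unpaired two-group
  designs even when tumor/adjacent pairs exist; pairing metadata is not
  part of the input contract.
* **Degenerate genes.** A gene constant within *both* groups has an
  undefined t statistic; it receives *p* = 1 regardless of its mean
  difference so it can never pass the screen silently.
* **Direction.** The screen is one-directional (upregulation only);
  downregulated signatures are out of scope.
* **BH implementation.** The adjustment is the explicit sort /
  suffix-minimum of p·m/rank, which makes it bit-for-bit comparable to
  an independent brute-force oracle in the tests (and numerically
  indistinguishable from statsmodels' `fdr_bh`).

Scoring assigns each sample, for every signature gene, +1 if its value
is strictly above the cohort median for that gene and −1 otherwise, and
sums over genes. Tie and edge rules: with odd cohort size the median
sample scores −1; a constant gene contributes −1 to every sample (with
a warning); signature genes absent from a matrix are dropped, never
imputed, and the score stays a raw sum — it is *not* rescaled by the
number of genes used. The score depends only on within-gene ranks, so
it is invariant under any strictly increasing per-gene transform (e.g.
whether the input is log2 or linear scale). High/low groups split at
the cohort median score, strictly-above rule; if every sample has the
identical score the score table is still returned but the group label
is left unassigned (stratification is impossible, and
`assign_groups` raises if called directly on such input).

The gene-wise correlation screen keeps genes with Pearson *r* ≥ 0.05
and *p* < 0.05 against the score. An *r* cutoff of 0.05 is unusually
permissive — at typical cohort sizes the *p* threshold is what actually
binds — but it is the protocol's stated rule and is kept as the default
with both thresholds configurable.

## Association analyses

* **Log-rank / KM:** classic two-group log-rank (observed-minus-
  expected events over the hypergeometric variance, chi-square, 1 df)
  via lifelines, with KM step functions and median survival per group.
  A single group without events is fine; no events anywhere is an
  error.
* **Cox models:** partial-likelihood fits with Efron tie handling
  (lifelines), Wald 95% CIs and *p*-values. The hypoxia score enters as
  the binary high/low indicator (low = reference), matching the single
  hazard-ratio row convention of clinical tables. Grade is coded as G2
  and G3/G4 indicators against a G1 reference, stage as II and III/IV
  against stage I; residual tumor and gender are 0/1. Fits that do not
  converge, show effectively infinite standard errors (monotone
  likelihood/separation) or have fewer than two events per parameter
  return a flagged result rather than silent numbers.
* **Forward LR selection:** at each step the candidate with the
  smallest likelihood-ratio *p* (2·Δ partial log-likelihood against the
  current model, chi-square with df = parameters added; against the
  null model at step one) enters if *p* < 0.05; selection stops when no
  candidate qualifies. An empty final model is a reported outcome, not
  an error. No multiple-testing correction is applied across
  endpoints/models.
* **Partial correlation:** residualize both scores on the controls by
  least squares with intercept and correlate the residuals; *p* from
  the *t* transform with df = n − 2 − k. Ordinal controls are coded as
  consecutive integers (stage I=1, II=2, III/IV=3; grade G1=1, G2=2,
  G3/G4=3). Collinear controls and variables fully explained by the
  controls are errors. The tests verify agreement with the
  inverse-correlation-matrix identity −Ω01/√(Ω00·Ω11) to 1e−8 and with
  pingouin.
* **Contingency:** Pearson chi-square of independence without
  continuity correction; empty category levels are dropped with a
  warning.

Confidence level is fixed at 95% throughout.

## The synthetic cohort generator

The generator produces everything the pipeline consumes, with planted
parameters as recoverable ground truth. It emulates the *statistical
structure* of a two-study derivation plus a TCGA-like survival cohort,
not platform artifacts: no batch effects, probe-level structure or
count-distribution features are modeled, so passing tests demonstrate
correct recovery of the assumed model, not robustness to real-data
messiness.

Model:

* Gene baselines are uniform on log2 ∈ [4, 10] with i.i.d. Gaussian
  noise (`noise_sd`, default 0.5 log2 units — a typical microarray-like
  within-group SD).
* In the two DE studies, the same `n_planted` (default 30) hallmark
  genes get a `effect_log2fc` (default 2.0) mean shift in tumors;
  everything else is null.
* In the survival cohort each sample carries a latent hypoxia level
  z ~ N(0, 1). Planted genes load on z with `factor_loading` (default
  1.0); all EMT-hallmark genes load with `emt_loading` (default 0.03,
  chosen from the binarization attenuation formula so the 200-gene EMT
  score correlates with the hypoxia score at ~0.5, the magnitude
  typical of bulk-cohort program coupling).
* Survival is exponential — constant baseline hazards (OS 0.035, PFS
  0.058 per time unit, i.e. median ~20 and ~12 months event-free at
  z = 0) times exp(`log_hr`·z) — with independent exponential censoring
  (`censor_rate` 0.018, ~60–65% observed events). The exponential
  baseline satisfies proportional hazards exactly, making Cox recovery
  a clean oracle. The default `log_hr` 0.38 per latent SD induces a
  high-vs-low score-group hazard ratio of ≈ exp(0.38·1.6) ≈ 1.8
  (1.6 = E[z | top half] − E[z | bottom half] for a standard normal).
* `hazard_form="dichotomized"` replaces exp(log_hr·z) with
  exp(log_hr·1[z>0]). A hazard linear in z induces a *non*-proportional
  and attenuated contrast between score halves, so an exactly specified
  group hazard ratio needs the hazard planted on the dichotomy itself;
  this form exists for parameter-recovery experiments.
* Stage and grade are 3-level ordinals drawn through a cumulative
  logistic link with slope 0.8 on z (higher z → higher category), with
  intercepts set to give marginals resembling a pancreatic cohort
  (stage II most common, III/IV rare; grade G2 predominant). Residual
  tumor (p = 0.35) and gender (p = 0.5) are independent Bernoulli. A
  two-level subtype label is enriched for high z and consumed only as a
  given annotation.
* Defaults — 39/39 samples per DE study, a 177-sample cohort, 200-gene
  hallmark sets, 10,000 genes — mirror the sizes of the public cohorts
  this design targets.

All draws flow from the config seed through per-operation child
streams, so identical configs are bit-identical and the planted gene
list is shared across operations by construction.

## Problem sizes and numerics

The test suite runs the derivation screen at 2,000 genes and 20/20
samples per study (20 seeds), null calibration on 200 cohorts of 200
samples, and hazard-recovery on 50 cohorts of 500 samples — sizes at
which the Monte-Carlo error of every asserted quantity is comfortably
inside its tolerance while the whole suite stays interactive (<1 min).
The acceptance script uses the full default conditions (10,000 genes,
177 samples). Numerical edge rules are as documented above: strict
inequalities at thresholds, p = 1 for doubly-constant genes, −1 at
median ties, NA groups for constant scores, flagged Cox fits instead of
unreliable estimates.

## Known limitations

* Gene identifiers are matched by exact string identity; no
  probe-to-gene collapsing or symbol/alias translation.
* Samples missing from either expression or clinical input are dropped
  from joint analyses, never imputed; time units are taken as given.
* No proportional-hazards diagnostics, time-varying covariates or
  competing risks; no continuous enrichment scoring (ssGSEA/GSVA) —
  the ±1 median-sum score is the only scoring kernel shipped.
* The generator's Gaussian log-scale model does not emulate RSEM count
  distributions or microarray platform artifacts, and its clinical
  covariates are conditionally independent given z, which real cohorts
  are not.
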