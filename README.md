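# hyposig

Hypoxia gene-signature derivation, median-dichotomized scoring and
prognostic association analysis for bulk tumor expression cohorts.

## The problem

Hypoxia is a hallmark of the pancreatic-cancer microenvironment and is
linked to epithelial-to-mesenchymal transition (EMT), invasion and poor
outcome. A common way to quantify it from bulk transcriptomes is a
*hypoxia signature*: genes of the MSigDB hypoxia hallmark set that are
reproducibly upregulated in tumor versus normal tissue, summarized into
a per-sample score that can be tested against survival and other
clinical variables. `hyposig` implements that pipeline end to end for
analysts working with gene-by-sample expression tables, GMT gene sets
and clinical survival tables, and ships a synthetic-cohort generator
with planted, recoverable ground truth so every stage is testable
without access to controlled patient data.

## The method

1. **Signature derivation.** In each tumor/normal study, a per-gene
   Welch *t*-test on log2 expression with Benjamini–Hochberg adjustment
   screens for upregulated genes (fold-change > 2 computed as
   2^(Δ log2 mean), adjusted *p* < 0.05, both strict). The signature is
   the intersection of the upregulated sets across all studies with the
   hypoxia hallmark set.
2. **Scoring.** For each signature gene *g* and sample *j*, the sample
   contributes *s\_gj* = +1 if its expression is in the top half of the
   cohort for *g*, and −1 otherwise; the hypoxia score is
   Σ\_g *s\_gj* — an integer in [−*m*, *m*] for *m* genes, depending
   only on within-gene ranks. The EMT score applies the same rule to
   the 200-gene EMT hallmark set. Samples are split into high/low
   groups at the cohort median score (strictly-above rule).
3. **Association.** Kaplan–Meier curves with the two-group log-rank
   test; univariate Cox proportional-hazards models (Efron ties, Wald
   95% CIs); multivariate Cox with forward likelihood-ratio covariate
   entry (smallest LR *p* enters while *p* < 0.05); Pearson and partial
   correlation (residualization on integer-coded stage/grade/residual
   controls) between hypoxia and EMT scores; chi-square contingency
   tests of stage, grade and subtype against the score group; and a
   gene-wise Pearson screen for genes positively correlated with the
   score (*r* ≥ 0.05, *p* < 0.05, configurable).

## Worked example

`examples/02_score_and_survival.py` simulates a 177-sample cohort in
which a latent hypoxia level (standard normal, log HR 0.38 per SD)
drives 30 signature genes and the event hazard, then scores and tests
it:

```
cohort of 177 samples; score range [-30, 30], 85 high / 92 low
OS log-rank: chi2 = 12.60, p = 0.0003855, median survival high = 15.7, low = 28.7
PFS log-rank: chi2 = 7.48, p = 0.006252, median survival high = 10.0, low = 15.5
univariate OS HR (high vs low) = 1.999 (1.354-2.949), p = 0.0004861
forward-LR multivariate OS model retained: ['hypoxia_score']
               hazard_ratio  ci_low  ci_high      se  p_value
term
hypoxia_score        1.9986  1.3544    2.949  0.1985   0.0005
planted per-latent-SD log HR: 0.38 (group-level HR ~ 1.84)
```

High-score tumors have shorter overall and progression-free survival
(log-rank *p* < 0.01 for both), the univariate hazard ratio of the high
group is ~2 and forward selection keeps the score in the multivariate
model — recovering the planted group-level hazard ratio of ~1.84 within
sampling error. `examples/01_derive_signature.py` shows the signature
derivation (30/30 planted genes recovered, zero contamination) and
`examples/03_hypoxia_emt_correlation.py` the hypoxia–EMT correlation
and clinical contingency analyses.

The same stages are available from a shell:

```sh
hyposig simulate --outdir data/
hyposig derive-signature --expr data/study1.tsv --groups data/study1.groups.tsv \
    --expr data/study2.tsv --groups data/study2.groups.tsv \
    --hallmark data/gene_sets.gmt --out signature.gmt
hyposig score --expr data/cohort_expression.tsv --signature signature.gmt \
    --emt data/gene_sets.gmt --out scores.tsv
hyposig associate --scores scores.tsv --clinical data/cohort_clinical.tsv --outdir results/
```

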