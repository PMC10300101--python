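# plasmasieve

Tumor-only somatic variant filtering for large targeted cfDNA panels.

## The problem

Cell-free DNA (cfDNA) sequencing with a large targeted panel finds far more
candidate variants than a metastatic breast-cancer patient plausibly
carries: most calls are sequencing artefacts or germline polymorphisms.
Without a matched germline sample, separating the handful of tumor-derived
somatic mutations from this background is the central analytical problem.
`plasmasieve` implements a complete tumor-only filtering pipeline for this
setting, aimed at bioinformaticians analysing UMI-consensus amplicon panel
data:

1. **Basic filtering** — keep SNVs on chromosomes 1–22/X inside panel
   target regions, present in COSMIC, with unique-molecule genotype 0/0 or
   0/1.
2. **SVM false-positive removal** — each call is represented by a
   22-dimensional feature vector (16 caller statistics: quality,
   segregation metric, four bias p-values, allele count, strand-specific
   high-quality support, mapping quality, genotype, coverage, VAF,
   unique-molecule support; plus 6 sequence-context features from a 60 bp
   window: A/C/G/T counts, GC fraction, soft-masked repeat fraction).
   Vectors are standardized and classified by an SVM (linear or RBF kernel;
   C and γ tuned over the grid 1e-4 … 50). A call is kept when its decision
   score is ≥ 0.
3. **Rule-based baseline** — the exhaustive grid of 9 coverage × 11 VAF ×
   10 quality cutoffs (990 rules), selected by cross-validated F1.
4. **Post-processing cascade** — keep protein-affecting consequences
   (missense, start/stop lost, stop gained, splice acceptor/donor and
   donor-5th-base), keep variants seen in ≥ 1 of three breast-cancer cohort
   sets, and remove dbSNP variants whose VAF lies in a germline range.
5. **Germline VAF model** — a four-component beta mixture over VAFs
   (error / somatic / germline-het / germline-hom) fitted by EM; the VAF
   ranges where the germline components dominate (defaults [36%, 67%) and
   [67%, 100%]) drive the germline removal.
6. **Cross-assay VAF regression** — Bayesian no-intercept regression
   logit(VAF_b) = β·logit(VAF_a) + ε with β ~ N(1, 0.5) and error variance
   ~ Exp(mean 1), fitted by ensemble MCMC, for checking variants seen by
   only one panel against the cross-panel VAF relationship.

Evaluation uses leave-one-patient-out cross-validation with inner
stratified fourfold hyperparameter tuning, scored by precision, recall,
F1 = 2·pr·rc/(pr+rc), Matthews correlation coefficient and Youden's J.

A seeded synthetic-cohort generator (`plasmasieve.simulate`) emulates the
whole experiment — soft-masked reference, per-patient VCFs with
class-conditional VAF/quality regimes, COSMIC/dbSNP/cohort tables and
VEP-style consequences consistent with the truth labels — so every stage is
testable end to end without any data download.

## Worked example

```bash
python examples/03_svm_lopo.py
```

```
168 labeled calls from 6 patients (24 true somatic)

strategy          pr    rc    F1   MCC     J
none            0.14  1.00  0.25  0.00  0.00
rule            0.29  0.92  0.44  0.38  0.53
svm             1.00  0.96  0.98  0.98  0.96
```

With no filtering every call is kept, so recall is 1 by construction but
MCC and Youden's J are exactly 0 — the performance of random guessing. The
rule-based baseline (a single coverage/VAF/quality cutoff triple) improves
on that; the SVM, which can also use bias statistics and sequence context,
dominates it on every metric. The other scripts in `examples/` walk through
basic filtering, rule tuning, the beta-mixture germline model, the
post-processing cascade and the cross-assay regression, each printing the
quantities it computes.

A thin CLI mirrors the library (`plasmasieve simulate | basic-filter |
featurize | tune | lopo | train | apply | mixture-fit | cascade |
subtract-germline | regress-vaf`); every run writes a JSON manifest
alongside its outputs.

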