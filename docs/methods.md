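# Methods

## Setting and data model

The pipeline targets tumor-only variant calling on large targeted cfDNA
panels sequenced with unique molecular identifiers (UMIs). Input calls are
assumed to come from `bcftools mpileup`/`call` on UMI-consensus reads: each
record carries a PHRED quality, the mpileup annotations (segregation-based
metric SGB; Mann–Whitney bias p-values RPB/MQB/MQSB/BQB; allele count AC;
mean mapping quality MQ; raw depth DP; strand-split high-quality support
DP4) and a FORMAT/AD field holding unique-molecule allelic depths. VAF and
coverage are computed from unique molecules (ref + alt consensus reads)
throughout the rule-based filter; the coverage *feature* uses the caller's
DP when present and falls back to unique-molecule depth otherwise.

Basic filtering keeps single-nucleotide variants on chromosomes 1–22/X
("chr" prefixes normalized) inside the panel's BED regions (1-based VCF
positions converted to the 0-based half-open BED convention at the one
point where the two meet), present in a COSMIC-style membership table keyed
by (chrom, pos, ref, alt), and excludes unique-molecule genotypes 1/1 and
1/2. Genotype 0/0 calls with alt support are retained deliberately: the
classifier encodes the genotype as a feature (2 reference alleles for 0/0,
1 for 0/1) and low-VAF somatic candidates frequently genotype as 0/0.
Multi-allelic records are also recognised structurally (more than one ALT
allele), since callers differ in whether they split records.

## Feature representation

Each call maps to exactly 22 features: the 16 call features above plus 6
sequence-context features computed on a 60 bp window around the site — 30
bases upstream and 30 downstream, the variant base itself excluded (30+30
only totals 60 under that convention). The context features are the
case-insensitive A/C/G/T counts, the GC fraction and the fraction of
soft-masked (lowercase) bases; repeat annotation is consumed as lowercase
soft-masking in the reference FASTA rather than by invoking a repeat
annotator, which makes the fraction reproducible from the reference alone.
N bases count toward no nucleotide bin but stay in the fraction
denominators, and windows at chromosome ends are truncated (fractions use
the realized window length).

Missing annotations are imputed, never invented silently: absent bias
p-values become 1.0 (no evidence of bias), an absent segregation metric,
mapping quality or allele count 0.0, absent DP the unique-molecule depth,
absent DP4 zeros — every imputation is flagged in a per-feature missing
mask. Constant-value placeholders were preferred over training-set
statistics (e.g. a median) to keep feature extraction a pure per-call
function; the mask lets a caller re-impute from training rows if desired. Vectors are
standardized to zero mean and unit variance; the standardizer is fitted on
training rows only, inside every cross-validation fold and every outer
leave-one-patient-out iteration, so no held-out information leaks into the
transform. Constant features get divisor 1 and are flagged.

## Classifiers

**Rule baseline.** The cutoff grid is the Cartesian product of coverage
(10, 20, 50, 75, 100, 150, 200, 500, 1000 unique molecules), VAF (0.1%,
0.5%, 1%, 2%, 3%, 4%, 5%, 7.5%, 10%, 15%, 20%) and quality (1, 2, 5, 10,
15, 20, 25, 30, 40, 50) — 990 rules, all minima inclusive. Selection
maximizes mean held-out F1 over stratified fourfold CV on pooled calls;
ties break toward the earlier rule in the deterministic coverage-major grid
order.

**SVM.** Linear and RBF kernels with C (and γ for RBF) drawn from
(1e-4, 1e-3, 1e-2, 0.1, 0.5, 1, 2, 5, 10, 20, 50): 11 linear + 121 RBF =
132 configurations, tuned by the same inner-CV criterion, ties again
breaking by grid order. No class weighting or probability calibration is
applied; the raw decision function is thresholded at 0 by default, and the
threshold is exposed for precision–recall sweeps. Should a fold assignment
produce a single-class training fold, the assignment is redrawn with the
next seed (logged); this can only arise when a class has fewer members than
folds.

**Evaluation.** Leave-one-patient-out: all of one patient's calls form the
test set; tuning and the final refit use only the remaining patients.
Ground truth joins large-panel calls to hotspot-panel calls by variant key
within the panels' shared regions; hotspot variants never called by the
large panel enter as label-only rows that count as false negatives of every
strategy and never reach training. Metrics are precision, recall, F1, MCC
and Youden's J with the standard zero-denominator conventions (empty
denominator → 0; zero MCC root factor → 0), under which the
accept-everything strategy scores recall 1 and MCC = J = 0.

## Germline beta mixture

VAFs (clamped to [1e-4, 1-1e-4]) are modeled as a four-component beta
mixture for sequencing errors, somatic variants, germline heterozygotes and
germline homozygotes. Components are initialized at role-biased means
0.005 / 0.10 / 0.50 / 0.95 with concentration 20 and equal weights. The
E-step is exact; the M-step solves each component's weighted beta MLE
numerically (Nelder–Mead on log-parameters) and falls back to the previous
parameters whenever the optimizer fails to improve the component objective,
so the observed log-likelihood is non-decreasing by the EM argument, a
property the tests assert. Convergence: relative log-likelihood change
below 1e-7, cap 500 iterations. Roles are assigned by sorted fitted means.

Germline VAF intervals are the ranges where the het/hom components have the
highest posterior, found by a dense scan at step 1e-3 and refined by
bisection to 1e-6, with the shared het/hom boundary made contiguous (the
heterozygous interval is half-open at its upper end). For small panels
where fitting is unwarranted, the published operating intervals
[36%, 67%) and [67%, 100%] are available as `DEFAULT_GERMLINE_INTERVALS` without
fitting. A call is flagged germline only when its VAF lies in a germline
range *and* it is a known polymorphism (dbSNP member).

## Post-processing cascade

Three pure set-selections: most-severe transcript consequence in the
allowed set (missense_variant, start_lost, stop_lost, stop_gained,
splice_acceptor_variant, splice_donor_variant,
splice_donor_5th_base_variant); membership in at least one cohort variant
set; not flagged germline. "Most severe" uses the standard Ensembl
consequence severity order embedded as a static table. Because each step
depends only on variant identity and its annotations, the cascade's final
set is the intersection of the per-step keep-sets and is order-independent,
idempotent and anti-monotone in configuration strictness — properties the
tests verify over all six orders. Unannotated calls are removed and
counted. The matched-germline comparator subtracts, per patient, any cfDNA
call whose full variant key appears in the germline calls.

## Cross-assay VAF regression

For mutations called by two assays, logit(VAF_test) = β·logit(VAF_ref) + ε
with no intercept, β ~ Normal(1, sd 0.5) and the error *variance* ~
Exponential(mean 1); the sampler works on the log variance with the
Jacobian included. The shorthand N(1, 0.5) leaves open whether 0.5 is a
standard deviation or a variance; the standard-deviation reading is the
default and a flag selects the variance reading. The
posterior is drawn by affine-invariant ensemble MCMC (emcee): by default 4
independent 8-walker chains, 1000 warmup steps, 2000 retained draws per
chain; convergence is judged by split-R̂ of the slope across chains with
threshold 1.01, and a failed check warns and flags the result rather than
erroring. Logits clamp their argument to [1e-4, 1-1e-4]. Predictive
intervals simulate one noise draw per posterior draw on the logit scale and
back-transform, so endpoints always lie in (0, 1).

## Synthetic cohorts

The generator emulates the study conditions end to end. Per patient it
draws calls from four class-conditional regimes with default VAF laws
Beta(1, 200) for errors, Beta(2, 8) for somatic, Beta(45, 45) for germline
het and Beta(90, 2) for germline hom; default per-patient counts (2
somatic, 6 germline het, 3 germline hom, 15 errors) echo the observed
scale of a large panel restricted to hotspot-shared regions, where an
order of magnitude more artefactual than somatic calls survive basic
filtering. Unique-molecule coverage is negative-binomial around 1500;
DP4 strand splits are binomial, balanced for true calls and imbalanced for
errors. A `separation` knob (default 3) sets how far somatic call quality
and bias statistics sit from the error regime. Membership tables are
constructed consistent with truth (all non-control calls in COSMIC,
germline in dbSNP, somatic spread across three cohort sets) plus decoy
entries and per-patient non-COSMIC control calls that exercise the
membership logic. Everything is byte-deterministic under the spec seed.

What the generator does **not** emulate: real error processes are
position- and context-dependent (the synthetic errors are i.i.d. across
sites), germline variants cluster on population haplotypes, panels have
non-uniform coverage across amplicons, and true somatic VAFs track tumor
fraction within a patient rather than being drawn independently. Passing
tests therefore demonstrate that the pipeline machinery is correct and
leakage-free, not that the reported operating points transfer to real
cfDNA data.

Two named configurations matter for validation. Under the default laws the
somatic Beta(2, 8) VAF range genuinely overlaps the germline-het range, so
no classifier can approach perfect F1 — that irreducible overlap is a
feature of the realistic conditions. `high_separation_spec()` instead
places every class in a distinct feature region (somatic VAFs Beta(3, 40),
separation 5) and exists purely to validate the nested-CV machinery, which
should and does recover that signal almost perfectly.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: cohorts of 6–12
patients with ~26 calls each, mixture fits at n = 10,000, regression at
n ≤ 200, five label-shuffle replicates for the chance-level check. Grid
evaluation of all 990 rules is vectorized (rules × calls boolean matrix).
Tie-breaks everywhere are deterministic (first in documented grid order);
all randomness flows from explicit seeds. Model serialization (joblib)
stores the SVC together with its standardizer, configuration, feature-name
order and a training-data fingerprint, and round-trips are tested.

## Known limitations

- The SVM operating point (threshold 0) is not calibrated; on heavily
  imbalanced cohorts a threshold sweep is advisable.
- The beta-mixture role assignment assumes the four regimes are present
  and ordered by mean; degenerate cohorts (e.g. a single tight VAF
  cluster) fit fine but interval derivation will report that a germline
  component is nowhere the most likely origin.
- Interval derivation returns a single contiguous range per germline
  component (the run containing the component mean); exotic fits with
  disconnected dominance regions are truncated to that run.
- Indels and multi-nucleotide variants are parsed but excluded by design;
  the pipeline is SNV-only.
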