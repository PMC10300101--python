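"""Run the post-processing cascade on one patient's model-passing calls.

Three set-selections applied in sequence: keep protein-affecting
consequences, keep variants seen in at least one breast-cancer cohort,
remove dbSNP variants whose VAF is in a germline range.  The final set is
order-independent.
"""

from plasmasieve import (
    CascadeConfig,
    CohortSpec,
    ConsequenceAnnotation,
    DEFAULT_GERMLINE_INTERVALS,
    germline_subtraction,
    make_cohort,
    run_cascade,
)

cohort = make_cohort(CohortSpec(n_patients=2, seed=3))
patient = "P001"
calls = cohort.calls[patient]
annotations = {k: ConsequenceAnnotation(key=k, consequences=v)
               for k, v in cohort.consequences.items()}
config = CascadeConfig(cohort_sets=cohort.cohort_sets, dbsnp=cohort.dbsnp,
                       intervals=DEFAULT_GERMLINE_INTERVALS)

kept, step_log = run_cascade(calls, annotations, config)
for step, count in step_log:
    print(f"{step:<12} {count} calls")
truth = {cohort.truth[(patient, c.key)] for c in kept}
print(f"\nsurviving call classes: {sorted(truth)}")

# matched-germline comparator: subtract calls seen in the patient's own
# white-blood-cell DNA instead of using population databases
germline_like = [c for c in calls
                 if cohort.truth[(patient, c.key)].startswith("germline")]
somatic = germline_subtraction(calls, germline_like)
print(f"germline subtraction: {len(calls)} cfDNA calls -> {len(somatic)} "
      "labeled somatic (germline-matched removal)")
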