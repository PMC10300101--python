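"""Generate a synthetic cfDNA cohort and apply the pre-model basic filters.

The basic filters keep SNVs on chromosomes 1-22/X that fall inside a panel
target region, are known COSMIC variants, and are not homozygous or
multi-allelic by unique-molecule genotype.
"""

from plasmasieve import CohortSpec, basic_filter, make_cohort

cohort = make_cohort(CohortSpec(n_patients=4, seed=0))

total_in = total_out = 0
for patient, calls in sorted(cohort.calls.items()):
    kept = basic_filter(calls, cohort.regions, cohort.cosmic)
    total_in += len(calls)
    total_out += len(kept)
    print(f"{patient}: {len(calls)} raw calls -> {len(kept)} after basic filtering")

print(f"\ncohort: {total_in} calls in, {total_out} kept")
print("the removed calls are the generated non-COSMIC controls; everything")
print("else (true somatic, germline and artefactual calls alike) passes and")
print("is handed to the classifier stage.")
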