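"""Leave-one-patient-out comparison of the three filtering strategies.

Each outer iteration holds out one patient's calls entirely, tunes
hyperparameters by stratified fourfold CV on the remaining patients, and
scores the held-out patient.  Pooled confusion counts give the strategy's
cohort-level precision/recall/F1/MCC/Youden's J.
"""

from plasmasieve import high_separation_spec, lopo_evaluate, make_cohort

cohort = make_cohort(high_separation_spec(seed=2, n_patients=6))
rows = cohort.labeled_variants()
print(f"{len(rows)} labeled calls from 6 patients "
      f"({sum(r.label for r in rows)} true somatic)\n")

print(f"{'strategy':<14}{'pr':>6}{'rc':>6}{'F1':>6}{'MCC':>6}{'J':>6}")
for strategy in ("none", "rule", "svm"):
    m = lopo_evaluate(rows, strategy=strategy, seed=0).pooled
    print(f"{strategy:<14}{m.precision:>6.2f}{m.recall:>6.2f}"
          f"{m.f1:>6.2f}{m.mcc:>6.2f}{m.youden_j:>6.2f}")

print("\nwith no filtering every call is kept: recall is 1 by construction")
print("but MCC and Youden's J are exactly 0 - random-guessing performance.")
print("the SVM uses all 22 features and dominates the single-rule baseline.")
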