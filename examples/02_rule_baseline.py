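"""Tune the rule-based baseline (coverage/VAF/quality cutoffs) by CV.

All 990 combinations of the cutoff grids are scored by mean held-out F1
under stratified fourfold cross-validation on pooled labeled calls; the
winner is the filter a rule-based pipeline would deploy.
"""

from plasmasieve import apply_rule, high_separation_spec, make_cohort, select_rule_cv

cohort = make_cohort(high_separation_spec(seed=1, n_patients=6))
rows = cohort.labeled_variants()
labeled = [(r.call, r.label) for r in rows if r.call is not None]

rule = select_rule_cv(labeled, folds=4, seed=0)
print(f"selected rule: coverage >= {rule.min_coverage} unique molecules, "
      f"VAF >= {rule.min_vaf:.3f}, quality >= {rule.min_quality}")

calls = [c for c, _ in labeled]
kept = apply_rule(rule, calls)
tp = sum(1 for c, l in labeled if l and c in kept)
fp = sum(1 for c, l in labeled if not l and c in kept)
fn = sum(1 for c, l in labeled if l and c not in kept)
print(f"in-sample: {len(kept)}/{len(calls)} calls kept, "
      f"{tp} true somatic recovered, {fp} false positives, {fn} missed")
print("a single cutoff triple cannot use bias statistics or sequence")
print("context, which is why the SVM filter outperforms it.")
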