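"""Paired MRI-vs-CEM comparison with the DeLong test.

The two modalities read the same lesions, so their AUCs are correlated;
the DeLong test accounts for that pairing via per-observation structural
components.
"""

from kscem import delong_paired_test, exact_count_cohort, load_builtin_tree

trees = {m: load_builtin_tree(m) for m in ("mri", "cem")}
records = exact_count_cohort(seed=0)

labels = [r.truth for r in records]
mri = [trees["mri"].score(r.mri.features) for r in records]
cem = [trees["cem"].score(r.cem.features) for r in records]

result = delong_paired_test(mri, cem, labels)
print(f"AUC MRI: {result.auc_a:.3f}")
print(f"AUC CEM: {result.auc_b:.3f}")
print(f"DeLong z = {result.z:.3f}, two-sided p = {result.p:.3f}")
# p above 0.05: no evidence that the two modalities discriminate
# malignant from benign lesions differently on this cohort.
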