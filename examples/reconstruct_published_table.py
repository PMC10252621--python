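"""Reconstruct confusion matrices from printed summary metrics.

Published ROC tables report percentages, not the underlying 2x2 counts.
With known class margins (47 malignant, 21 benign) an exhaustive integer
search over all confusion matrices recovers the counts — and doubles as a
consistency audit: if no matrix rounds to every printed cell, the printed
cells contradict each other.
"""

from kscem import metrics, reconstruct_confusion

# Youden operating point, MRI column: PPV 97.67%, NPV 80%
res = reconstruct_confusion(47, 21, [("ppv", "97.67", 2), ("npv", "80", 0)])
cm = res.matrices[0]
print(f"unique: {res.unique}; TP={cm.tp} FP={cm.fp} FN={cm.fn} TN={cm.tn}")
m = metrics(cm)
print(f"implied sensitivity {m.sensitivity:.2%}, specificity {m.specificity:.2%}, "
      f"accuracy {m.accuracy:.1%}")

# adding the printed accuracy cell (88.2%) to the constraints leaves no
# surviving matrix: that cell is arithmetically inconsistent with the rest
audit = reconstruct_confusion(
    47, 21, [("ppv", "97.67", 2), ("npv", "80", 0), ("accuracy", "88.2", 1)]
)
print(f"consistent with printed accuracy cell: {audit.consistent}")
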