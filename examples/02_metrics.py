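"""Q8 accuracy, per-class precision/recall and the dash convention.

Q8 pools residues over all proteins; a class absent from both truth
and prediction has 0/0 precision and recall and is rendered as a dash
rather than 0 — there is nothing to measure for it.
"""

import numpy as np

import q8fuse as q

alpha = q.DEFAULT_ALPHABET
enc = lambda s: np.array([alpha.index_of(c) for c in s])

true = enc("HHEELLTT")
pred = enc("HHEELLTG")
print(f"truth      {'HHEELLTT'}")
print(f"prediction {'HHEELLTG'}")
print(f"Q8 = {q.q8_accuracy(pred, true):.3f}  (7 of 8 residues correct)")
print()
report = q.per_class_precision_recall(pred, true)
print(report.format_text())
print()
print("row-normalized confusion matrix (dash rows = class absent from truth):")
print(report.confusion_csv().rstrip())
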