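"""Sliding windows for local residue classifiers.

A window of odd size centered on each residue, zero-padded at the
protein ends — the input convention of window-based predictors
(default sizes 9, 11, 13, 15, 17).
"""

import q8fuse as q

rec = q.make_toy_dataset(1, (12, 12), seed=0).records[0]
spec = q.WindowSpec(size=9, features="both")
windows, labels = q.extract_windows(rec, spec)
print(f"protein of {rec.length} residues -> {windows.shape[0]} windows "
      f"of shape {windows.shape[1:]} (9 positions x 42 features)")
print(f"first window: {int((windows[0].sum(axis=1) == 0).sum())} zero rows "
      "(the 4 left-context positions fall before the protein start)")
table = q.windows_table(rec, spec)
print(f"flat export for external training: {table.shape} table, "
      f"labels {labels[:5]}... per center residue")
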