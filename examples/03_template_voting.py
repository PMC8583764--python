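"""Template-based prediction: rank-weighted voting over three alignments.

Three retrieved hits for a 6-residue query transfer their subjects'
structure strings to the aligned residues.  Under the specific-
alignments thresholds the kept hits carry weights 10, 9, 8; the
general-alignments predictor uses 100, 99, 98 and fills uncovered
residues from their nearest covered neighbour.
"""

import io

import q8fuse as q

alpha = q.DEFAULT_ALPHABET

rows = [
    ["qq", "t1", "1e-30", "1", "6", "1", "6", "ACDEFG", "ACDEFG"],  # full match
    ["qq", "t2", "1e-20", "1", "4", "1", "3", "ACDE", "AC-E"],      # subject gap at query pos 3
    ["qq", "t3", "1e-10", "4", "6", "1", "3", "EFG", "EFG"],        # covers the tail
]
hits = q.parse_hits(io.StringIO("\n".join("\t".join(r) for r in rows)), "qq")
db = q.TemplateDB(ss={"t1": "HHHHHH", "t2": "EEE", "t3": "TTT"})

tally = q.vote_specific(hits, db, length=6)
probs = q.tally_to_probabilities(tally)
print("specific alignments (weights 10/9/8):")
for i in range(6):
    votes = {s: int(v) for s, v in zip(alpha, tally.votes[i]) if v}
    print(f"  residue {i}: votes {votes}  ->  p = "
          + ", ".join(f"{s}:{probs[i, k]:.3f}" for k, s in enumerate(alpha) if probs[i, k]))
print()
print("residue 0 splits 10/19 vs 9/19 between the H and E votes of hits 1 and 2")

gen = q.vote_general(hits, db, length=6)
print()
print("general alignments re-weights the same hits 100/99/98:",
      {s: int(v) for s, v in zip(alpha, gen.votes[0]) if v}, "at residue 0")
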