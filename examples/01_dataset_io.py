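"""Dataset round trip: toy proteins -> flattened feature matrix -> FASTA.

Each protein is stored as 700 x 50 features (21 amino-acid one-hot,
21 PSSM, 8 structure one-hot), zero-padded past its true length; the
reader strips the padding and validates the one-hot rows.
"""

import tempfile
from pathlib import Path

import q8fuse as q

ds = q.make_toy_dataset(n_proteins=3, length_range=(8, 20), seed=0)
print(f"generated {len(ds)} proteins with lengths {[r.length for r in ds]}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.npy"
    q.write_cb_matrix(ds, path)
    back = q.read_cb_matrix(path, ids=ds.ids)
    print(f"round trip preserved lengths: {[r.length for r in back]}")

print()
print(q.to_fasta(ds).rstrip())
print()

# proteins beyond 700 residues are split into 700-residue chunks
long = q.make_toy_dataset(1, (100, 100), seed=1).records[0]
import numpy as np

big = q.ProteinRecord(
    id="giant",
    aa_onehot=np.tile(long.aa_onehot, (8, 1))[:750],
    pssm=np.tile(long.pssm, (8, 1))[:750],
    labels=np.tile(long.labels, 8)[:750],
)
parts = q.split_long_protein(big)
print(f"a 750-residue protein splits into {[p.length for p in parts]} "
      f"with ids {[p.id for p in parts]}")
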