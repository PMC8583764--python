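"""Reading, validating and writing CB6133/CB513-style protein feature matrices.

The on-disk convention these datasets use is one flattened row per
protein: 700 residue slots times F feature columns (F = 50 in the
canonical form handled here).  Per residue the features are 21 one-hot
amino-acid columns (20 letters plus "X"), 21 PSSM columns scaled to
[0, 1], and 8 one-hot secondary-structure columns.  Proteins shorter
than 700 residues are padded with all-zero rows; a real residue can
never be all-zero because its one-hot block sums to 1.

Because the column ordering inside the feature block is not part of the
file format itself, it is described by a :class:`CBLayout` which is a
mandatory, documented configuration (with a shipped default) rather
than a hard-coded constant.  Public releases of these datasets carry 57
features per residue; a layout selecting the relevant 50 columns makes
the reader accept those files too, ignoring the extra columns.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_LETTERS, DEFAULT_ALPHABET, ClassAlphabet
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MAX_LEN = 700
_ONEHOT_ATOL = 1e-6


@dataclass(frozen=True)
class CBLayout:
    """Column map for the per-residue feature block.

    Parameters
    ----------
    n_features
        Total feature columns per residue in the file (50 canonical,
        57 for the public releases).
    aa_cols, pssm_cols, label_cols
        0-based column indices of the amino-acid one-hot block, the
        PSSM block, and the structure one-hot block.  ``label_cols``
        may be ``None`` for unlabeled data.
    aa_letters
        Amino-acid letter corresponding to each ``aa_cols`` entry.
    classes
        Structure symbol ordering of ``label_cols``.
    """

    n_features: int = 50
    aa_cols: tuple[int, ...] = tuple(range(0, 21))
    pssm_cols: tuple[int, ...] = tuple(range(21, 42))
    label_cols: tuple[int, ...] | None = tuple(range(42, 50))
    aa_letters: str = AA_LETTERS
    classes: ClassAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        if len(self.aa_cols) != len(self.aa_letters):
            raise ValueError("aa_cols and aa_letters lengths differ")
        if self.label_cols is not None and len(self.label_cols) != 8:
            raise ValueError("label_cols must list exactly 8 columns")
        cols = list(self.aa_cols) + list(self.pssm_cols) + list(self.label_cols or ())
        if max(cols) >= self.n_features or min(cols) < 0:
            raise ValueError("column index outside [0, n_features)")

    @property
    def feature_cols(self) -> tuple[int, ...]:
        """All columns used for padding detection."""
        return tuple(self.aa_cols) + tuple(self.pssm_cols) + tuple(self.label_cols or ())

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_features": self.n_features,
            "aa_cols": list(self.aa_cols),
            "pssm_cols": list(self.pssm_cols),
            "label_cols": None if self.label_cols is None else list(self.label_cols),
            "aa_letters": self.aa_letters,
            "classes": list(self.classes.labels),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CBLayout":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            n_features=int(doc["n_features"]),
            aa_cols=tuple(doc["aa_cols"]),
            pssm_cols=tuple(doc["pssm_cols"]),
            label_cols=None if doc.get("label_cols") is None else tuple(doc["label_cols"]),
            aa_letters=doc.get("aa_letters", AA_LETTERS),
            classes=ClassAlphabet(tuple(doc.get("classes", DEFAULT_ALPHABET.labels))),
        )


#: Canonical 50-column layout: 21 aa one-hot, 21 PSSM, 8 structure one-hot.
DEFAULT_LAYOUT = CBLayout()

#: Layout for the widely circulated 57-column public releases
#: (princeton "+profile" files): columns 0-21 amino acid one-hot
#: ("ACEDGFIHKMLNQPSRTWVYX" + a no-sequence flag), 22-30 structure
#: one-hot ("LBEGIHST" + no-sequence), 31-34 terminal/solvent flags,
#: 35-56 PSSM in the same residue order.  The no-sequence columns are
#: ignored, leaving the canonical 50.
CB57_LAYOUT = CBLayout(
    n_features=57,
    aa_cols=tuple(range(0, 21)),
    pssm_cols=tuple(range(35, 56)),
    label_cols=tuple(range(22, 30)),
    aa_letters="ACEDGFIHKMLNQPSRTWVYX",
    classes=ClassAlphabet(("L", "B", "E", "G", "I", "H", "S", "T")),
)


@dataclass
class ProteinRecord:
    """One protein's residues, features and (optionally) true labels.

    Arrays are stored unpadded: ``L`` rows for a length-``L`` protein.
    ``labels`` holds 0-based class indices into the run's
    :class:`~q8fuse.alphabet.ClassAlphabet`, or ``None`` for unlabeled
    input.
    """

    id: str
    aa_onehot: np.ndarray
    pssm: np.ndarray
    labels: np.ndarray | None = None

    @property
    def length(self) -> int:
        return self.aa_onehot.shape[0]

    def validate(self, n_aa: int = 21) -> None:
        L = self.length
        if L < 1:
            raise ValidationError(f"protein {self.id!r}: zero-length record")
        if self.aa_onehot.shape != (L, n_aa):
            raise ValidationError(f"protein {self.id!r}: aa_onehot shape {self.aa_onehot.shape}")
        if self.pssm.shape != (L, n_aa):
            raise ValidationError(f"protein {self.id!r}: pssm shape {self.pssm.shape}")
        sums = self.aa_onehot.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ONEHOT_ATOL)
        if bad.size:
            raise ValidationError(
                f"protein {self.id!r}: amino-acid one-hot row does not sum to 1 "
                f"at position {bad[0] + 1} (1-based)"
            )
        if self.pssm.min() < -_ONEHOT_ATOL or self.pssm.max() > 1 + _ONEHOT_ATOL:
            raise ValidationError(f"protein {self.id!r}: PSSM values outside [0, 1]")
        if self.labels is not None:
            if self.labels.shape != (L,):
                raise ValidationError(f"protein {self.id!r}: labels shape {self.labels.shape}")
            if self.labels.min() < 0 or self.labels.max() > 7:
                raise ValidationError(f"protein {self.id!r}: label index outside 0..7")

    def sequence(self, aa_letters: str = AA_LETTERS) -> str:
        """Decode the one-hot block back to a letter sequence."""
        idx = self.aa_onehot.argmax(axis=1)
        if idx.max() >= len(aa_letters):
            raise ValidationError(
                f"protein {self.id!r}: one-hot column {idx.max()} outside the "
                f"{len(aa_letters)}-letter map"
            )
        return "".join(aa_letters[i] for i in idx)


@dataclass
class Dataset:
    """A split of protein records (train / validation / test)."""

    records: list[ProteinRecord]
    split_tag: str = "test"

    def validate(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rid: str) -> ProteinRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def labels(self) -> dict[str, np.ndarray]:
        out = {}
        for r in self.records:
            if r.labels is None:
                raise ValidationError(f"protein {r.id!r} has no labels")
            out[r.id] = r.labels
        return out

    @property
    def n_residues(self) -> int:
        return sum(r.length for r in self.records)


def _load_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return np.loadtxt(fh, ndmin=2)
    return np.loadtxt(path, ndmin=2)


def _save_array(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, arr)
    elif path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            np.savetxt(fh, arr, fmt="%.8g")
    else:
        np.savetxt(path, arr, fmt="%.8g")


def dataset_from_array(
    arr: np.ndarray,
    layout: CBLayout = DEFAULT_LAYOUT,
    ids: Sequence[str] | None = None,
    split_tag: str = "test",
) -> Dataset:
    """Build a :class:`Dataset` from an in-memory flattened matrix.

    Accepts ``(n, 700 * F)`` or ``(n, 700, F)`` arrays where ``F`` is
    ``layout.n_features``.
    """
    arr = np.asarray(arr, dtype=np.float64)
    F = layout.n_features
    if arr.ndim == 2:
        if arr.shape[1] != MAX_LEN * F:
            raise FormatError(
                f"expected rows of width {MAX_LEN}*{F} = {MAX_LEN * F}, got {arr.shape[1]}"
            )
        arr = arr.reshape(arr.shape[0], MAX_LEN, F)
    elif arr.ndim != 3 or arr.shape[1:] != (MAX_LEN, F):
        raise FormatError(f"expected shape (n, {MAX_LEN}, {F}), got {arr.shape}")

    if ids is None:
        ids = [f"protein_{i}" for i in range(arr.shape[0])]
    if len(ids) != arr.shape[0]:
        raise FormatError(f"{len(ids)} ids for {arr.shape[0]} proteins")

    feat_cols = list(layout.feature_cols)
    records: list[ProteinRecord] = []
    for pid, block in zip(ids, arr):
        mask = np.any(block[:, feat_cols] != 0, axis=1)
        if not mask.any():
            raise ValidationError(f"protein {pid!r}: all 700 rows are zero (empty protein)")
        L = int(np.flatnonzero(mask)[-1]) + 1
        if not mask[:L].all():
            pos = int(np.flatnonzero(~mask[:L])[0]) + 1
            raise ValidationError(
                f"protein {pid!r}: interior all-zero row at position {pos} (1-based); "
                "padding must be a contiguous tail"
            )
        real = block[:L]
        labels = None
        if layout.label_cols is not None:
            lab_block = real[:, list(layout.label_cols)]
            sums = lab_block.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _ONEHOT_ATOL):
                pos = int(np.flatnonzero(np.abs(sums - 1.0) > _ONEHOT_ATOL)[0]) + 1
                raise ValidationError(
                    f"protein {pid!r}: structure one-hot row does not sum to 1 "
                    f"at position {pos} (1-based)"
                )
            labels = lab_block.argmax(axis=1).astype(np.int64)
        rec = ProteinRecord(
            id=pid,
            aa_onehot=real[:, list(layout.aa_cols)].copy(),
            pssm=real[:, list(layout.pssm_cols)].copy(),
            labels=labels,
        )
        rec.validate(n_aa=len(layout.aa_cols))
        records.append(rec)
    ds = Dataset(records=records, split_tag=split_tag)
    ds.validate()
    return ds


def read_cb_matrix(
    path: str | Path,
    layout: CBLayout = DEFAULT_LAYOUT,
    ids: Sequence[str] | None = None,
    split_tag: str = "test",
) -> Dataset:
    """Read a flattened feature-matrix file into a validated Dataset.

    ``path`` may be a ``.npy`` array, a ``.gz`` gzipped text matrix, or
    plain whitespace-separated text.  Padding rows (all selected
    feature columns zero) are stripped; the structure one-hot block, if
    the layout names one, is converted to class indices.
    """
    return dataset_from_array(_load_array(path), layout=layout, ids=ids, split_tag=split_tag)


def dataset_to_array(dataset: Dataset, layout: CBLayout = DEFAULT_LAYOUT) -> np.ndarray:
    """Flatten a Dataset back to an ``(n, 700 * F)`` padded matrix."""
    F = layout.n_features
    out = np.zeros((len(dataset.records), MAX_LEN, F), dtype=np.float64)
    for i, rec in enumerate(dataset.records):
        if rec.length > MAX_LEN:
            raise ValidationError(
                f"protein {rec.id!r} has {rec.length} residues > {MAX_LEN}; "
                "apply split_long_protein first"
            )
        if layout.label_cols is not None and rec.labels is None:
            raise ValidationError(
                f"protein {rec.id!r} has no labels but the layout includes label columns"
            )
        out[i, : rec.length, list(layout.aa_cols)] = rec.aa_onehot.T
        out[i, : rec.length, list(layout.pssm_cols)] = rec.pssm.T
        if layout.label_cols is not None:
            lab = np.zeros((rec.length, 8))
            lab[np.arange(rec.length), rec.labels] = 1.0
            out[i, : rec.length, list(layout.label_cols)] = lab.T
    return out.reshape(len(dataset.records), MAX_LEN * F)


def write_cb_matrix(dataset: Dataset, path: str | Path, layout: CBLayout = DEFAULT_LAYOUT) -> None:
    """Write a Dataset as a flattened matrix file (inverse of read)."""
    _save_array(dataset_to_array(dataset, layout), path)


def split_long_protein(record: ProteinRecord, max_len: int = MAX_LEN) -> list[ProteinRecord]:
    """Split a record into consecutive chunks of at most ``max_len``.

    The first chunk takes the first ``max_len`` residues, the next the
    following ``max_len``, and so on; concatenating the outputs
    reproduces the input exactly.  A record already within the limit is
    returned unchanged (same id).  Split chunks get deterministic
    ``_part<k>`` id suffixes.
    """
    if record.length < 1:
        raise ValidationError(f"protein {record.id!r}: empty record")
    if record.length <= max_len:
        return [record]
    parts: list[ProteinRecord] = []
    for k, start in enumerate(range(0, record.length, max_len)):
        stop = min(start + max_len, record.length)
        parts.append(
            ProteinRecord(
                id=f"{record.id}_part{k + 1}",
                aa_onehot=record.aa_onehot[start:stop].copy(),
                pssm=record.pssm[start:stop].copy(),
                labels=None if record.labels is None else record.labels[start:stop].copy(),
            )
        )
    return parts


def to_fasta(dataset: Dataset, aa_letters: str = AA_LETTERS) -> str:
    """Export a Dataset as standard FASTA text (60-column wrapped).

    Zero-length records are omitted with a warning.  Decoding uses the
    layout's amino-acid letter order.
    """
    seqrecs = []
    for rec in dataset.records:
        if rec.length == 0:
            warnings.warn(f"protein {rec.id!r} empty after masking; omitted from FASTA")
            logger.warning("protein %r empty after masking; omitted from FASTA", rec.id)
            continue
        seqrecs.append(SeqRecord(Seq(rec.sequence(aa_letters)), id=rec.id, description=""))
    buf = io.StringIO()
    seqio_write(seqrecs, buf, "fasta")
    return buf.getvalue()


def sequence_to_onehot(seq: str, aa_letters: str = AA_LETTERS) -> np.ndarray:
    """Encode a letter sequence as an L x len(aa_letters) one-hot matrix."""
    idx = []
    for pos, ch in enumerate(seq):
        j = aa_letters.find(ch)
        if j < 0:
            raise ValidationError(f"letter {ch!r} at position {pos + 1} not in amino-acid map")
        idx.append(j)
    out = np.zeros((len(seq), len(aa_letters)))
    out[np.arange(len(seq)), idx] = 1.0
    return out


def summarize_public_cb513(path: str | Path, layout: CBLayout = CB57_LAYOUT) -> dict:
    """Summary statistics of a public CB513 release file.

    Reports the number of residues in each structure class and the
    number of full-length (700-residue) records; in the public release
    exactly one protein exceeded 700 residues and was stored split, so
    exactly one record is full length.
    """
    ds = read_cb_matrix(path, layout=layout)
    counts = {s: 0 for s in layout.classes}
    for rec in ds:
        for k in rec.labels:
            counts[layout.classes.symbol(int(k))] += 1
    return {
        "n_proteins": len(ds),
        "class_counts": counts,
        "n_full_length": sum(1 for r in ds if r.length == MAX_LEN),
    }
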