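"""Eight-state evaluation metrics.

All metrics pool residues across proteins (micro-average).  Q8
accuracy is the fraction of residues whose predicted state matches the
truth:

    Q8 = sum_i correct(i) / sum_i n(i),   i in {B,E,G,H,I,L,S,T}

Per-class precision TP/(TP+FP) and recall TP/(TP+FN) with a 0/0
denominator are reported as a distinct *undefined* marker (rendered as
a dash), never as 0 or NaN — a class absent from both truth and
prediction simply has nothing to measure.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

from .alphabet import DEFAULT_ALPHABET, ClassAlphabet
from .errors import ValidationError

DASH = "-"


def _pool(pred, true, mask):
    """Flatten (lists of) per-protein label vectors into pooled arrays."""
    if isinstance(pred, np.ndarray) and pred.ndim == 1:
        pred, true = [pred], [true]
        mask = None if mask is None else [mask]
    elif isinstance(pred, dict):
        keys = sorted(pred)
        if sorted(true) != keys:
            raise ValidationError("prediction and truth protein ids differ")
        pred = [np.asarray(pred[k]) for k in keys]
        true = [np.asarray(true[k]) for k in keys]
        mask = None if mask is None else [np.asarray(mask[k]) for k in keys]
    ps, ts = [], []
    for i, (p, t) in enumerate(zip(pred, true)):
        p = np.asarray(p).ravel()
        t = np.asarray(t).ravel()
        if p.shape != t.shape:
            raise ValidationError(f"prediction/truth length mismatch in protein #{i}")
        if mask is not None:
            m = np.asarray(mask[i], dtype=bool).ravel()
            if m.shape != p.shape:
                raise ValidationError(f"mask length mismatch in protein #{i}")
            p, t = p[m], t[m]
        ps.append(p)
        ts.append(t)
    if not ps:
        raise ValidationError("no residues to score")
    return np.concatenate(ps).astype(np.int64), np.concatenate(ts).astype(np.int64)


def q8_accuracy(pred_labels, true_labels, mask=None) -> float:
    """Pooled eight-state accuracy over all masked-in residues.

    Accepts single label vectors, lists of per-protein vectors, or
    ``{protein id: vector}`` dicts (prediction and truth keyed alike).
    Raises instead of returning NaN when no residue is masked in.
    """
    p, t = _pool(pred_labels, true_labels, mask)
    if p.size == 0:
        raise ValidationError("zero masked-in residues; Q8 undefined")
    return float(np.mean(p == t))


@dataclass
class ClassTally:
    """Per-class TP/FP/FN counts pooled over all residues."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.tp + self.fn

    @classmethod
    def from_labels(cls, pred, true, mask=None, n_classes: int = 8) -> "ClassTally":
        p, t = _pool(pred, true, mask)
        conf = confusion_counts(p, t, n_classes=n_classes)
        tp = np.diag(conf).copy()
        return cls(tp=tp, fp=conf.sum(axis=0) - tp, fn=conf.sum(axis=1) - tp)


def confusion_counts(pred, true, mask=None, n_classes: int = 8) -> np.ndarray:
    """Unnormalized confusion matrix: entry (i, j) counts true-i predicted-j."""
    p, t = _pool(pred, true, mask)
    return np.bincount(t * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes
    )


def confusion_matrix(pred, true, mask=None, normalize: str = "row", n_classes: int = 8):
    """Confusion matrix, row-normalized by default.

    With ``normalize="row"`` entry (i, j) is the fraction of true-class-i
    residues predicted as j; rows of classes absent from the truth are
    NaN and flagged by the returned ``defined`` vector.  Returns
    ``(matrix, defined_rows)``; with ``normalize="none"`` the raw count
    matrix is returned alone.
    """
    counts = confusion_counts(pred, true, mask, n_classes=n_classes)
    if normalize == "none":
        return counts
    if normalize != "row":
        raise ValueError(f"unknown normalization {normalize!r}")
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    out = np.full(counts.shape, np.nan)
    out[defined] = counts[defined] / row_sums[defined, None]
    return out, defined


@dataclass
class MetricsReport:
    """Q8, per-class precision/recall and the row-normalized confusion matrix.

    Undefined (0/0) precision or recall entries are ``None``.
    """

    q8: float
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    confusion: np.ndarray
    confusion_defined: np.ndarray
    n_residues: int
    alphabet: ClassAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def to_dict(self) -> dict:
        return {
            "q8": self.q8,
            "n_residues": self.n_residues,
            "precision": dict(self.precision),
            "recall": dict(self.recall),
            "confusion": [
                [None if np.isnan(v) else float(v) for v in row] for row in self.confusion
            ],
        }

    def format_text(self) -> str:
        lines = [f"Q8 accuracy: {self.q8:.4f}  ({self.n_residues} residues)", ""]
        lines.append(f"{'class':>5}  {'precision':>9}  {'recall':>9}")
        for s in self.alphabet:
            pr = DASH if self.precision[s] is None else f"{self.precision[s]:.4f}"
            rc = DASH if self.recall[s] is None else f"{self.recall[s]:.4f}"
            lines.append(f"{s:>5}  {pr:>9}  {rc:>9}")
        return "\n".join(lines)

    def confusion_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["true\\pred", *self.alphabet.labels])
        for i, s in enumerate(self.alphabet):
            if self.confusion_defined[i]:
                w.writerow([s, *(f"{v:.6f}" for v in self.confusion[i])])
            else:
                w.writerow([s, *([DASH] * 8)])
        return buf.getvalue()


def per_class_precision_recall(
    pred_labels, true_labels, mask=None, alphabet: ClassAlphabet = DEFAULT_ALPHABET
) -> MetricsReport:
    """Full pooled metrics report for one prediction/truth pairing."""
    p, t = _pool(pred_labels, true_labels, mask)
    tally = ClassTally.from_labels(p, t)
    conf, defined = confusion_matrix(p, t)
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    for k, s in enumerate(alphabet):
        pd = tally.tp[k] + tally.fp[k]
        rd = tally.tp[k] + tally.fn[k]
        precision[s] = None if pd == 0 else float(tally.tp[k] / pd)
        recall[s] = None if rd == 0 else float(tally.tp[k] / rd)
    return MetricsReport(
        q8=float(np.mean(p == t)),
        precision=precision,
        recall=recall,
        confusion=conf,
        confusion_defined=defined,
        n_residues=int(p.size),
        alphabet=alphabet,
    )
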