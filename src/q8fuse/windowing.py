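"""Fixed-size sliding windows centered on each residue.

Local residue classifiers see a window of ``size`` residues (``size``
odd) centered on the residue to classify; positions falling before the
first or after the last residue are filled with all-zero feature rows,
the same convention the padded datasets use.  Windows never cross
protein boundaries: each record is padded independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import ProteinRecord

#: Window sizes used by the sliding-window classifiers: 9 (4 residues of
#: context on each side) up to 17.
DEFAULT_SIZES = (9, 11, 13, 15, 17)

_SELECTORS = ("aa", "pssm", "both")


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry and feature selection.

    ``size`` must be odd so the window has a unique central residue;
    ``half`` context residues flank it on each side.
    """

    size: int
    features: str = "both"

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"window size must be an odd integer >= 1, got {self.size}")
        if self.features not in _SELECTORS:
            raise ValueError(f"features must be one of {_SELECTORS}, got {self.features!r}")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2


def _select(record: ProteinRecord, features: str) -> np.ndarray:
    if features == "aa":
        return record.aa_onehot
    if features == "pssm":
        return record.pssm
    return np.concatenate([record.aa_onehot, record.pssm], axis=1)


def extract_windows(record: ProteinRecord, spec: WindowSpec):
    """Extract one zero-padded window per residue.

    Returns ``(windows, labels)`` where ``windows`` has shape
    ``(L, size, F)`` — window ``i`` is centered on residue ``i`` — and
    ``labels`` is the record's label vector (``None`` if unlabeled).
    """
    feats = _select(record, spec.features)
    L, F = feats.shape
    h = spec.half
    padded = np.zeros((L + 2 * h, F), dtype=feats.dtype)
    padded[h : h + L] = feats
    windows = np.stack([padded[i : i + spec.size] for i in range(L)])
    return windows, (None if record.labels is None else record.labels.copy())


def windows_table(record: ProteinRecord, spec: WindowSpec) -> np.ndarray:
    """Flat export: one row per residue, ``size * F`` feature columns."""
    windows, _ = extract_windows(record, spec)
    return windows.reshape(record.length, -1)
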