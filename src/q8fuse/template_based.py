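"""Template-based secondary-structure prediction by alignment voting.

Structure labels are transferred from retrieved alignments against a
reference of proteins with experimentally solved structures.  Two
predictors share the machinery and differ only in thresholds:

* **specific alignments** — only good hits: the first 10 hits with
  E-value <= 1e-5, rank-weighted 10, 9, ..., 1.  Residues no qualifying
  alignment covers abstain (all-zero probability row).
* **general alignments** — permissive: the first 100 hits with
  E-value <= 10, rank-weighted 100, 99, ..., 1, followed by a local
  search: a residue left uncovered borrows the tally of the nearest
  covered residue inside a centered window (201 positions by default),
  and the window grows until one is found.  This predictor labels
  every residue whenever at least one residue is covered.

Each hit contributes its weight to the subject's structure symbol at
every aligned residue pair; per-residue tallies normalize to
probability rows, so both predictors plug directly into the GA
ensemble as ordinary classifiers.
"""

from __future__ import annotations


import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .alphabet import DEFAULT_ALPHABET, ClassAlphabet
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default BLAST-style tabular columns (outfmt "6 qseqid sseqid evalue
#: qstart qend sstart send qseq sseq"); qseq/sseq are the *gapped*
#: aligned sequences, without which residue pairing is impossible.
TABULAR_FIELDS = ("qseqid", "sseqid", "evalue", "qstart", "qend", "sstart", "send", "qseq", "sseq")

_REQUIRED = ("qseqid", "sseqid", "evalue", "qstart", "sstart", "qseq", "sseq")


@dataclass
class TemplateDB:
    """Reference map: subject id -> secondary-structure string.

    One symbol of the eight-state alphabet per subject residue;
    subject sequences are optional and, when present, must match the
    structure string in length.
    """

    ss: dict[str, str]
    sequences: dict[str, str] | None = None
    alphabet: ClassAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        for sid, s in self.ss.items():
            bad = set(s) - set(self.alphabet.labels)
            if bad:
                raise ValidationError(f"subject {sid!r}: unknown structure symbols {sorted(bad)}")
            if self.sequences and sid in self.sequences and len(self.sequences[sid]) != len(s):
                raise ValidationError(
                    f"subject {sid!r}: sequence length {len(self.sequences[sid])} != "
                    f"structure string length {len(s)}"
                )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for sid, s in self.ss.items():
            seq = (self.sequences or {}).get(sid, "")
            rows.append(f"{sid}\t{seq}\t{s}")
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, alphabet: ClassAlphabet = DEFAULT_ALPHABET) -> "TemplateDB":
        ss: dict[str, str] = {}
        seqs: dict[str, str] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{ln}: expected 3 tab-separated columns")
            sid, seq, s = parts
            ss[sid] = s
            if seq:
                seqs[sid] = seq
        return cls(ss=ss, sequences=seqs or None, alphabet=alphabet)


@dataclass
class TemplateHit:
    """One retrieved alignment.

    ``aligned_pairs`` lists (query position, subject position) residue
    pairs, 0-based, strictly increasing in both coordinates — gap
    columns are excluded by construction.  ``rank`` is the 1-based
    retrieval order after self-hit removal.
    """

    query_id: str
    subject_id: str
    evalue: float
    rank: int
    aligned_pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"hit {self.subject_id!r}: negative E-value")
        prev_q, prev_s = -1, -1
        for q, s in self.aligned_pairs:
            if q <= prev_q or s <= prev_s:
                raise ValidationError(
                    f"hit {self.subject_id!r}: aligned pairs not strictly increasing"
                )
            prev_q, prev_s = q, s


def walk_alignment(qseq: str, sseq: str, qstart: int = 0, sstart: int = 0) -> list[tuple[int, int]]:
    """Residue pairs from two gapped alignment strings walked in lockstep.

    A pair is emitted only where both columns hold residues; ``qstart``
    and ``sstart`` are the 0-based coordinates of the first residue of
    each string.
    """
    if len(qseq) != len(sseq):
        raise FormatError(
            f"aligned strings of unequal length ({len(qseq)} vs {len(sseq)})"
        )
    pairs: list[tuple[int, int]] = []
    qi, si = qstart, sstart
    for qc, sc in zip(qseq, sseq):
        qgap, sgap = qc == "-", sc == "-"
        if not qgap and not sgap:
            pairs.append((qi, si))
        if not qgap:
            qi += 1
        if not sgap:
            si += 1
    return pairs


def parse_hits(
    source: str | Path | TextIO,
    query_id: str,
    fields: Sequence[str] = TABULAR_FIELDS,
    drop_identical: bool = False,
) -> list[TemplateHit]:
    """Parse tabular alignment-search output into ranked hits for one query.

    ``source`` is BLAST-style tab-separated text (path or handle) whose
    columns are named by ``fields`` and must include the gapped aligned
    sequences (``qseq``/``sseq``) plus 1-based ``qstart``/``sstart``.
    Hits whose subject id equals the query id are removed (the query
    itself may sit in the reference database) and ranks are reassigned
    so the numbering stays gapless; ``drop_identical`` additionally
    removes 100%-identity full-coverage hits.
    """
    missing = [c for c in _REQUIRED if c not in fields]
    if missing:
        raise FormatError(f"tabular input must carry columns {missing} (have {list(fields)})")
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t", names=list(fields), comment="#", dtype=str)
    else:
        df = pd.read_csv(source, sep="\t", names=list(fields), comment="#", dtype=str)
    hits: list[TemplateHit] = []
    for _, row in df.iterrows():
        if row["qseqid"] != query_id:
            continue
        sid = row["sseqid"]
        if sid == query_id:
            continue
        qseq, sseq = row["qseq"], row["sseq"]
        if not isinstance(qseq, str) or not isinstance(sseq, str):
            raise FormatError(f"hit {sid!r}: missing aligned sequence columns qseq/sseq")
        if len(qseq) != len(sseq):
            raise FormatError(
                f"hit {sid!r}: aligned strings of unequal length "
                f"({len(qseq)} vs {len(sseq)})"
            )
        if drop_identical and qseq == sseq and "-" not in qseq:
            continue
        pairs = walk_alignment(qseq, sseq, int(row["qstart"]) - 1, int(row["sstart"]) - 1)
        hits.append(
            TemplateHit(
                query_id=query_id,
                subject_id=sid,
                evalue=float(row["evalue"]),
                rank=len(hits) + 1,
                aligned_pairs=pairs,
            )
        )
    return hits


def parse_hits_xml(source: str | Path | TextIO, query_id: str) -> list[TemplateHit]:
    """Parse BLAST XML output into ranked hits for one query.

    One hit is emitted per HSP, in file order; self-hits are removed
    and ranks reassigned, as in :func:`parse_hits`.
    """
    from Bio.Blast import NCBIXML

    close = False
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
    try:
        hits: list[TemplateHit] = []
        for record in NCBIXML.parse(handle):
            rec_query = record.query.split()[0] if record.query else ""
            if rec_query and rec_query != query_id:
                continue
            for aln in record.alignments:
                sid = aln.hit_def.split()[0] if aln.hit_def else aln.hit_id
                if sid == query_id:
                    continue
                for hsp in aln.hsps:
                    pairs = walk_alignment(
                        hsp.query, hsp.sbjct, hsp.query_start - 1, hsp.sbjct_start - 1
                    )
                    hits.append(
                        TemplateHit(
                            query_id=query_id,
                            subject_id=sid,
                            evalue=float(hsp.expect),
                            rank=len(hits) + 1,
                            aligned_pairs=pairs,
                        )
                    )
        return hits
    finally:
        if close:
            handle.close()


@dataclass
class VoteTally:
    """Per-residue accumulated class votes for one query protein."""

    votes: np.ndarray  # (L, 8) non-negative
    alphabet: ClassAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    @property
    def covered(self) -> np.ndarray:
        """Boolean coverage flag per residue (any vote mass)."""
        return self.votes.sum(axis=1) > 0


def _vote(
    hits: Iterable[TemplateHit],
    db: TemplateDB,
    length: int,
    max_hits: int,
    evalue_max: float,
    alphabet: ClassAlphabet,
) -> VoteTally:
    """Shared rank-weighted voting core.

    The E-value filter (and removal of hits whose subject the reference
    lacks) is applied *first*; the ``max_hits`` best survivors are then
    re-ranked 1..max_hits so a failing hit never wastes a slot, and the
    hit at kept-rank r contributes weight ``max_hits + 1 - r``.
    """
    votes = np.zeros((length, 8))
    kept = 0
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        if hit.subject_id not in db.ss:
            warnings.warn(f"subject {hit.subject_id!r} absent from template reference; skipped")
            continue
        kept += 1
        if kept > max_hits:
            break
        weight = max_hits + 1 - kept
        ss = db.ss[hit.subject_id]
        for q, s in hit.aligned_pairs:
            if not (0 <= q < length):
                raise ValidationError(
                    f"hit {hit.subject_id!r}: query position {q} outside protein of length {length}"
                )
            if not (0 <= s < len(ss)):
                raise ValidationError(
                    f"hit {hit.subject_id!r}: subject position {s} outside structure string"
                )
            votes[q, alphabet.index_of(ss[s])] += weight
    return VoteTally(votes=votes, alphabet=alphabet)


def vote_specific(
    hits: Iterable[TemplateHit],
    db: TemplateDB,
    length: int,
    max_hits: int = 10,
    evalue_max: float = 1e-5,
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
) -> VoteTally:
    """Specific-alignments tally: first 10 hits at E <= 1e-5, weights 10..1.

    Residues no qualifying alignment covers keep a zero vote vector and
    will abstain after normalization.
    """
    return _vote(hits, db, length, max_hits, evalue_max, alphabet)


def vote_general(
    hits: Iterable[TemplateHit],
    db: TemplateDB,
    length: int,
    max_hits: int = 100,
    evalue_max: float = 10.0,
    window_init: int = 201,
    window_growth: int = 200,
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
) -> VoteTally:
    """General-alignments tally: first 100 hits at E <= 10, weights 100..1,
    then local search for uncovered residues.

    An uncovered residue borrows (copies) the tally of the nearest
    covered residue within a centered window of ``window_init``
    positions; if the window holds none it is enlarged by
    ``window_growth`` positions per round until one is found, so every
    residue is labelled whenever at least one residue is covered.  Two
    covered residues at equal distance have their tallies averaged.
    Borrowed tallies never propagate further.  A query with no covered
    residue at all returns a fully abstaining tally with a warning.
    """
    tally = _vote(hits, db, length, max_hits, evalue_max, alphabet)
    covered = tally.covered
    if not covered.any():
        warnings.warn(
            "general-alignments predictor found no covered residue; abstaining everywhere"
        )
        return tally
    if covered.all():
        return tally
    cov_idx = np.flatnonzero(covered)
    out = tally.votes.copy()
    half = (window_init - 1) // 2
    grow = window_growth // 2
    for i in np.flatnonzero(~covered):
        pos = np.searchsorted(cov_idx, i)
        left = cov_idx[pos - 1] if pos > 0 else None
        right = cov_idx[pos] if pos < cov_idx.size else None
        d_left = i - left if left is not None else np.inf
        d_right = right - i if right is not None else np.inf
        # the window only ever expands, so the eventual winner is the
        # nearest covered residue; expansion rounds affect nothing else
        reach = half
        while min(d_left, d_right) > reach:
            reach += grow
        if d_left < d_right:
            out[i] = tally.votes[left]
        elif d_right < d_left:
            out[i] = tally.votes[right]
        else:
            out[i] = (tally.votes[left] + tally.votes[right]) / 2.0
    return VoteTally(votes=out, alphabet=alphabet)


def tally_to_probabilities(tally: VoteTally) -> np.ndarray:
    """Normalize a tally to an L x 8 probability matrix.

    Covered rows are divided by their vote mass (so they sum to 1);
    uncovered rows stay all-zero (abstention).
    """
    totals = tally.votes.sum(axis=1, keepdims=True)
    out = np.zeros_like(tally.votes, dtype=np.float64)
    np.divide(tally.votes, totals, out=out, where=totals > 0)
    return out


def predict_template(
    hits_per_query: Mapping[str, list[TemplateHit]],
    db: TemplateDB,
    lengths: Mapping[str, int],
    mode: str = "specific",
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
    **thresholds,
) -> dict[str, np.ndarray]:
    """Run one template predictor over a set of queries.

    Returns ``{query id: (L, 8) probability matrix}`` suitable for
    :meth:`q8fuse.ga_ensemble.PredictionSet.from_matrices`.
    """
    if mode not in ("specific", "general"):
        raise ValueError(f"mode must be 'specific' or 'general', got {mode!r}")
    voter = vote_specific if mode == "specific" else vote_general
    out = {}
    for qid, L in lengths.items():
        tally = voter(hits_per_query.get(qid, []), db, L, alphabet=alphabet, **thresholds)
        out[qid] = tally_to_probabilities(tally)
    return out
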