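"""Synthetic fixtures: toy datasets, planted-skill predictions, fabricated hits.

Everything downstream of the upstream classifiers and the alignment
search is testable without trained models, real datasets, or a
structure database: this module fabricates

* toy protein datasets with the characteristic eight-state class
  imbalance (loop, alpha helix and strand dominate; pi helix is rare),
  amino acids drawn conditionally on the structure label so windows
  carry real signal, and PSSM rows that are label-blurred one-hots;
* planted-skill classifier outputs — per-class accuracies are chosen
  per classifier, so complementary ensembles with a known optimum can
  be constructed;
* synthetic retrieval results: subjects are mutated copies of query
  substrings with structure strings copied from the truth (corrupted
  only at mutated positions) and E-values growing with mutation load,
  so a mutation-free database makes template voting exactly recover
  the truth.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import AA_LETTERS, DEFAULT_ALPHABET, ClassAlphabet
from .dataset_io import Dataset, ProteinRecord
from .errors import ValidationError
from .ga_ensemble import PredictionSet
from .template_based import TemplateDB, TemplateHit

#: Default class frequencies in B,E,G,H,I,L,S,T order, mimicking the
#: imbalance of real eight-state assignments: loop/helix/strand
#: dominate, pi helix (I) is vanishingly rare.
DEFAULT_CLASS_FREQS = (0.011, 0.210, 0.039, 0.340, 0.002, 0.200, 0.085, 0.113)

#: Error-spill map over class indices (B,E,G,H,I,L,S,T): errors land on
#: the structurally confusable partner — bridge<->strand, 3-10
#: helix<->alpha helix, pi helix->alpha helix, bend/turn<->loop.
CONFUSABLE = {0: (1,), 1: (0,), 2: (3,), 3: (2,), 4: (3,), 5: (6, 7), 6: (5,), 7: (5,)}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_toy_dataset(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (30, 120),
    class_freqs: Sequence[float] = DEFAULT_CLASS_FREQS,
    seed: int | np.random.Generator = 0,
    split_tag: str = "validation",
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
) -> Dataset:
    """Generate a labelled toy dataset.

    Labels are i.i.d. from ``class_freqs``; each structure class
    prefers a small set of amino-acid letters (chosen with probability
    0.6, else uniform over the 20 standard letters), so sequence
    windows are informative about the label.  PSSM rows are the
    residue's one-hot blurred with Dirichlet noise.  Lengths are
    uniform over ``length_range`` inclusive.
    """
    rng = _rng(seed)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"bad length range {length_range}")
    freqs = np.asarray(class_freqs, dtype=np.float64)
    if freqs.shape != (8,) or abs(freqs.sum() - 1.0) > 1e-6 or freqs.min() < 0:
        raise ValidationError("class_freqs must be 8 non-negative values summing to 1")

    # class k prefers letters {2k, 2k+1} mod 20 — arbitrary but fixed,
    # enough to give windows mutual information with the label
    preferred = {k: ((2 * k) % 20, (2 * k + 1) % 20) for k in range(8)}
    records = []
    for i in range(n_proteins):
        L = int(rng.integers(lo, hi + 1))
        labels = rng.choice(8, size=L, p=freqs)
        aa_idx = np.empty(L, dtype=np.int64)
        use_pref = rng.random(L) < 0.6
        for j in range(L):
            if use_pref[j]:
                aa_idx[j] = rng.choice(preferred[labels[j]])
            else:
                aa_idx[j] = rng.integers(0, 20)
        onehot = np.zeros((L, 21))
        onehot[np.arange(L), aa_idx] = 1.0
        noise = rng.dirichlet(np.full(21, 0.3), size=L)
        pssm = 0.7 * onehot + 0.3 * noise
        rec = ProteinRecord(id=f"syn_{i:04d}", aa_onehot=onehot, pssm=pssm, labels=labels)
        records.append(rec)
    ds = Dataset(records=records, split_tag=split_tag)
    ds.validate()
    return ds


@dataclass(frozen=True)
class SkillProfile:
    """Planted per-class skill of one synthetic classifier.

    ``accuracy[k]`` is the probability that the classifier's peaked
    class equals the truth when the true class is k; errors land on a
    spill class — by default the confusable partner, or uniformly over
    the other seven with ``spill="uniform"``.  ``peak`` (> 0.5) is the
    probability mass put on the peaked class, which therefore always
    wins the row's argmax.
    """

    name: str
    accuracy: tuple[float, ...]
    spill: str = "confusable"
    peak: float = 0.7

    def __post_init__(self) -> None:
        if len(self.accuracy) != 8 or not all(0.0 <= a <= 1.0 for a in self.accuracy):
            raise ValidationError("accuracy must be 8 values in [0, 1]")
        if self.spill not in ("confusable", "uniform"):
            raise ValidationError(f"unknown spill rule {self.spill!r}")
        if not 0.5 < self.peak <= 1.0:
            raise ValidationError("peak must be in (0.5, 1] so the peaked class wins the argmax")

    @classmethod
    def uniform(cls, name: str, accuracy: float, **kw) -> "SkillProfile":
        return cls(name=name, accuracy=(accuracy,) * 8, **kw)

    @classmethod
    def reliable_on(
        cls, name: str, classes: Sequence[str], high: float = 0.9, low: float = 0.3,
        alphabet: ClassAlphabet = DEFAULT_ALPHABET, **kw,
    ) -> "SkillProfile":
        """High accuracy on the named classes, low elsewhere."""
        acc = [low] * 8
        for s in classes:
            acc[alphabet.index_of(s)] = high
        return cls(name=name, accuracy=tuple(acc), **kw)


def make_planted_predictions(
    dataset: Dataset,
    profiles: Sequence[SkillProfile],
    seed: int | np.random.Generator = 0,
) -> PredictionSet:
    """Fabricate per-classifier probability matrices with planted skill.

    For classifier c at a residue of true class k: with probability
    ``accuracy[k]`` the row is peaked on k, otherwise on a spill class;
    the peaked class gets ``peak`` mass and the remainder is Dirichlet
    noise over all eight classes, so rows sum to 1 and the peak always
    wins the argmax.
    """
    rng = _rng(seed)
    matrices: dict[str, dict[str, np.ndarray]] = {p.name: {} for p in profiles}
    if len(matrices) != len(profiles):
        raise ValidationError("profile names must be distinct")
    for rec in dataset:
        if rec.labels is None:
            raise ValidationError(f"protein {rec.id!r} has no labels")
        L = rec.length
        for prof in profiles:
            acc = np.asarray(prof.accuracy)[rec.labels]
            correct = rng.random(L) < acc
            target = rec.labels.copy()
            for j in np.flatnonzero(~correct):
                k = rec.labels[j]
                if prof.spill == "uniform":
                    others = [c for c in range(8) if c != k]
                    target[j] = rng.choice(others)
                else:
                    target[j] = rng.choice(CONFUSABLE[int(k)])
            noise = rng.dirichlet(np.ones(8), size=L)
            rows = (1.0 - prof.peak) * noise
            rows[np.arange(L), target] += prof.peak
            matrices[prof.name][rec.id] = rows
    pset = PredictionSet.from_matrices(matrices)
    pset.validate(lengths={r.id: r.length for r in dataset})
    return pset


def make_synthetic_hits(
    dataset: Dataset,
    db_size: int = 5,
    mutation_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    class_freqs: Sequence[float] = DEFAULT_CLASS_FREQS,
    alphabet: ClassAlphabet = DEFAULT_ALPHABET,
) -> tuple[TemplateDB, dict[str, list[TemplateHit]]]:
    """Fabricate a template reference and per-query retrieval results.

    Each query gets ``db_size`` subjects: the first is a full-length
    copy of the query, the rest cover random substrings.  Point
    mutations at ``mutation_rate`` corrupt both the amino-acid letter
    and the structure symbol (resampled from ``class_freqs``), so the
    structure transferred from heavily mutated templates is
    uninformative.  E-values grow with mutation load and shrink with
    coverage; hits are returned ranked by strictly ascending E-value.
    """
    rng = _rng(seed)
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValidationError("mutation_rate must be in [0, 1]")
    freqs = np.asarray(class_freqs, dtype=np.float64)
    freqs = freqs / freqs.sum()
    ss_db: dict[str, str] = {}
    seq_db: dict[str, str] = {}
    hits: dict[str, list[TemplateHit]] = {}
    for rec in dataset:
        if rec.labels is None:
            raise ValidationError(f"protein {rec.id!r} has no labels")
        L = rec.length
        qseq = rec.sequence()
        raw = []
        for j in range(db_size):
            if j == 0:
                start, stop = 0, L
            else:
                span = int(rng.integers(max(1, min(10, L)), L + 1))
                start = int(rng.integers(0, L - span + 1))
                stop = start + span
            sub_seq = list(qseq[start:stop])
            sub_ss = [alphabet.symbol(int(k)) for k in rec.labels[start:stop]]
            mutated = rng.random(stop - start) < mutation_rate
            for pos in np.flatnonzero(mutated):
                sub_seq[pos] = AA_LETTERS[int(rng.integers(0, 20))]
                sub_ss[pos] = alphabet.symbol(int(rng.choice(8, p=freqs)))
            mut_frac = float(mutated.mean())
            coverage = (stop - start) / L
            # exact full-length copies sit at 1e-30; heavy mutation or
            # poor coverage pushes E toward (and past) the loose cutoff
            exponent = -30.0 * (1.0 - mut_frac) * coverage + 1e-6 * j
            sid = f"{rec.id}|tpl{j}"
            ss_db[sid] = "".join(sub_ss)
            seq_db[sid] = "".join(sub_seq)
            raw.append((10.0 ** exponent, sid, start, stop))
        raw.sort(key=lambda t: t[0])
        hits[rec.id] = [
            TemplateHit(
                query_id=rec.id,
                subject_id=sid,
                evalue=ev,
                rank=r + 1,
                aligned_pairs=[(q, q - start) for q in range(start, stop)],
            )
            for r, (ev, sid, start, stop) in enumerate(raw)
        ]
    return TemplateDB(ss=ss_db, sequences=seq_db, alphabet=alphabet), hits


def write_hits_tabular(
    hits_per_query: Mapping[str, list[TemplateHit]],
    db: TemplateDB,
    dataset: Dataset,
    path: str | Path,
) -> None:
    """Write synthetic (ungapped) hits as BLAST-style tabular text.

    Columns follow :data:`q8fuse.template_based.TABULAR_FIELDS`, so the
    file round-trips through :func:`q8fuse.template_based.parse_hits`.
    """
    if db.sequences is None:
        raise ValidationError("template reference carries no subject sequences")
    lines = []
    for rec in dataset:
        qseq = rec.sequence()
        for hit in hits_per_query.get(rec.id, []):
            qs, ss_ = hit.aligned_pairs[0], hit.aligned_pairs[-1]
            q0, s0 = qs
            q1, s1 = ss_
            lines.append(
                "\t".join(
                    [
                        hit.query_id,
                        hit.subject_id,
                        f"{hit.evalue:.3e}",
                        str(q0 + 1),
                        str(q1 + 1),
                        str(s0 + 1),
                        str(s1 + 1),
                        qseq[q0 : q1 + 1],
                        db.sequences[hit.subject_id][s0 : s1 + 1],
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
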