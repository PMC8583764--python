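"""Genetic-algorithm weighted-voting fusion of per-residue class probabilities.

Each upstream classifier ``c`` contributes, per protein, an ``L x 8``
matrix of class probabilities.  The ensemble assigns one voting weight
``w[c, k]`` in [0, 1] per classifier per class and labels each residue

    argmax_k  sum_c  w[c, k] * p_c[k]

so the search space for ``C`` classifiers is ``C x 8`` weights (five
classifiers -> forty weights).  Weights are learned on a validation
split by an elitist genetic algorithm: a population of 2000 random
individuals; per generation the 100 fittest (highest pooled Q8) are
kept, 900 offspring are created by uniform crossover between them, and
those 1000 then each spawn one Gaussian mutant, restoring 2000.  Each
newly created individual is rescaled so its largest weight is 1 (the
labelling is scale-invariant, so this only canonicalizes).  The run
stops after 1000 generations or 50 generations without a strictly
better best-ever Q8, and is followed by a local-search phase in which
the top 100 individuals are refined with small mutations under the
same stopping rule.

The initial population is augmented with one "selector" individual per
classifier (weight 1 on all of that classifier's classes, 0 elsewhere);
with elitism this guarantees the fused validation Q8 is never below
the best single classifier's.

Abstention rows — all-zero probability rows emitted by a template
predictor with no qualifying alignment — contribute nothing to any
class score and therefore simply do not vote.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .alphabet import DEFAULT_ALPHABET, ClassAlphabet
from .errors import ValidationError

logger = logging.getLogger(__name__)

_ROW_ATOL = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class PredictionSet:
    """Per-classifier stacks of L x 8 probability matrices.

    ``probs`` maps protein id to an array of shape ``(C, L, 8)`` whose
    first axis follows ``classifier_ids``.  Every row either sums to 1
    or is all-zero (abstention).
    """

    classifier_ids: tuple[str, ...]
    probs: dict[str, np.ndarray]

    @property
    def n_classifiers(self) -> int:
        return len(self.classifier_ids)

    @classmethod
    def from_matrices(
        cls, matrices: Mapping[str, Mapping[str, np.ndarray]]
    ) -> "PredictionSet":
        """Build from ``{classifier id: {protein id: (L, 8) matrix}}``."""
        cids = tuple(matrices)
        pids = list(next(iter(matrices.values())))
        probs = {}
        for pid in pids:
            mats = []
            for cid in cids:
                if pid not in matrices[cid]:
                    raise ValidationError(f"classifier {cid!r} missing protein {pid!r}")
                mats.append(np.asarray(matrices[cid][pid], dtype=np.float64))
            probs[pid] = np.stack(mats)
        return cls(classifier_ids=cids, probs=probs)

    def matrix(self, classifier_id: str, protein_id: str) -> np.ndarray:
        return self.probs[protein_id][self.classifier_ids.index(classifier_id)]

    def validate(self, lengths: Mapping[str, int] | None = None) -> None:
        C = self.n_classifiers
        for pid, arr in self.probs.items():
            if arr.ndim != 3 or arr.shape[0] != C or arr.shape[2] != 8:
                raise ValidationError(f"protein {pid!r}: prediction stack shape {arr.shape}")
            if lengths is not None:
                if pid not in lengths:
                    raise ValidationError(f"protein {pid!r} not in the reference dataset")
                if arr.shape[1] != lengths[pid]:
                    raise ValidationError(
                        f"protein {pid!r}: {arr.shape[1]} prediction rows for "
                        f"{lengths[pid]} residues"
                    )
            sums = arr.sum(axis=2)
            ok = (np.abs(sums - 1.0) <= _ROW_ATOL) | (sums == 0.0)
            if not ok.all():
                c, i = np.argwhere(~ok)[0]
                raise ValidationError(
                    f"protein {pid!r}, classifier {self.classifier_ids[c]!r}: "
                    f"row {i} sums to {sums[c, i]:.6f} (must be 1 or all-zero)"
                )
        if lengths is not None:
            missing = set(lengths) - set(self.probs)
            if missing:
                raise ValidationError(f"predictions missing for proteins {sorted(missing)}")

    def argmax_labels(self, classifier_id: str) -> dict[str, np.ndarray]:
        """One classifier's own argmax labelling (ties -> lowest class index)."""
        c = self.classifier_ids.index(classifier_id)
        return {pid: arr[c].argmax(axis=1) for pid, arr in self.probs.items()}


def write_prediction_files(
    pset: PredictionSet, out_dir: str | Path, alphabet: ClassAlphabet = DEFAULT_ALPHABET
) -> dict[str, Path]:
    """Write one TSV per classifier: protein_id, residue_index, p_<class>...

    Residue indices are 0-based.  Returns ``{classifier id: path}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cols = [f"p_{s}" for s in alphabet]
    for c, cid in enumerate(pset.classifier_ids):
        frames = []
        for pid in pset.probs:
            arr = pset.probs[pid][c]
            df = pd.DataFrame(arr, columns=cols)
            df.insert(0, "residue_index", np.arange(arr.shape[0]))
            df.insert(0, "protein_id", pid)
            frames.append(df)
        path = out_dir / f"{cid}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.8g")
        paths[cid] = path
    return paths


def read_prediction_files(
    files: Mapping[str, str | Path], alphabet: ClassAlphabet = DEFAULT_ALPHABET
) -> PredictionSet:
    """Read ``{classifier id: TSV path}`` back into a PredictionSet."""
    cols = [f"p_{s}" for s in alphabet]
    matrices: dict[str, dict[str, np.ndarray]] = {}
    for cid, path in files.items():
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in ["protein_id", "residue_index", *cols] if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        per: dict[str, np.ndarray] = {}
        for pid, grp in df.groupby("protein_id", sort=False):
            grp = grp.sort_values("residue_index")
            if not np.array_equal(grp["residue_index"].to_numpy(), np.arange(len(grp))):
                raise ValidationError(f"{path}: protein {pid!r} residue indices not 0..L-1")
            per[str(pid)] = grp[cols].to_numpy(dtype=np.float64)
        matrices[cid] = per
    return PredictionSet.from_matrices(matrices)


@dataclass
class WeightMatrix:
    """C x 8 voting weights in [0, 1] — one GA individual."""

    classifier_ids: tuple[str, ...]
    values: np.ndarray
    provenance: str = "seeded"
    alphabet: ClassAlphabet = field(default_factory=lambda: DEFAULT_ALPHABET)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.classifier_ids), 8):
            raise ValidationError(
                f"weight matrix shape {self.values.shape} for "
                f"{len(self.classifier_ids)} classifiers"
            )

    def to_json(self) -> str:
        doc = {
            "provenance": self.provenance,
            "weights": {
                cid: {s: float(self.values[c, k]) for k, s in enumerate(self.alphabet)}
                for c, cid in enumerate(self.classifier_ids)
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str, alphabet: ClassAlphabet = DEFAULT_ALPHABET) -> "WeightMatrix":
        doc = json.loads(text)
        cids = tuple(doc["weights"])
        vals = np.array(
            [[doc["weights"][cid][s] for s in alphabet] for cid in cids], dtype=np.float64
        )
        return cls(classifier_ids=cids, values=vals, provenance=doc.get("provenance", "seeded"),
                   alphabet=alphabet)


@dataclass
class GAConfig:
    """Genetic-algorithm hyper-parameters.

    Defaults follow the standard recipe: a population of 2000, the 100
    fittest kept as parents, 900 crossover offspring, 1000 mutants
    (restoring 2000), up to 1000 generations with early stopping after
    50 generations without strict improvement, and a local-search
    phase refining the top 100 with 100 small mutants per generation
    under the same caps.  ``mutation_rate`` defaults to 1/(C*8) — one
    expected mutated gene per individual.
    """

    population_size: int = 2000
    n_parents: int = 100
    n_crossover: int = 900
    max_generations: int = 1000
    patience: int = 50
    ls_max_generations: int = 1000
    ls_pool: int = 100
    mutation_rate: float | None = None
    mutation_sigma: float = 0.1
    ls_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents + self.n_crossover != self.population_size // 2:
            raise ValueError(
                "parents + crossover offspring must equal half the population "
                f"({self.n_parents} + {self.n_crossover} != {self.population_size} / 2)"
            )
        if self.population_size % 2:
            raise ValueError("population size must be even (mutants double the pool)")

    @property
    def n_mutants(self) -> int:
        return self.n_parents + self.n_crossover


# ---------------------------------------------------------------------------
# voting primitives


def weighted_vote(
    probs: np.ndarray, weights: WeightMatrix | np.ndarray, tie_break: str = "lowest"
) -> int:
    """Fused label for a single residue.

    ``probs`` is the residue's ``(C, 8)`` probability stack.  The label
    is ``argmax_k sum_c w[c,k] p_c[k]``; exact ties go to the lowest
    class index by default (``tie_break="highest"`` for the other end).
    """
    w = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights)
    if w.shape != probs.shape:
        raise ValidationError(f"weights shape {w.shape} vs probabilities {probs.shape}")
    scores = (w * probs).sum(axis=0)
    if tie_break == "lowest":
        return int(scores.argmax())
    if tie_break == "highest":
        return int(7 - scores[::-1].argmax())
    raise ValueError(f"unknown tie_break {tie_break!r}")


def normalize_weights(values: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Rescale one individual so its maximum weight is 1.

    An all-zero individual carries no information and is repaired by a
    fresh uniform-random individual (requires ``rng``; without one the
    all-zero individual is returned unchanged with a warning).
    """
    values = np.asarray(values, dtype=np.float64)
    m = values.max()
    if m <= 0:
        if rng is None:
            warnings.warn("all-zero weight matrix and no rng to repair it; left as-is")
            return values.copy()
        return rng.uniform(0.0, 1.0, size=values.shape)
    return values / m


def normalize_individual(w: WeightMatrix, rng: np.random.Generator | None = None) -> WeightMatrix:
    """:func:`normalize_weights` on a :class:`WeightMatrix`."""
    return replace(w, values=normalize_weights(w.values, rng))


def _normalize_batch(pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Max-normalize each individual of a (M, C, 8) batch in place."""
    m = pop.max(axis=(1, 2))
    zero = m <= 0
    if zero.any():
        pop[zero] = rng.uniform(0.0, 1.0, size=(int(zero.sum()),) + pop.shape[1:]).astype(pop.dtype)
        m = pop.max(axis=(1, 2))
    pop /= m[:, None, None]
    return pop


# ---------------------------------------------------------------------------
# pooled fitness


class PooledFitness:
    """Pooled Q8 fitness over a validation split, vectorized over individuals.

    Pre-stacks every masked residue into a single ``(C, N, 8)`` tensor
    so a batch of ``M`` weight matrices is scored with eight
    ``(M, C) @ (C, N)`` products and a running argmax.
    """

    def __init__(self, pset: PredictionSet, labels: Mapping[str, np.ndarray]):
        pset.validate(lengths={pid: len(v) for pid, v in labels.items()})
        pids = list(labels)
        self.P = np.concatenate([pset.probs[pid] for pid in pids], axis=1).astype(np.float64)
        self.y = np.concatenate([np.asarray(labels[pid]) for pid in pids]).astype(np.int64)
        self.n_classifiers = pset.n_classifiers
        self.n_residues = int(self.y.size)
        if self.n_residues == 0:
            raise ValidationError("empty validation split")
        if len(pids) == 1:
            logger.warning("validation split holds a single protein; fitness may be degenerate")
        if np.unique(self.y).size == 1:
            logger.warning("validation split holds a single class; fitness may be degenerate")

    def __call__(self, batch: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Q8 of each individual in a (M, C, 8) batch."""
        batch = np.asarray(batch, dtype=np.float64)
        single = batch.ndim == 2
        if single:
            batch = batch[None]
        M = batch.shape[0]
        if batch.shape[1:] != (self.n_classifiers, 8):
            raise ValidationError(
                f"individuals have shape {batch.shape[1:]}, "
                f"expected ({self.n_classifiers}, 8)"
            )
        out = np.empty(M, dtype=np.float64)
        for lo in range(0, M, chunk):
            W = batch[lo : lo + chunk]
            best = W[:, :, 0] @ self.P[:, :, 0]
            arg = np.zeros(best.shape, dtype=np.int8)
            for k in range(1, 8):
                s = W[:, :, k] @ self.P[:, :, k]
                better = s > best
                arg[better] = k
                np.maximum(best, s, out=best)
            out[lo : lo + chunk] = (arg == self.y[None, :]).mean(axis=1)
        return out[0] if single else out


# ---------------------------------------------------------------------------
# GA phases


def init_population(
    config: GAConfig,
    n_classifiers: int,
    rng: np.random.Generator,
    seed_selectors: bool = True,
) -> np.ndarray:
    """Initial population: uniform-random individuals plus selectors.

    Returns ``(population_size + C, C, 8)`` when ``seed_selectors`` is
    on: one appended selector individual per classifier (1 on all that
    classifier's classes, 0 elsewhere) so the ensemble provably never
    underperforms its best member.
    """
    pop = rng.uniform(0.0, 1.0, size=(config.population_size, n_classifiers, 8))
    pop = _normalize_batch(pop, rng)
    if seed_selectors:
        selectors = np.zeros((n_classifiers, n_classifiers, 8))
        for c in range(n_classifiers):
            selectors[c, c, :] = 1.0
        pop = np.concatenate([pop, selectors])
    return pop


@dataclass
class PhaseResult:
    best: np.ndarray
    best_q8: float
    generations: int
    history: list[float]
    final_pool: np.ndarray
    final_fitness: np.ndarray


def _rank_desc(fitness: np.ndarray) -> np.ndarray:
    """Stable descending rank (earlier index wins ties)."""
    return np.argsort(-fitness, kind="stable")


def _mutate(
    pool: np.ndarray, rate: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    mask = rng.random(pool.shape) < rate
    noise = rng.normal(0.0, sigma, size=pool.shape)
    return np.clip(pool + mask * noise, 0.0, 1.0)


def ga_phase(
    population: np.ndarray,
    fitness: Callable[[np.ndarray], np.ndarray],
    config: GAConfig,
    rng: np.random.Generator,
) -> PhaseResult:
    """Main evolutionary loop.

    Per generation: rank by Q8, keep the ``n_parents`` best, create
    ``n_crossover`` offspring by uniform crossover between two parents
    drawn uniformly at random, then let each of those parents+offspring
    spawn one mutant; new individuals are max-normalized on creation.
    Stops at ``max_generations`` or after ``patience`` generations
    without a strictly better best-ever Q8.
    """
    n_genes = population.shape[1] * population.shape[2]
    rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_genes
    fit = np.asarray(fitness(population), dtype=np.float64)
    if fit.shape != (population.shape[0],):
        raise ValidationError("fitness must return one value per individual")

    order = _rank_desc(fit)
    best = population[order[0]].copy()
    best_q8 = float(fit[order[0]])
    history = [best_q8]
    stagnant = 0
    gen = 0
    for gen in range(1, config.max_generations + 1):
        order = _rank_desc(fit)
        parents = population[order[: config.n_parents]]
        pfit = fit[order[: config.n_parents]]

        pa = rng.integers(0, config.n_parents, size=config.n_crossover)
        pb = rng.integers(0, config.n_parents, size=config.n_crossover)
        take_a = rng.random((config.n_crossover,) + population.shape[1:]) < 0.5
        children = np.where(take_a, parents[pa], parents[pb])
        children = _normalize_batch(children, rng)
        cfit = np.asarray(fitness(children), dtype=np.float64)

        pool = np.concatenate([parents, children])
        pool_fit = np.concatenate([pfit, cfit])

        mutants = _mutate(pool, rate, config.mutation_sigma, rng)
        mutants = _normalize_batch(mutants, rng)
        mfit = np.asarray(fitness(mutants), dtype=np.float64)

        population = np.concatenate([pool, mutants])
        fit = np.concatenate([pool_fit, mfit])

        gen_best = int(fit.argmax())
        if fit[gen_best] > best_q8:
            best_q8 = float(fit[gen_best])
            best = population[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_q8)
        if stagnant >= config.patience:
            logger.info("ga_phase: early stop at generation %d (best Q8 %.5f)", gen, best_q8)
            break
    return PhaseResult(best, best_q8, gen, history, population, fit)


def local_search_phase(
    top: np.ndarray,
    fitness: Callable[[np.ndarray], np.ndarray],
    config: GAConfig,
    rng: np.random.Generator,
    top_fitness: np.ndarray | None = None,
) -> PhaseResult:
    """Refinement phase: small mutations of the elite pool.

    Each generation the ``ls_pool`` survivors spawn one small-sigma
    mutant apiece; the best ``ls_pool`` of the combined 2x pool survive
    (elitist mu+lambda, parents win ties).  Same generation cap and
    patience as the main phase.
    """
    if top.shape[0] != config.ls_pool:
        raise ValidationError(f"local search expects {config.ls_pool} entrants, got {top.shape[0]}")
    n_genes = top.shape[1] * top.shape[2]
    rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_genes
    pool = top.copy()
    fit = (
        np.asarray(top_fitness, dtype=np.float64)
        if top_fitness is not None
        else np.asarray(fitness(pool), dtype=np.float64)
    )
    order = _rank_desc(fit)
    best = pool[order[0]].copy()
    best_q8 = float(fit[order[0]])
    history = [best_q8]
    stagnant = 0
    gen = 0
    for gen in range(1, config.ls_max_generations + 1):
        mutants = _mutate(pool, rate, config.ls_sigma, rng)
        mutants = _normalize_batch(mutants, rng)
        mfit = np.asarray(fitness(mutants), dtype=np.float64)
        both = np.concatenate([pool, mutants])
        bfit = np.concatenate([fit, mfit])
        order = _rank_desc(bfit)[: config.ls_pool]
        pool, fit = both[order], bfit[order]
        if fit[0] > best_q8:
            best_q8 = float(fit[0])
            best = pool[0].copy()
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_q8)
        if stagnant >= config.patience:
            logger.info("local_search: early stop at generation %d (best Q8 %.5f)", gen, best_q8)
            break
    return PhaseResult(best, best_q8, gen, history, pool, fit)


@dataclass
class FitResult:
    """Outcome of :func:`fit_ensemble`."""

    weights: WeightMatrix
    q8: float
    ga_generations: int
    ls_generations: int
    history: list[float]


def fit_ensemble(
    predictions: PredictionSet,
    labels: Mapping[str, np.ndarray],
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    seed_selectors: bool = True,
) -> FitResult:
    """Learn voting weights on a validation split.

    ``labels`` maps protein id to the true label vector (class indices)
    of every protein in ``predictions``; weights are chosen to maximize
    pooled Q8 on exactly these residues.  Runs initialization, the main
    GA phase, then local search on the resulting top 100; returns the
    best-ever individual and its validation Q8.
    """
    config = config or GAConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fitness = PooledFitness(predictions, labels)

    pop = init_population(config, fitness.n_classifiers, rng, seed_selectors=seed_selectors)
    ga = ga_phase(pop, fitness, config, rng)

    order = _rank_desc(ga.final_fitness)[: config.ls_pool]
    ls = local_search_phase(
        ga.final_pool[order], fitness, config, rng, top_fitness=ga.final_fitness[order]
    )

    if ga.best_q8 >= ls.best_q8:
        best, best_q8 = ga.best, ga.best_q8
    else:
        best, best_q8 = ls.best, ls.best_q8
    weights = WeightMatrix(
        classifier_ids=predictions.classifier_ids,
        values=best.astype(np.float64),
        provenance="ga+local-search",
    )
    logger.info(
        "fit_ensemble: Q8 %.5f after %d GA + %d local-search generations",
        best_q8, ga.generations, ls.generations,
    )
    return FitResult(
        weights=weights,
        q8=best_q8,
        ga_generations=ga.generations,
        ls_generations=ls.generations,
        history=ga.history + ls.history,
    )


# ---------------------------------------------------------------------------
# deployment


@dataclass
class EnsembleResult:
    """Fused labels and raw per-class weighted sums, per protein."""

    labels: dict[str, np.ndarray]
    scores: dict[str, np.ndarray]
    no_vote: dict[str, np.ndarray]


def apply_ensemble(predictions: PredictionSet, weights: WeightMatrix) -> EnsembleResult:
    """Apply learned weights to a PredictionSet.

    The classifier order of the predictions must match the weights'
    order.  Residues where every classifier abstained (all scores zero)
    take the tie-break label (lowest class index) and are flagged in
    ``no_vote``.
    """
    if predictions.classifier_ids != weights.classifier_ids:
        raise ValidationError(
            "classifier order mismatch: predictions "
            f"{list(predictions.classifier_ids)} vs weights {list(weights.classifier_ids)}"
        )
    labels: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    no_vote: dict[str, np.ndarray] = {}
    for pid, arr in predictions.probs.items():
        s = np.einsum("ck,clk->lk", weights.values, arr)
        labels[pid] = s.argmax(axis=1)
        scores[pid] = s
        no_vote[pid] = ~np.any(s > 0, axis=1)
        if no_vote[pid].any():
            logger.warning(
                "protein %r: %d residues with no votes (tie-break label used)",
                pid, int(no_vote[pid].sum()),
            )
    return EnsembleResult(labels=labels, scores=scores, no_vote=no_vote)


def fuse_forward_reverse(p_forward: np.ndarray, p_reverse_realigned: np.ndarray) -> np.ndarray:
    """Merge forward- and reverse-direction predictions of one protein.

    The reverse-direction matrix must already be re-flipped to forward
    residue order.  Rows are summed elementwise and renormalized so the
    eight classes sum to 1; a residue where both rows are all-zero
    stays all-zero (with a warning).
    """
    p_forward = np.asarray(p_forward, dtype=np.float64)
    p_reverse_realigned = np.asarray(p_reverse_realigned, dtype=np.float64)
    if p_forward.shape != p_reverse_realigned.shape:
        raise ValidationError(
            f"shape mismatch {p_forward.shape} vs {p_reverse_realigned.shape}"
        )
    s = p_forward + p_reverse_realigned
    totals = s.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} residues with all-zero rows in both directions")
    out = np.zeros_like(s)
    np.divide(s, totals, out=out, where=totals > 0)
    return out
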