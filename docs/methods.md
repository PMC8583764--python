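# Methods

## Problem setting

A protein of length `L` is labelled residue-by-residue over the
eight-state secondary-structure alphabet {B, E, G, H, I, L, S, T}
(column order fixed per run by a `ClassAlphabet`; the shipped default
is alphabetical). Upstream classifiers are represented only by their
outputs: per protein, a `C x L x 8` stack of class-probability rows.
A row either sums to 1 or is all-zero — the abstention convention used
by the specific-alignments predictor when no qualifying alignment
covers a residue. `q8fuse` fuses these stacks; it does not train the
upstream classifiers.

## Weighted-voting ensemble

The fused label of residue `i` is `argmax_k Σ_c w[c,k]·p_c[i,k]` with
`w ∈ [0,1]^{C×8}`. Exact ties go to the lowest class index
(configurable to highest); abstention rows add zero to every class
score and so simply do not vote — no renormalization is applied to
them. Because the argmax is invariant under positive scaling of `w`,
individuals are canonicalized by dividing by their maximum weight; an
all-zero individual carries no information and is repaired by a fresh
uniform draw.

### Genetic algorithm

Fitness is pooled Q8 over all masked residues of the fitting split
(micro-average; no per-protein weighting). The defaults are

| parameter | default | meaning |
|---|---|---|
| population | 2000 | uniform-random individuals on [0,1) |
| parents kept | 100 | elitist selection by Q8 |
| crossover offspring | 900 | uniform crossover, two parents drawn uniformly from the kept 100 |
| mutants | 1000 | one per parent/offspring |
| mutation rate | 1/(C·8) | per-gene Bernoulli (one expected gene per individual) |
| mutation sigma | 0.1 | additive Gaussian, clipped to [0,1] |
| generations | ≤ 1000 | early stop after 50 without strict best-ever improvement |
| local search | top 100, sigma 0.02 | (mu+lambda) with mu=lambda=100, same caps |

Design choices where the recipe was genuinely open: the crossover
operator is uniform per gene (simplest unbiased operator over a flat
gene vector); parents are drawn without rank bias; mutation adds
clipped Gaussian noise, with a smaller sigma in the local-search phase
since that phase is a refinement; "no better result" means no strict
improvement of the best-ever fitness, and any strict improvement
resets the patience counter; the 100+900 pool doubled by mutation
restores the population exactly, so no extra truncation step exists;
the local-search survivor rule keeps the best 100 of parents ∪ mutants
(parents win ties, which also makes a zero-sigma configuration an
exact no-op); normalization is applied to newly created individuals
only — survivors are already normalized.

The initial population is augmented with `C` *selector* individuals
(weight 1 on every class of one classifier). With elitism this makes
the fused validation Q8 provably ≥ every individual classifier's Q8.
Note the guarantee is one-sided: per-class weights act as class
priors, so even a single-classifier "ensemble" can end strictly above
that classifier's raw argmax accuracy.

Scaled-down configurations (any even population with
`parents + crossover = population/2`) are accepted for small problems;
the defaults above are used whenever a configuration is not given.

### Numerical notes

Fitness is evaluated for whole batches of individuals via eight
`(M,C)@(C,N)` products and a running argmax in float64, chunked at 256
individuals to bound memory; deployment (`apply_ensemble`) uses the
same argmax convention, so the Q8 reported during fitting is exactly
reproduced when the learned weights are applied to the fitting split.
Only newly created individuals are re-evaluated (parents keep their
fitness), and all randomness flows through one `numpy` generator
seeded from the configuration, making runs bit-reproducible.

## Template-based predictors

Hits are parsed from BLAST-style tabular text (or BLAST XML) carrying
the gapped aligned sequences; residue pairs are derived by walking the
two gapped strings in lockstep, emitting a pair only where both
columns are residues. Hits whose subject equals the query are removed
(the query may sit in the reference) and ranks are reassigned
gaplessly; an optional strict mode also drops 100%-identity
full-coverage hits.

Both predictors filter by E-value *first* and then take the best
`n` survivors, re-ranked `1..n` — a failing hit never wastes a slot.
A hit at kept-rank `r` adds weight `n+1−r` to the subject's structure
symbol at every aligned pair. Specific: `n=10`, `E ≤ 1e-5`. General:
`n=100`, `E ≤ 10`, followed by a local search: an uncovered residue
copies the tally of the nearest covered residue within a centered
201-position window, the window growing by 100 positions per side per
round until a covered residue is found. Since the window grows without
bound, the outcome equals nearest-covered-neighbour assignment; two
equidistant neighbours are averaged, and borrowed tallies are copies
that never propagate further. Equal E-values keep the search tool's
output order (stable ranking). Tallies normalize row-wise into
probability matrices, zero rows staying zero, so the predictors are
ordinary ensemble members.

## Dataset conventions

Feature files hold one flattened row per protein: 700 residue slots x
50 columns (21 amino-acid one-hot with the wildcard X, 21 PSSM values
in [0,1], 8 structure one-hot), shorter proteins zero-padded. Padding
is detected as *all selected feature columns zero* — a real residue
cannot be all-zero because its one-hot sums to 1 — and must be a
contiguous tail. The column order inside the block is not part of the
file format, so it is a mandatory layout configuration: the shipped
default is the canonical 50-column order, and a second preset selects
the relevant 50 columns of the widely circulated 57-column public
releases (ignoring the no-sequence flags and solvent columns); neither
layout is asserted to be "the" original. Proteins beyond 700 residues
are split into consecutive 700-residue chunks whose concatenation
reproduces the input. Sliding windows (odd sizes; defaults
9, 11, 13, 15, 17) are zero-padded at protein ends and never cross
protein boundaries. Coordinates are 0-based internally; FASTA export
and error messages use 1-based positions.

## Metrics

Q8, per-class precision `TP/(TP+FP)` and recall `TP/(TP+FN)` pool
residues across proteins. A 0/0 denominator is reported as a distinct
*undefined* marker and rendered as a dash — never 0 or NaN — matching
the convention for classes absent from a split (e.g. pi helix in some
test sets). Confusion matrices are row-normalized with undefined rows
flagged. Q8 on an empty residue set raises rather than returning NaN.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the real task: eight-state
class imbalance (defaults ≈ B 1%, E 21%, G 4%, H 34%, I 0.2%, L 20%,
S 8.5%, T 11%), sequences whose letters correlate with the label (each
class prefers two letters with probability 0.6), PSSM rows as blurred
one-hots, planted per-class classifier skill with errors spilling onto
structurally confusable partners (B↔E, G↔H, I→H, S/T↔L; uniform spill
available), and retrievals whose E-values grow with mutation load and
shrink with coverage. Mutations corrupt the transferred structure
symbol as well as the sequence letter, so `mutation_rate=0` makes
template voting recover the truth exactly while `mutation_rate=1`
degrades it to the chance level `Σ_k f_k²`.

It deliberately does **not** imitate real PSSM statistics, real
secondary-structure segment lengths (labels are i.i.d., real
structures are runs), or realistic alignment gap patterns (synthetic
hits are ungapped substrings). Passing tests therefore demonstrate
that the fusion machinery is correct and that the GA recovers planted
structure — not that any particular Q8 level transfers to real
proteins, which depends entirely on the upstream classifiers and the
template reference supplied by the user.

## Problem sizes

The test suite and the acceptance script run the GA at its default
configuration on fixtures of 60 residues (exhaustive-oracle check,
where only 2x3 weights are effective and the coarse grid has 5^6
combinations) up to 200 proteins / ~20k residues (planted-skill
recovery); the acceptance script uses 100 proteins (~10k residues) for
the fusion benchmark and 40 proteins for the template benchmarks.
These sizes were chosen so the planted effects are measured with
comfortable statistical margins while a full run stays in the
minutes range on a single CPU.

## Known limitations

* Fitness is pooled Q8 only; no per-protein or multi-objective
  fitness.
* The GA is stochastic: the selector guarantee bounds it from below,
  but reaching the global optimum is only verified empirically (and
  exhaustively on the small-instance oracle).
* Whether population-wide renormalization (rather than
  new-individuals-only) was intended in the original recipe is
  ambiguous; the choice here is documented above and does not affect
  the voting semantics.
* The general-alignments local search reads "search the neighbourhood
  for a predicted residue" as borrowing the nearest covered residue's
  tally; re-voting from alignments overlapping the window is a
  defensible alternative reading that is not implemented.
* No Q3 (three-state) reduction.
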