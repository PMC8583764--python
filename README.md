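# q8fuse

Classifier fusion for **eight-state protein secondary structure
prediction**.

Predicting the DSSP eight-state label (B isolated beta bridge,
E extended strand, G 3-10 helix, H alpha helix, I pi helix, L loop,
S bend, T turn) of every residue is a long-standing sequence-labelling
problem, and the strongest systems are ensembles: several template-free
classifiers (recurrent networks, sliding-window predictors, ...) plus
template-based predictors that copy labels from homologous proteins
with solved structures. `q8fuse` implements the fusion layer of such a
system for anyone who already has per-residue class-probability
matrices from their own classifiers:

* a **genetic-algorithm weighted-voting ensemble** that learns one
  weight per class per classifier,
* two **template-based predictors** ("specific" and "general"
  alignments) that transfer structure labels from retrieved alignments
  by rank-weighted voting,
* the surrounding conventions: CB6133/CB513-style feature matrices,
  sliding-window extraction, and Q8 / precision / recall metrics,
* a synthetic-data module that fabricates datasets, planted-skill
  predictions and fake retrievals so the whole pipeline runs with no
  external downloads.

## The model

Each classifier `c` emits, per protein, an `L x 8` matrix `p_c` of
class probabilities (rows sum to 1, or are all-zero when a template
predictor abstains). The ensemble holds a weight matrix
`w ∈ [0,1]^{C x 8}` and labels residue `i`

```
ŷ_i = argmax_k  Σ_c  w[c,k] · p_c[i,k]
```

so fusing five classifiers means learning forty weights. Weights are
learned on a validation split by maximizing pooled Q8 accuracy

```
Q8 = Σ_k (correct residues in class k) / Σ_k (residues in class k)
```

with an elitist GA: 2000 uniform-random individuals; per generation
the 100 fittest survive, 900 offspring arise by uniform crossover and
those 1000 each spawn one Gaussian mutant (population back to 2000);
every new individual is rescaled so its largest weight is 1 (voting is
scale-invariant). The loop stops after 1000 generations or 50 without
improvement, then a local-search phase refines the top 100 with
small-sigma mutants. The initial population also contains one
*selector* per classifier (weight 1 on exactly one classifier), so the
fused validation Q8 provably never falls below the best single
classifier.

The template predictors vote structure labels across alignment columns:
*specific* uses the 10 best hits with E-value ≤ 1e-5, weighted
10, 9, ..., 1, abstaining where nothing aligns; *general* uses the 100
best hits with E-value ≤ 10, weighted 100, 99, ..., 1, and fills
uncovered residues from the nearest covered neighbour within an
expanding window. Tallies normalize to probability rows, so both plug
into the GA ensemble as ordinary classifiers — group ensembles and a
final ensemble are just repeated `fit_ensemble` calls.

## Worked example

`examples/04_ensemble_fitting.py` plants complementary skills — A is
reliable on E/H, B on L/T — and fits the ensemble:

```
classifier A alone: Q8 = 0.6279
classifier B alone: Q8 = 0.4810
fused ensemble:       Q8 = 0.8364 (33 GA + 15 local-search generations)

learned weights (rows = classifiers, columns = B E G H I L S T):
  A: 0.22 0.65 0.05 1.00 0.48 0.02 0.00 0.05
  B: 0.24 0.50 0.01 1.00 0.08 0.52 0.26 0.49
```

The fused Q8 (0.84) exceeds both individuals because the learned
weights route each class to the classifier that is good at it: A
out-votes B on E, while B dominates L and T. The other examples walk
the dataset round trip, the metric conventions (undefined 0/0
precision/recall prints as a dash), template voting (a two-way
conflict at one residue normalizes to probabilities 10/19 vs 9/19),
and window extraction.

A `q8fuse` command-line interface wraps the same functions
(`simulate`, `convert`, `template-predict`, `fit-ensemble`,
`apply-ensemble`, `metrics`); see `q8fuse --help`.

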