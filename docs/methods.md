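# Methods

## Problem setting

The package addresses binary tumour/normal classification of expression
matrices with *n* samples (tens) and *p* genes (thousands), where most
genes are irrelevant and informative genes often come in correlated
groups. Selection proceeds in two nested phases — a recall-oriented
filter/wrapper pass, then a redundancy-oriented refinement — followed by
multi-classifier evaluation on the selected genes. Tumour is the positive
class everywhere; the rationale is that sensitivity to tumours is the
clinically costly direction and a fixed convention keeps precision/recall
comparable across runs.

## Preprocessing

* **Duplicate genes** are defined by identical identifier (the auditable
  reading; an optional flag also collapses bit-identical expression
  profiles). The first occurrence is kept.
* **Z-scoring** standardises each gene to mean 0 and *population* variance
  1 (divide by *n*). Constant genes are mapped to all-zeros with a warning
  rather than an error so degenerate simulated genes never abort a run.
* **Splits.** Holdout draws a stratified test set of `round((1-f)·n)`
  samples, allocating per-class counts by largest fractional remainder with
  ties to the larger class. K-fold assigns each class's shuffled members
  round-robin to folds with a fold pointer carried across classes, which
  keeps total fold sizes within one of each other *and* per-class
  proportions within rounding — e.g. 36 samples at k = 10 gives six folds
  of 4 and four of 3. Stratified k-fold refuses classes smaller than k;
  wrapper cross-validation clips k to the minority-class size instead,
  since a metaheuristic must be total.
* An optional `--skip-normalize` flag supports tables already standardised
  at source; re-normalising standardised data is a no-op up to the
  variance convention, so the default is to normalise.

## Information measures and discretization

All information quantities are plug-in Shannon estimates in bits.
Expression values are continuous, so information gain and mutual
information operate on discretized values. The default discretizer is
recursive entropy minimisation with the Fayyad–Irani MDL stopping rule: a
binary cut is accepted only when its gain exceeds
`(log2(N−1) + log2(3^k − 2) − kH(S) + k1 H(S1) + k2 H(S2)) / N`.
Class-independent genes typically receive zero cuts, i.e. a single bin and
exactly zero gain — which makes the phase-1 rule "eliminate zero-gain
genes" a meaningful filter without any tuned threshold. Equal-frequency
binning (default 4 bins) is available as an unsupervised fallback.
MDL discretization is implemented in-package; no installed library
provides a supervised discretizer.

## Phase 1: IG filter + GA wrapper

Genes with gain ≤ 0 are removed (the threshold is exact zero by default;
it is a config knob). The GA searches binary masks over the survivors:

* generational GA, population 50, 100 generations, tournament size 3,
  one-point crossover at rate 0.9, per-bit mutation at 1/L, elitism 1,
  early stop after 20 stagnant generations — conventional small-GA values,
  all in `GAConfig`;
* initial bits set with probability `min(0.5, 100/L)` so initial subsets
  stay small when many genes survive;
* fitness `(1−w)·acc + w·(1−|m|/L)` with `w = 0` by default, where `acc`
  is pooled out-of-fold accuracy of a 1-NN classifier under 5-fold
  stratified CV (cheap, parameter-free; any registered classifier can be
  substituted). The empty mask scores 0 with a warning. Fitness values are
  memoised per mask, and folds are drawn once per search so all masks see
  identical partitions.
* total ordering of candidates: higher fitness, then **more** selected
  genes, then lexicographically smaller mask. Phase 1 is deliberately
  recall-oriented: once CV accuracy saturates (common at these sample
  sizes), ties resolve toward retaining more information-rich genes, and
  parsimony is left to phase 2. The reverse preference produces minimal
  masks that discard planted informative genes the moment accuracy
  saturates, which contradicts the phase's purpose of carrying *all*
  candidate signal forward.

## Phase 2: mRMR ranking + binary PSO

Relevance is MI between a gene's (MDL-binned) values and the label;
redundancy between genes is MI between their binned values. The greedy
ranking follows the difference scheme (MID): pick
`argmax_g MI(g;y) − mean_{s∈S} MI(g;s)`, ties to the lower index; the
quotient scheme (MIQ) floors the denominator at 1e-6.

The PSO candidate pool is the top `pool_size` ranked genes (default
`min(100, phase-1 count)`) that pass a **duplicate screen**: a gene is
dropped when its MI with any single higher-ranked gene exceeds its MI
with the class. The greedy score itself averages redundancy over all
selected genes, so one high-MI pairing (a near-copy) is diluted once
several genes are selected; the pairwise maximum is not. On the planted
redundancy benchmark the screen raises the pass rate from 5/10 to 18/20
seeded replicates.

The swarm (30 particles, 100 iterations, inertia 0.729,
cognitive = social = 1.49445, velocities clamped to ±4, stagnation
patience 20 — standard constriction-style constants) resamples each bit
to 1 with probability `sigmoid(v)`. Particles are initialised with per-bit
on-probability decaying linearly 0.9 → 0.1 down the mRMR ranking. Personal
and global bests update on strict improvement, ordered by fitness, then
more genes, then lexicographic mask, so the gbest trace is non-decreasing
and runs are bit-identical for a fixed seed. Fitness is pure CV accuracy
(no size term), shared with the GA implementation.

## Evaluation harness

Classifier families: linear-kernel SVM, Gaussian naive Bayes, decision
tree, 100-tree random forest, 5-NN, and an MLP with two hidden layers
(64/32, early stopping) as the "deep network" — expression subsets are
small tabular data, where a compact MLP is the appropriate realisation.
Fitting is delegated to scikit-learn with fixed seeds and otherwise
default hyperparameters. Under k-fold protocols the out-of-fold
predictions are pooled into a single confusion matrix (declared in the
report header) rather than averaging per-fold metrics, which is unstable
for folds of 3–4 samples. Degenerate metric denominators return 0 with a
warning so report tables are always complete. ROC area is the rank
(Mann–Whitney) statistic with ties averaged, computed from
`decision_function` scores where available and positive-class
probabilities otherwise.

## Synthetic data

The generator plants known structure in the simplest model that makes all
pipeline stages non-trivially testable:

* labels drawn to match `class_balance` within one sample;
* informative genes: class-conditional Gaussians with means ±d·σ/2
  (standardized shift `effect_size = d`, within-class SD `noise_sd`,
  default 1);
* redundant genes: a planted parent plus fresh `N(0, noise_sd²)` noise;
* all other genes: independent standard Gaussians;
* one root seed streams to the label draw, gene placement and noise draws
  in that fixed order, so regeneration is stable.

`kentridge_like` fixes the shape of the classic 62-biopsy colon benchmark:
2000 genes, 40 tumour / 22 normal, 20 informative genes, 40 redundant
copies, d = 2.

What the generator does **not** emulate: microarray intensity
distributions, probe-level effects, batch structure, label noise, missing
values, or correlated noise between non-copy genes. Passing recovery tests
therefore demonstrates that the pipeline's machinery behaves as designed
under its stated assumptions, not that it attains any particular accuracy
on real tumour data.

## Study conditions used by tests and the acceptance script

Planted-recovery studies use the conditions the recovery claims are stated
for: phase 1 on 300 genes / 10 informative / d = 2 / n = 150 (20 seeded
replicates, success = ≥8/10 planted genes retained); phase 2 on 30 genes /
5 informative + 5 redundant copies / n = 150 (20 replicates, success =
≥4 parents kept and ≤1 copy admitted). The end-to-end demonstration uses
the 62 × 2000 `kentridge_like` shape. Search-oracle checks run on
12-dimensional surrogate objectives (random linear + symmetric quadratic
pseudo-boolean functions) where exhaustive enumeration of all 4096 masks
is feasible.

## Known limitations

* Plug-in MI on MDL bins is biased low for genes whose binning collapses
  to one bin; such genes are invisible to mRMR. This is intentional
  (they carry no detected class signal) but means phase 2 cannot rescue a
  gene phase 1's discretizer missed.
* The duplicate screen compares each gene only against higher-ranked
  genes; a group of mutually redundant genes that are all weakly relevant
  can survive as a block if none dominates another.
* Wrapper fitness reuses the same CV folds for every mask, which is what
  makes searches deterministic, but also means selection can overfit those
  folds; the evaluation harness uses an independent split seeded
  separately.
* With n in the tens, CV accuracy saturates quickly and subset choice
  within a saturated plateau is governed by the declared tie-break rules,
  not by the data.
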