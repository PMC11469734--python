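# Methods

## Models

Every architecture in the package is a feed-forward rectifier MLP over a
min-max-normalised design matrix (continuous features scaled into [0, 1],
categorical features one-hot). For M target items:

- **STL** — one independent network per item: h hidden layers of r nodes,
  then a single output head. The ensemble of M such models (eSTL) is the
  single-task baseline.
- **All-task MTL (MTLaT)** — hard parameter sharing: a trunk of h/2 hidden
  layers shared by all tasks, then one branch of h/2 layers per task, then
  per-task heads. The training signal is the unweighted sum of the per-task
  cross-entropy losses, so backpropagation integrates all tasks' error
  gradients through the trunk.
- **Grouped MTL** — the MTLaT shape restricted to a subset of tasks. In a
  grouped ensemble each task's prediction comes from the one member model
  for which it is *primary*; its appearances in other selected groups are
  *secondary*: trained (their losses still shape the shared layers) but
  ignored at inference.
- **Concatenation MTL** — an all-task MTL in which the head of task j reads
  the horizontal concatenation of the last branch hidden layers of every
  member of j's selected group (j's own branch included), replacing the
  single-branch connection. Head input width is r·|group|. In the PTM
  variant the trunk and branch weights are copied from an already-trained
  MTLaT before continued training of all layers; the re-shaped heads start
  fresh.

Binary items use a single sigmoid unit with binary cross-entropy and a 0.5
decision threshold; multinomial items use softmax with categorical
cross-entropy and argmax decisions.

## Task relatedness and group selection

Candidate groups are all task subsets of size ≥ 2 — L = 2^M − M − 1 of them
(1013 for a 10-item profile, 57 for 6 items). Enumeration is exhaustive and
guarded at M ≤ 20; there is deliberately no pruning or greedy search.

**Gradient-lookahead affinity.** During the training of an all-task MTL,
for each mini-batch χ and each task i:

1. snapshot the shared trunk parameters θ_s;
2. compute the gradient of task i's loss w.r.t. θ_s only (the chain runs
   through task i's branch and head, but only trunk parameters move);
3. apply one *plain* (momentum-free) gradient step of size η, the current
   epoch's learning rate;
4. evaluate every other task's lookahead loss on the same batch and record
   z(i→j) = 1 − L_j(lookahead) / L_j(current);
5. restore θ_s exactly, then let the ordinary combined momentum update
   proceed.

Because the learning-rate schedule decays, raw z values shrink over
training; each value is therefore divided by that epoch's η. Per-epoch
values are the mean over batches, and the reported matrix ẑ is the mean
over completed epochs. The matrix is directed and generally asymmetric.
Pairs whose current loss is at the floor (≤ 1e−12) are skipped for that
batch rather than clamped — the ratio is undefined there — and logged.

**Cramér's V.** The classical coefficient
v = √(χ² / (n·(min(r,c) − 1))) on the contingency table of two target
columns, χ² without continuity correction and without bias correction.
The χ² p-value is computed and reported but does not gate inclusion —
group scoring uses v directly. A variable with fewer than two observed
levels gets v defined as 0 with a warning.

**Scoring and selection.** The score of group G onto member j is the mean
of the relatedness of the other members onto j, computed per fold on the
k-fold training subsets of the full-training rows and then averaged over
folds (averaging scores per fold or averaging matrices first are equivalent
by linearity; the tests pin this). For each task the argmax-scoring group
is selected; ties break to the smallest group, then lexicographically by
member indices, so selection is deterministic. Every task is primary in
exactly one selected group and may be secondary elsewhere.

## Resampling protocol

Each run uses seeded Monte Carlo splits: 20% hold-out test, the remaining
80% "full-training" set split again 75/25 into training and validation
(i.e. 60/20/20 of the cohort), plus a k-fold partition of the full-training
rows used only for relatedness estimation (k = 3 for 10-item BI-sized
cohorts, k = 5 for 6-item EQ-5D-sized ones, both configurable). Default
suite: seeds 0..49. Non-integral sizes floor the smaller partition.
Splits are not stratified by outcome. Encoders (min-max ranges) are fitted
on the full-training rows of each seed, never on test rows; category maps
cover the whole table so held-out rows always encode, and held-out
continuous values outside the fitted range are clipped into [0, 1].

## Training hyper-parameters

| parameter | default | rationale |
|---|---|---|
| hidden layers h | 4 (trunk 2 + branch 2) | standard small-cohort MLP depth |
| nodes per layer r | 100 | |
| optimizer | SGD, momentum 0.9 | |
| learning rate η₀ | 5e−4, halved every 15 epochs | |
| early stopping | patience 15 on summed validation loss, counted only after epoch 10 | guards against premature stops |
| max epochs T | 200 | |
| batch size | 32 (unconstrained by the protocol; configurable) | typical for cohorts of 10²–10³ rows |
| weight init | Glorot-uniform, seeded | fan-based scale keeps early epochs stable |

The best-validation-loss weights are restored after training. A non-finite
loss aborts with a diagnostic rather than silently continuing; in the
multi-seed driver such a failure marks the seed failed and the suite
continues. PTM retraining restarts the η schedule from η₀.

## Metrics

Per-item F1: macro average of per-class F1 over the item's *declared*
classes for multinomial items — a class absent from both truth and
prediction contributes 0, which is conservative and deterministic; binary
items use the positive-class F1, the positive class being the higher level
by convention (configurable). Overall F1 is the arithmetic mean over items.
Aggregation over seeds reports mean, sample STD and the normal-approximation
95% CI (mean ± 1.96·STD/√S). The MPI score of a candidate against a
reference is the fraction of items whose F1 is *strictly* higher, so ties
count against the candidate and s(a,b) + s(b,a) ≤ 1.

## Synthetic cohorts

The generator plants a symmetric M×M dependence matrix D (diagonal 1,
entries in [0, 1]) into ordinal targets via a latent-factor threshold
model. Item i's latent score is

  s_i = w_feature·(C t)_i + w_latent·(C f)_i + noise_sd·ε_i

where C is the row-normalised PSD square root of D, t are near-orthonormal
linear signals extracted from the continuous features (standardised
uniforms), f are independent standard-normal factors and ε is independent
noise. Defaults w_feature = 1.0, w_latent = 0.5, noise_sd = 0.5 put about
two-thirds of the latent variance on the systematic part — predictable but
far from saturated, the regime where sharing can matter. Scores are cut at
equal-probability Gaussian quantiles, shifted per item by `class_skew`
offsets to inject imbalance (positive offsets push mass toward low levels,
mirroring the skewed item distributions typical of discharge assessments).

Consequences used by the tests: D = I gives independent targets; a loading
of 1 with equal thresholds and vanishing noise gives identical columns;
empirical Cramér's V increases monotonically with the planted loading; and
because the same mixing C applies to the feature-driven part, strongly
loaded tasks share *predictable* structure, so multi-task architectures
have a real advantage to find.

What the generator does **not** emulate: real instruments' item-specific
marginals and measurement error, missingness (records are complete by
construction), nonlinear feature effects, cohort-specific demographics, or
survival/censoring. Passing tests therefore demonstrate that the machinery
detects and exploits planted dependence under the model's assumptions, not
that any particular clinical effect size will be realised on real cohorts.

## Problem sizes

The test suite and the acceptance script keep simulations small by design:
sampling-based checks use 2000–5000 rows where only an association needs to
be estimated, and the architecture-ordering experiment uses 4 tasks with a
common loading of 0.8, 1000 rows and 10 repeated splits of the full
h = 4 / r = 100 networks — large enough that the ordering
(concatenation-PTM ≥ all-task MTL ≥ STL ensemble) is stable across seeds,
small enough to run on one CPU in minutes.

## Known limitations

- The affinity probe evaluates lookahead losses per mini-batch; epoch-level
  probing would be a coarser but cheaper alternative.
- Group search is exhaustive; beyond M ≈ 16 the catalog (and the grouped
  ensemble) becomes impractical, matching the method's intended scale of
  5–10 items.
- No nested hyper-parameter tuning, class stratification of splits, or
  formal significance testing between variants; the CI columns support
  informal comparison only.
- Ensembles retrain each selected group from scratch; there is no weight
  sharing across ensemble members.
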