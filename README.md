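# mtlprofile

Task-grouping-conditioned multi-task learning for predicting multi-item
ordinal health profiles.

## The problem

Clinical instruments such as the Barthel Index (BI; 10 activities-of-daily-living
items scored on 2/3/4-point scales coded 0, 5, 10, 15, total 0–100) and the
EQ-5D-3L quality-of-life questionnaire (five 3-level dimensions plus the
EQ-VAS overall health score, binned into 4 classes) describe a patient as a
*profile*: a vector of M ordinal items. Predicting the follow-up profile from
admission data is naturally M parallel classification tasks, and the items
are rarely independent — a patient who struggles with transfers usually also
struggles with stairs. `mtlprofile` is for biostatisticians and clinical ML
researchers who want to exploit that inter-item dependence with multi-task
neural networks, and to decide *which* items should be learned together.

## Methods in the package

All models are rectifier MLPs (h = 4 hidden layers of r = 100 nodes by
default) trained with SGD (η = 0.0005, momentum 0.9, η halved every 15
epochs, early stopping with patience 15 after at least 10 epochs, at most
T = 200 epochs), with a sigmoid/binary-cross-entropy head per binary item
and a softmax/categorical-cross-entropy head per multinomial item; the total
loss is the unweighted sum of per-task losses.

Two measures of task relatedness drive the architecture search over all
L = 2^M − M − 1 candidate task groups of size ≥ 2:

- **Gradient-lookahead affinity** ẑ(i→j): while an all-task MTL trains, each
  mini-batch is probed — snapshot the shared trunk θ_s, take one plain
  gradient step of size η on task i's loss alone, and measure
  z(i→j) = 1 − L_j(lookahead)/L_j(current), restoring θ_s afterwards.
  Values are scaled by 1/η, averaged over batches and epochs. The group
  score onto a member task j is the mean of ẑ(i→j) over the other members,
  averaged over k cross-validation folds of the full-training set.
- **Cramér's V association** v(i,j) = √(χ² / (n·(min(r,c) − 1))) between the
  target columns themselves — symmetric, in [0, 1], no bias correction.

For each task the argmax-scoring group is selected; the union of selected
groups defines either an ensemble of grouped MTLs (each task's prediction
taken from its own argmax group, other members being training-only
"secondary" branches) or a set of concatenation links in a single all-task
MTL, where the head of task j reads the concatenated last branch layers of
every member of j's group — optionally initialised from the pre-trained
all-task MTL's weights (PTM) before continued training.

Evaluation follows a repeated-split protocol: 50 seeded Monte Carlo 80/20
full-train/test splits, 75/25 train/validation within full-train, per-item
F1 (macro over classes for multinomial items), the item-averaged overall F1
with mean/STD/95% CI over seeds, and the multi-task performance improvement
score s_MPI — the fraction of items on which one model strictly beats a
reference.

Because real BI/EQ-5D cohorts are not redistributable, the package includes
a synthetic-cohort generator that plants an explicit M×M dependence matrix
into correlated ordinal targets through a latent-factor threshold model, so
every grouping and architecture claim is testable end to end.

## Worked example

```python
import numpy as np
from mtlprofile import (
    CohortSpec, ExperimentConfig, generate_cohort, run_seed,
    synthetic_profile_spec, uniform_dependence, association_matrix,
)

# 1000 patients, 4 correlated 3-level items (common loading 0.8)
spec = CohortSpec(
    n_rows=1000,
    profile=synthetic_profile_spec(4),
    dependence=uniform_dependence(4, 0.8),
    seed=0,
)
table = generate_cohort(spec)
print(np.round(association_matrix(table.targets()).values, 2))

cfg = ExperimentConfig(n_seeds=1, k=3, variants=("eSTL", "MTLaT", "MTLaT-ccVTAG-PTM"))
res = run_seed(table, 0, cfg)
for variant, d in res["variants"].items():
    print(f"{variant:18s} overall F1 {d['overall']:.3f}  params {d['params']}")
print("VTAG groups:", [g.members for g in res["vtag_grouping"]])
```

prints

```
[[1.   0.42 0.42 0.4 ]
 [0.42 1.   0.42 0.43]
 [0.42 0.42 1.   0.45]
 [0.4  0.43 0.45 1.  ]]
eSTL               overall F1 0.437  params 128812
MTLaT              overall F1 0.501  params 93712
MTLaT-ccVTAG-PTM   overall F1 0.589  params 94912
VTAG groups: [(0, 2), (1, 3), (2, 3)]
```

The planted loading of 0.8 surfaces as pairwise Cramér's V ≈ 0.4 between
the discretised targets. On this split the classic all-task MTL (`MTLaT`)
beats the ensemble of single-task models (`eSTL`) while using ~27% fewer
parameters, and the concatenation model initialised from the pre-trained
MTL (`MTLaT-ccVTAG-PTM`) does best. The selected groups are the pairs with
the highest fold-averaged association onto each task.

The same pipeline is scriptable from the shell:

```bash
mtlprofile simulate --profile eq5d --n 500 --seed 3 --out cohort
mtlprofile run --cohort cohort.csv --schema cohort.schema.json \
               --seeds 50 --k 5 --out runs/eq5d
mtlprofile report runs/eq5d
```

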