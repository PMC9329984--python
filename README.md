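# smearopt

Bayesian-optimized convolutional networks for screening acute
lymphoblastic leukemia (ALL) in stained blood-smear microscopy images.

ALL diagnosis starts with a human examining blood smears on glass slides
for immature lymphoid blasts — cells with enlarged, irregularly lobed,
darkly stained nuclei.  A small CNN can learn this distinction directly
from labeled images, but its performance hinges on hyperparameters that
interact: the learning rate, the network depth, the optimizer's momentum
and the weight penalty.  `smearopt` tunes all four jointly with Bayesian
optimization instead of hand-tuning or grid search, and ships a synthetic
smear generator so the entire pipeline runs and is tested end to end with
no external data.

## What it computes

**The search.**  Four hyperparameters are optimized over the box

| variable                | range          | scale  | type    |
|-------------------------|----------------|--------|---------|
| initial learning rate σ | 10⁻² – 1       | log₁₀  | real    |
| conv. block depth (CBD) | 1 – 6          | linear | integer |
| SGDM momentum M         | 0.75 – 0.99    | linear | real    |
| L2 coefficient ε        | 10⁻¹¹ – 10⁻²   | log₁₀  | real    |

by minimizing the validation classification error E = 1 − mean
validation accuracy.  A Gaussian process with a Matérn 5/2 kernel,

k(r) = σ_f² (1 + √5·r/ℓ + 5r²/3ℓ²) exp(−√5·r/ℓ),

models E over the unit-scaled search cube; the next trial is chosen by
maximizing Expected Improvement, EI(x) = E[max(E⁺ − E(x), 0)] under the
posterior, where E⁺ is the best error observed so far.  The loop runs up
to 30 objective evaluations (each one trains a network from scratch) and
stops early if a trial reaches E ≤ 10⁻⁴.

**The network.**  Three convolutional blocks of CBD basic blocks each
(3×3 same-padded convolution → batch norm → ReLU), giving 3·CBD
convolution layers; a max pool after block 1, an average pool after
block 2, then global average pooling, dropout 0.5 and a two-way softmax
head.  Filter counts scale as round(32·2^(b−1)/CBD) so depth does not
inflate the parameter budget.  Training is SGD with momentum,

β_{i+1} = β_i − σ ∇L(β_i) + M (β_i − β_{i−1}),

on cross-entropy plus ε·½‖w‖², mini-batches of 128, up to 150 epochs,
with σ dropped by 0.1 every 40 epochs.  The engine is pure numpy
(BLAS-backed convolutions), so no deep-learning framework is required.

**The evaluation.**  The best trial's model — and only that one — is
scored on a held-out test split with sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy, diseased being the positive class.

**The data path.**  Folder-per-class image sets (`healthy/`, `all/`) are
merged (e.g. the public ALL-IDB1 + ALL-IDB2 sets: 59+49 and 130+130
images → a 368-image hybrid), enlarged six-fold by horizontal/vertical
reflection and ±45°/90° rotation (→ 2208), resized to 64×64, and split
80/10/10 (→ 1768/220/220).

## Worked example

`examples/` holds one short script per capability.  The full desk-scale
pipeline (synthetic images, 200/40/40 split at 32×32, 5-trial budget,
10 epochs per trial):

```sh
$ python examples/06_end_to_end.py
trial  objective  cbd  learning-rate  momentum  regularization
    1     0.0250    6       0.10559    0.7846       3.450e-03
    2     0.0250    3       0.04204    0.9486       4.817e-08
    3     0.0250    1       0.12566    0.9308       6.971e-07
    4     0.0250    5       0.04565    0.8228       1.206e-07
    5     0.0250    1       0.93549    0.7580       1.108e-11
best validation error: 0.0250 (stopped by budget)
held-out test set:  sensitivity 1.000  specificity 1.000  accuracy 1.000
```

Each row is one trial: the hyperparameters chosen (first random, then by
EI) and the validation error of the network they trained.  Here every
trial misclassifies at most 1 of 40 validation images (error 0.025) and
the best model classifies the 40 held-out test images perfectly.  The
same API runs the full-scale protocol on a real dataset:

```sh
smearopt optimize --seed 0 --out runs/full      # ExperimentConfig() defaults
smearopt synth --healthy 189 --diseased 179 --out data/demo   # or real data
```

Pointing `ExperimentConfig(data_dir=..., extra_data_dir=...)` at the two
ALL-IDB folders reproduces the full experiment (64×64, augmentation,
30 evaluations, 150 epochs).

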