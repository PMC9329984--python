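# Methods

## The optimization problem

The package tunes four hyperparameters of a block-structured CNN for
binary blood-smear classification: the initial learning rate σ ∈
[10⁻², 1] (log₁₀ scale), the convolutional block depth CBD ∈ {1,…,6},
the SGDM momentum M ∈ [0.75, 0.99] (linear), and the L2 regularization
coefficient ε ∈ [10⁻¹¹, 10⁻²] (log₁₀).  The objective is the validation
classification error E = 1 − mean validation accuracy, an expensive,
noisy, derivative-free function of the hyperparameters — the setting
Bayesian optimization is built for.  Which variables are log-scaled
follows the search-table convention (learning rate and regularization);
log-scaling a [0.75, 0.99] momentum range would be ineffectual.

All variables are mapped to the unit cube: log₁₀ variables by
(log₁₀ v − log₁₀ lo)/(log₁₀ hi − log₁₀ lo), linear ones min–max.  The
integer CBD dimension lives on the images of its six admissible values;
candidate points snap to the nearest grid image before scoring, and
denormalization rounds — the usual continuous-relaxation treatment of
mixed spaces.

## Surrogate

A zero-mean Gaussian process on standardized objectives with a Matérn
5/2 kernel and ARD (per-dimension) length scales.  Hyperparameters
(σ_f², ℓ₁..d, noise σ_n²) maximize the log marginal likelihood via
L-BFGS-B with analytic gradients in log space, 8 starts (one fixed
moderate start, seven random log-uniform) inside box bounds
ℓ ∈ [10⁻³, 10], σ_f² ∈ [10⁻⁶, 10], σ_n² ∈ [10⁻⁸, 1] (bounds on the
standardized-y scale, where var(y) = 1).  A jitter ladder
(0, 10⁻¹⁰ … 10⁻⁴) enlarges the noise term until the Cholesky
factorization succeeds; jitter actually used is folded into the stored
noise variance so the factor reconstructs the stored matrix exactly.
Constant-objective histories set the standardization scale to 1 instead
of dividing by zero.  Posterior predictive variance is clipped at zero.

Correctness is established against an independent oracle: explicit
dense-matrix inversion of K + σ_n²I reproduces the Cholesky-based
posterior mean and sd to < 10⁻⁶ on designs up to n = 25.

## Acquisition

Expected Improvement for minimization:
EI = (E⁺ − μ)Φ(z) + sφ(z), z = (E⁺ − μ)/s, with the s → 0 limit
max(E⁺ − μ, 0); E⁺ is the best observed objective.  Maximization scores
2048 scrambled-Sobol candidates (integer dimensions snapped first), then
polishes the top 5 with bounded L-BFGS-B moves in the continuous
coordinates.  If the winner exactly duplicates an evaluated point, the
best non-duplicate candidate is taken instead; a fully duplicated
candidate set falls back to a perturbed point.  On a 10 001-point 1-D
grid the returned point's EI matches the grid maximum to 10⁻⁶.

## The loop

`n_initial = 4` seeding trials are drawn uniformly from the cube (a
small share of the default 30-trial budget), then fit → maximize EI →
evaluate repeats until the budget is exhausted or an objective
≤ 10⁻⁴ is observed (the threshold comparison is inclusive).  A trial
whose objective raises — e.g. divergent training — is recorded as
`failed` and assigned the worst ok objective seen so far (1.0, the error
rate's natural ceiling, if none exists yet): the surrogate stays
informed and learns to avoid the region without aborting the search.
One seeded generator drives initial points, GP restarts and Sobol
scrambling, so runs on deterministic objectives are reproducible bit for
bit.

## Network and training

Three blocks of CBD basic blocks (3×3 stride-1 same-padded convolution →
batch norm → ReLU); max pool 2×2 after block 1, average pool 2×2 after
block 2, then global average pooling → dropout 0.5 → fully connected →
softmax.  This pooling layout yields one max and one spatial average
pool plus the global pool, and two stride-2 reductions leave a 16×16 map
from 64×64 input for every CBD.  Filters per block are
round(32·2^(b−1)/CBD): the 1/CBD proportionality keeps parameter counts
comparable across depths (93 954 at CBD = 1 down to 29 834 at CBD = 6 —
comparable, not constant, since conv parameters scale with the product
of adjacent widths).  Base width 32, doubling across blocks, 3×3
kernels and He fan-in initialization are conventional choices the
protocol leaves open.

Training is mini-batch SGDM implemented in the velocity form
v ← Mv − σ∇L, β ← β + v, which is algebraically identical to the
two-point form β_{i+1} = β_i − σ∇L(β_i) + M(β_i − β_{i−1}) (a tested
property, exact to 10⁻¹²).  The loss is softmax cross-entropy plus
ε·½‖w‖² over convolution and fully-connected kernels only — biases and
batch-norm parameters are exempt, as is conventional.  The learning rate
is σ·0.1^⌊(epoch−1)/40⌋ ("drop per 40 epochs" is pinned to the epoch-41
boundary), so 150 epochs see exactly {σ, 0.1σ, 0.01σ, 0.001σ}.  Batches
are reshuffled each epoch by the trial's seeded generator; the
final-epoch model is the trial's model (no early stopping).  Non-finite
losses raise a divergence error naming the epoch — inside the search
loop this surfaces as a failed trial.

Batch-norm running statistics are updated with decay 0.1 during
training; after the last epoch they are replaced by population
statistics (the average of mini-batch moments over one full pass of the
training set with final weights).  Without this finalization, short
trainings evaluate with statistics that lag the weights and validation
accuracy is systematically understated.

The engine is pure numpy: convolutions execute as nine BLAS matrix
products (one per kernel offset) in float32, which keeps a 10-epoch
desk-scale trial around ten seconds on one core.  Analytic gradients of
every layer match central finite differences (float64) to 10⁻⁵
relative.

## Data pipeline

Folder-per-class trees (`healthy/`, `all/`) load into labeled bundles;
two sources concatenate into a hybrid set with provenance preserved.
Augmentation emits exactly six variants per source image — identity,
horizontal and vertical reflection, 90° rotation (all pixel-lossless),
and ±45° rotations about the center, cropped to the original frame with
reflected-border fill and bilinear resampling.  Augmenting an already
augmented bundle is refused.  Resizing is bilinear.

The 80/10/10 split takes ⌊0.1N⌋ images each for validation and test and
trains on the remainder — the only rounding that maps 2208 images to
1768/220/220.  The global counts are apportioned across the two classes
by largest remainder, which stratifies the split (for 1134/1074 images:
113/107 per holdout partition) while preserving the global floor sizes
even when per-class floors would degenerate (10 images still split
8/1/1).  Splitting happens after augmentation, mirroring the reference
processing order; this lets variants of one source image straddle
partitions, so a `by_source` option assigns whole source groups to one
partition for a leakage-free alternative.  Sensitivity, specificity and
accuracy treat diseased as positive; an undefined ratio (empty class) is
reported as NaN, never silently zero.

## Synthetic smear generator

The generator emulates the features that distinguish leukemic from
healthy frames: a pale pink background with faint red-cell discs, plus
dark purple stained nuclei whose count (Poisson, clamped to ≥ 1 per
frame), radius, and boundary irregularity all stochastically dominate in
the diseased class (defaults at a 256-px raster: count means 1.5 vs 4.0,
radius means 14 vs 26 px, irregularity 0.03 vs 0.35).  Irregularity
scales a harmonic perturbation of the boundary radius (orders 2–6,
random amplitudes and phases), chosen over plain noise because it
produces the lobed, blast-like outlines that make diseased nuclei
morphologically distinct rather than merely noisy.  Defaults were chosen
once so that a hand-crafted stained-pixel-fraction threshold already
classifies above 80% — i.e. the classes are separable before any network
is involved — and a CBD = 2 network reaches ≥ 95% validation accuracy at
desk scale.

What the generator does not emulate: staining and illumination
variability across laboratories, cell overlap and occlusion, the
single-cell vs multi-cell distinction between the two public subsets,
or any photorealistic texture.  Tests passing on synthetic data
therefore demonstrate that the search, training and evaluation machinery
works and that the advertised accuracy regime is attainable on separable
data — they do not certify accuracy on real smears, which requires
pointing the default full-scale configuration at the real image folders.

## Problem sizes

Unit and property tests run on toy designs (GP n ≤ 25, 8–16 px network
inputs).  The end-to-end checks use a deliberate desk-scale protocol —
280 synthetic frames rendered at 96 px, resized to 32×32, split
200/40/40, a 5-evaluation budget at 10 epochs per trial — chosen as the
smallest sizes at which the full pipeline still exhibits its qualitative
behavior (near-zero validation error, ≥ 0.9 test metrics).  The shipped
default configuration is the full-scale protocol (64×64, six-fold
augmentation, 30 evaluations, 150 epochs, batch 128).

## Known limitations

- Single-core numpy training: fine at desk scale, slow for the
  full-scale protocol compared to GPU frameworks.
- EI acquisition only, sequential (no batch proposals), Matérn 5/2 only.
- The GP treats the integer CBD dimension by continuous relaxation;
  with many integer dimensions a dedicated mixed-space kernel would be
  preferable.
- Failed-trial imputation (worst observed value) can flatten the
  surrogate if most trials fail.
- The generator's separability means headline metrics on synthetic data
  are optimistic relative to real smears by construction.
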