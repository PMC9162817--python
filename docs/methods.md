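# Methods

## Problem

Postural balance control is assessed on a force platform: a subject stands
still while the platform samples the center-of-pressure (COP) displacement
in the anteroposterior (x) and mediolateral (y) directions at 100 Hz.
Smaller sway generally indicates better balance control. `copnet`
classifies a two-channel COP window into one of three balance-control
levels — high-level athlete (H), medium-level athlete (M), normal person
(N) — directly from the raw time series, with no hand-crafted features.

## Model

The core classifier is a deep multi-scale residual connected 1D
convolutional network (`kind="msrc"`):

- **Multi-scale feature extraction.** Three parallel branches process the
  same `[2, N_in]` window with convolution kernels of size 3, 10 and 20,
  capturing local, intermediate and global temporal structure. Branch
  outputs are flattened and concatenated before classification.
- **Residual blocks.** Each branch stacks two residual blocks; a block is
  two same-padded convolutions (Leaky ReLU between them) plus a short-cut
  connection, `c = R(x) + x`, with the activation applied after the sum.
  When input and output channel counts differ (first block: 2 → F
  channels) the short-cut is a 1×1 convolution; otherwise it is the
  identity. A max-pool of size 2 follows each block, so with `N_in = 200`
  each branch emits a length-50 map per filter.
- **Head.** Concatenated branch features → fully-connected layer of 128
  units (Leaky ReLU) → dropout → fully-connected layer with one confidence
  value per class → softmax.

Training minimizes mean cross-entropy with mini-batch Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8): batch size 8, 100 epochs, learning rate
1e-4 by default. Each epoch reshuffles the training samples; a final short
batch is kept. Evaluation uses the final-epoch parameters; argmax
prediction breaks ties toward the lowest class index.

Comparison architectures share the training setup: `nn` (one hidden layer,
1000 units), `dnn` (hidden layers 1000/1000/500), `dscnn` (single-scale:
one branch, kernel 10, no concatenation), and `wores` (multi-scale with
the short-cut connections removed).

### Parameters that matter

| parameter | default | notes |
|---|---|---|
| `n_in` | 200 | window length (2 s at 100 Hz); the sample is `[2, 200]` |
| `branch_kernel_sizes` | (3, 10, 20) | one branch per size |
| `blocks_per_branch` / `convs_per_block` | 2 / 2 | 12 main conv layers in total |
| `filters_per_conv` | 10 | never fixed by the study design; swept {1, 5, 10, 15, 20} in the filter ablation |
| `pool_size` | 2 | one pool after each residual block |
| `fc_hidden` | 128 | feature layer used for t-SNE visualization |
| `leaky_slope` | 0.01 | activation slope for v < 0 |
| `dropout_rate` | 0.2 | after the 128-unit layer (and each MLP hidden layer) |
| `batch_size` / `epochs` / `learning_rate` | 8 / 100 / 1e-4 | study training settings |
| `repeats` | 3 | independent trainings averaged per experiment |

Choices that were genuinely open and how they were fixed:

- **Pooling placement** — one max-pool(2) after each residual block;
  pooling is required somewhere to keep the flattened width manageable,
  and per-block pooling is the common residual-network pattern.
- **Short-cut projection** — 1×1 convolution whenever channel counts
  differ; an additive short-cut needs shape-compatible operands.
- **Residual activation** — applied after the sum (both placements are
  legitimate; post-sum is exposed in code as the block's own activation).
- **Dropout rate 0.2** — dropout is part of the design but no rate is
  fixed by it; 0.2 is a conventional mild setting, config-exposed.
- **Single-scale kernel 10** for `dscnn` — the middle of the three scales.
- **Weight initialization** — uniform fan-in (±1/√fan_in) from a seeded
  generator.
- **Tie-breaking** — lowest class index at equal probabilities; this makes
  the untrained/uniform model score exactly 1/3 on a balanced test set.
- **Validation** — `TrainConfig.validation_fraction` (default 0.1) lets a
  caller hold out training data for monitoring, but the task runner trains
  on the full training set and evaluates the final epoch; no early
  stopping or epoch selection is performed.

## Data handling

Recordings are delimited text (`t,x,y` or `x,y`) plus a manifest CSV
(`subject_id,level,path,fs`). Windows are 0-based, half-open slices
`[i*stride, i*stride + n_in)`; the default stride is `n_in/2` (50%
overlap), which is not fixed by the study design and is config-exposed.
Label encoding is fixed: H → 0, M → 1, N → 2.

A task names one subject per level and a train/test size (the standard
four tasks use 1200/600). Because adjacent windows overlap, a random
window split would leak time steps across the train/test boundary; the
split is therefore chronological per subject — earliest windows to
training, latest to testing — and refuses configurations in which the two
blocks would share any time step. Pooled sets are shuffled with a seeded
generator and are exactly class-balanced by construction.

Per-channel z-scoring (mean/std computed on the training set only, zero
std guarded to 1) is applied by default and can be disabled
(`--no-standardize`); raw COP units are otherwise passed through.

## Synthetic sway generator

No public COP corpus matches this six-subject, three-level design, so the
generator emulates it. Each channel follows a discretized
Ornstein–Uhlenbeck process

    c[t+1] = c[t] − θ·c[t]·Δt + σ_eff·√Δt·ε[t],   c[0] = 0,  Δt = 1/fs,

plus an additive slow drift `A·sin(2π f_d t + φ)` with a per-channel
random phase. Mean reversion stands in for corrective postural control;
the noise intensity σ encodes the level (better balance → smaller sway,
so σ_H < σ_M < σ_N); the drift mimics slow postural adjustments. Each
subject's σ is jittered multiplicatively (`σ_eff = σ_level(1 + j·u)`,
`u ∈ [−1, 1]` fixed per subject) to create between-subject variation.
Euler–Maruyama discretization is adequate at Δt = 10 ms for θ around
1 /s; the one-pole recursion is evaluated in C via `scipy.signal.lfilter`.

Defaults (the "easy" regime): θ = 1 /s, σ = 0.6 / 1.0 / 1.6 units·s^-1/2,
drift 0.3 units at 0.1 Hz, jitter 0.15, fs = 100 Hz, duration 620 s. The
duration is the smallest round value for which a 1200/600 task is
satisfiable at the default stride (600 windows per subject need
60,100 steps; 620 s gives 619 windows). The "hard" preset narrows σ to
0.9 / 1.0 / 1.1 so that classes overlap strongly.

Calibration facts used by the tests: a drift-free channel has stationary
variance σ²/(2θ) and lag-1 autocorrelation exp(−θΔt); and the one-step
increment variance ≈ σ²Δt is the level-defining statistic, so a simple
threshold rule on the log mean squared increment per window reaches ≥95%
accuracy in the easy regime and falls below 90% in the hard regime. (Raw
within-window variance is a much weaker feature here: with θ = 1 /s a 2-s
window spans only ~2 correlation times.)

What the generator does **not** emulate: inverted-pendulum biomechanics,
force-plate noise floors, eyes-open/closed conditions, non-stationarity
across a session, or any spectral detail of real COP beyond mean
reversion plus slow drift. Passing tests therefore demonstrate that the
pipeline recovers level structure expressed through sway magnitude and
dynamics of an OU process — not performance on real athlete recordings.

## Numerical backend

No GPU tensor framework is used: the layers (same-padded 1D convolution,
Leaky ReLU, non-overlapping max pooling, dense, inverted dropout,
residual add, softmax cross-entropy) are implemented in numpy with
hand-written backward passes, single precision by default. Convolutions
run as one GEMM over a strided im2col view; the input gradient is the
flipped-kernel correlation of the padded output gradient; Adam folds all
parameters into one flat vector (optionally updated by a fused numba
kernel). Correctness is established two ways: every forward is checked
against an independent pure-numpy oracle module, and every backward
against central finite differences in float64.

Numerical conventions: cross-correlation (no kernel flip); asymmetric
same-padding (extra zero on the right for even kernels); pooling drops a
trailing remainder shorter than the pool size; softmax subtracts the row
maximum; cross-entropy clips probabilities to [1e-12, 1]; a non-finite
training loss raises a divergence error naming the epoch.

Determinism: one integer seed per entry point; component seeds
(simulation noise, per-subject jitter, split shuffling, weight
initialization, mini-batch order, dropout masks, t-SNE) are derived from
it with `numpy.random.SeedSequence` streams, so any sub-experiment is
independently reproducible. Re-running with the same seeds is
bit-reproducible on the same platform/BLAS.

## Experiment sizes

All experiments run single-core. The class-recovery experiment uses the
full study settings (1200/600 samples, batch 8, 100 epochs, three
repeats). The qualitative comparisons use reduced, desk-scale epoch
counts: the architecture comparison (tasks T1–T2 × three repeats) runs at
15 epochs; the filter-count sweep ({1, 5, 10, 15, 20} on easy T1) at 30
epochs, the smallest round count at which the moderate-capacity models
reach their accuracy plateau — so the sweep compares capacity, not
convergence speed; and the sample-count sweep ({300, 600, 900, 1200} on
hard T1) at 10 epochs. The sample-count sweep uses nested,
class-balanced subsamples so the curve is comparable across sizes.

## Known limitations

- Results on synthetic sway say nothing quantitative about real athlete
  data; headline accuracies from force-platform studies are not
  reproducible without their recordings.
- The backend is CPU-only and single-threaded; it is sized for `[2, 200]`
  windows and a few hundred thousand parameters, not for large-scale use.
- Two channels enter as convolution channels (not as a 2-row spatial
  axis); kernels therefore mix both directions at every tap.
- The hard regime's subject jitter can make a task's effective σ ordering
  differ from the nominal level ordering; classifiers then learn
  subject-specific boundaries, which is intended behaviour for these
  within-subject splits.
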