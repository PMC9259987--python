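# Methods

## Model and privacy accounting

All three model families are fully-connected stacks trained by plain
(momentum-free) mini-batch SGD:

* **dpAE** — a denoising autoencoder. The input batch is corrupted with
  elementwise Gaussian noise of standard deviation `corruption_std`
  (default 0.1), encoded through dense→relu→dropout layers to a bottleneck
  code, decoded through the mirrored widths (final layer linear, no dropout),
  and scored by mean-squared error against the **clean** batch. Corruption is
  redrawn fresh for every mini-batch.
* **dpClassM** — one dense+relu+dropout layer on autoencoder codes followed by
  a 2-unit layer with a row softmax; cross-entropy loss. Predicted label =
  argmax probability, ties resolved to class 0.
* **dpRegM** — dense+relu+dropout layers on codes with a single linear output
  unit; mean-squared-error loss. One independent model (and budget) per drug;
  samples with a missing response are dropped before any computation.

Privacy is tracked in (α, ε)-Rényi DP at a single order α > 1 (default 2; the
order is configuration, all formulas are order-parametric). One SGD update
releases

    g̃ = ( Σᵢ clip(gᵢ, C) + 𝒩(0, σ²C² I) ) / B

where gᵢ are per-example gradients, C the clip norm (default 1.0) and B the
batch size. Removing one example changes the clipped sum by at most C in ℓ₂
norm, so the mechanism's sensitivity is C and the release costs
ε_step = α·C²/(2σ²_abs) with σ_abs = σ·C. A run's total budget is split
uniformly: the schedule is planned up front as epochs × ⌊n/B⌋ steps (the
incomplete final batch is dropped so every release has identical B and
identical per-step ε), σ is calibrated once, and an accountant counts steps.
Exceeding the schedule raises a hard error; early stopping leaves unspent
budget unspent, never reallocated. No amplification-by-subsampling is
claimed: composition is plain additive, which is conservative.

No (ε, δ)-DP conversion is performed; all reports are (α, ε)-RDP.

Per-example gradients are computed by manual backprop through the dense
stacks (the mean of the per-example gradients equals the batch gradient of
the mean loss; this identity and agreement with central finite differences
are enforced by tests). Gradient vectors are flattened layer-major, weights
before biases, so serialized states are portable.

## Randomness and reproducibility

Every training run derives six named substreams from its single seed via
`SeedSequence(seed).spawn(6)`: parameter init, epoch shuffles, input
corruption, dropout masks, gradient noise, validation split. Trajectories
are bit-reproducible per seed, and the noise-free, corruption-free,
dropout-free, unclipped configuration reproduces an independent plain-SGD
implementation's trajectory exactly (this equivalence is an acceptance
test).

## Early stopping and hyperparameter search

dpClassM is evaluated once per epoch on a held-out stratified 10 % split of
its training samples; training stops when neither validation accuracy nor
validation AUC has strictly improved for `patience` (default 10) consecutive
evaluations. The hyperparameter search keeps an Indicator counter
(initial 10): candidate settings are drawn in seeded shuffled cyclic passes
over the finite grid; a candidate's score is the (mean accuracy, mean AUC)
of the classifier over cross-validation folds on that candidate's transfer
codes. Improvement means elementwise ≥ with at least one strict inequality —
the strictness prevents infinite loops on exact ties. On improvement the
Indicator resets to 10, otherwise it decrements; the loop ends at 0.
Candidate evaluation is deterministic (seed derived from base seed and grid
index), so revisits hit a cache and a size-1 grid terminates after at most
11 evaluations. Each candidate retrains the autoencoder from scratch with
the full stage budget; the per-candidate spends are reported individually
and their aggregation across the search is left to the user.

## Metrics

AUC uses the Mann–Whitney rank form (probability that a random positive
outscores a random negative, ties counted ½) rather than trapezoidal curve
integration — exact, tie-aware, and directly checkable by pair enumeration.
Spearman correlation averages tied ranks. Classification folds are
stratified (class ratios are preserved within ±1 sample per fold); regression
folds are not. Repeated experiments report the sample standard deviation
(ddof = 1; a single value has std 0 by convention).

## Synthetic data: what it emulates and what it does not

The generator draws a linear-Gaussian latent factor model: Z ~ 𝒩(0,1)
(n × k), loadings W ~ 𝒩(0,1) (k × d), X = ZW + 𝒩(0, noise_std²). Labels
follow a logistic rule on the first latent factor with the intercept solved
so the positive fraction matches `class_ratio` (default 0.8, the ~4:1
imbalance typical of ER-status cohorts); per-drug responses are linear in Z
plus noise, masked completely at random (default 30 %, leaving ~700 usable
samples per drug at n = 1000). Discrete copy-number calls in {−1, 0, 1} come
from columnwise quantile thresholding of such a matrix (15 %/15 % loss/gain
by default).

The model makes a low-dimensional code provably sufficient for both
downstream tasks, so autoencoder utility is testable against a known oracle.
It does **not** model gene–gene correlation structure, batch effects, count
noise, or informative missingness; passing tests demonstrate that the
machinery recovers recoverable structure under stated budgets, not that the
same utility holds on real cohorts. Default shapes are desk-scale
(1000 × 200, k = 10); cohort-scale shapes are reachable through the same
config.

## Width profiles and training defaults

The architecture defaults are desk-scale: encoder (64, 32, 16) with mirrored
decoder as the three-layer profile, and the `--full-scale` flag (or
`AutoencoderSpec.full_scale`) selects the 8000/4000/2000 profile for
transcriptome-width inputs through the identical code path.

The worked end-to-end experiment (`classification_experiment`) z-scores
features on the training split, uses a single-hidden-layer encoder of width
64 with dropout 0 and standardized codes, and deliberately uses different
SGD profiles per regime, because the update dynamics differ:

* non-private reference: unclipped (the clip bound is a DP device), batch 64,
  learning rate 0.3, 40 epochs for both stages — small-batch SGD to
  convergence;
* private: clip C = 1, two large batches per epoch (B = n/2), 30 autoencoder
  epochs at learning rate 0.1 and 40 classifier epochs at learning rate 1.0 —
  few, large steps so each noisy release carries a useful per-step budget
  (per-step noise grows as √T for a fixed total ε, so shorter schedules are
  quieter).

These defaults were chosen once for the desk-scale fixture by pilot runs of
the *private* pipeline (mirroring the framework's own practice of tuning on
DP outputs) and then frozen; they are arguments, not constants.

## Numerical choices

* softmax subtracts the row maximum; cross-entropy clamps probabilities at
  1e−12;
* dropout is inverted (survivors scaled by 1/(1−rate)) so inference is the
  exact identity;
* weights initialize He-normal (variance 2/fan_in), biases zero, seeded;
* all budget identities (round trips, conservation) hold to 1e−9 absolute;
* rank correlation on constant vectors and AUC with a single class present
  are errors, not NaNs;
* matrix files are strict TSV (rows = samples, `NA` for missing, 10
  significant digits); transposed files are rejected rather than guessed.

## Publication contract

A bundle directory holds `manifest.json` (format version "1", architecture
record, privacy ledger, provenance: seed + config hash, checksum) and
`arrays.npz` with layer weights. Loading verifies version and checksum and
reproduces the saved model's predictions bit-exactly; bundles contain no
rows of any input matrix and no intermediate representations (tested
structurally). Per-drug regressors are separate bundles with separate
ledgers (parallel composition over disjoint models).

## Known limitations

* The accounting is plain additive composition at one fixed Rényi order; no
  subsampling amplification, no optimal-order search, no (ε, δ) conversion.
  Reported budgets are therefore conservative but not comparable to
  (ε, δ)-DP numbers without an external conversion.
* Per-sample DP-SGD at desk-scale n (hundreds of training samples) is noisy;
  the private pipeline's utility depends strongly on batch size and schedule
  length, as the defaults above reflect.
* The decoder reconstructs through a single end-to-end loss; no layerwise
  auxiliary losses are used.
* The tuning loop evaluates once per epoch/candidate as described; the total
  privacy cost across a search is reported per candidate, not aggregated.
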