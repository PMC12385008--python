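# Methods

This note documents the models and procedures implemented in `eegstress`,
the assumptions behind them, the parameters that matter, and the design
choices made where the published description leaves the design open.

## Problem setting

The package detects a binary mental state — calm vs. stress — from
multi-channel EEG sampled at 128 Hz in 60 s trials. Labels derive from
self-reported affect ratings on the 0–9 arousal (arl) / valence (val)
scales: a trial is *calm* when arl < 4 and 4 < val < 6, *stress* when
arl > 5 and val < 3, and *unlabeled* otherwise. The inequalities are
strict, so ratings on a boundary are unlabeled. Physiologically the method
assumes the standard band signature of acute stress: suppressed alpha
(8–13 Hz) together with elevated beta (13–30 Hz) and gamma (30–45 Hz)
power.

## Signal conditioning

1. **Band-pass.** A linear-phase FIR band-pass (Hamming design, 425 taps,
   0.75–45 Hz) applied forward–backward (zero phase). The order follows
   the ≈3.3/(Δf/fs) rule for the 0.75 Hz lower transition at 128 Hz.
2. **Wavelet-packet denoising.** Each channel is decomposed into a full
   3-level db3 wavelet-packet tree (symmetric extension). The noise scale
   is estimated robustly as σ̂ = median(|c|)/0.6745 on the
   highest-frequency terminal node — the packet-tree analogue of the
   classical finest-detail estimator — and every non-approximation node is
   soft-shrunk at the universal threshold T = σ̂·sqrt(2 ln N). The
   lowest-frequency (approximation) node is spared to preserve slow EEG
   content. With T = 0 the operation is a perfect-reconstruction round
   trip (verified to 1e-8).

## Feature extraction (527 per channel)

Per channel, in fixed registry order:

| family | count | content |
|---|---|---|
| time domain | 13 | mean, SD, variance (1/N), median, skewness (biased moment), zero-crossing rate, Hjorth activity (1/(N−1)), mobility, complexity, RMS, Shannon amplitude entropy (64 bins, natural log), line length (Σ|ΔE|), nonlinear energy |
| wavelet packet | 224 | 5-level db2 tree → 32 subbands in frequency order × 7 statistics (mean, median, energy, skewness, kurtosis, variance, entropy of normalized squared coefficients) |
| spectral scalars | 3 | total energy Σx², IWMF (unit-sum Welch-PSD weighted mean frequency), IWBF (PSD-weighted variance about IWMF) |
| spectral kurtosis | 257 | per-bin excess kurtosis of the one-sided 512-sample Hann STFT magnitude (50 % overlap) |
| texture | 30 | 10-bin normalized histograms over [0, 255] of LBP, LNDP and LGP codes |

Numerical conventions: population (1/N) variance everywhere except Hjorth
activity, which uses the sample (1/(N−1)) form — both forms appear in the
printed definitions and each is followed as printed. Degenerate inputs
(constant signals, zero energy) return 0 by convention rather than NaN.

Texture coding: the 1-D LBP uses 8 neighbors (4 left, 4 right), bit = 1
when the neighbor lies below the center, weights 2^(i−1). LGP applies the
same coding to the first-difference (gradient) sequence; binary weights
are used so the mandated 10-bin histogram over [0, 255] is meaningful.
LNDP (whose operator is not standardized) compares each neighbor's
difference from the center against the next neighbor's difference,
cyclically — an ordering-sensitive descriptor in the Jaiswal–Banka style.
Downstream results never depend on LNDP values beyond count and
normalization.

The wavelet-packet feature tree uses periodization boundary handling so
the transform is orthogonal and subband energies sum exactly to the
signal energy (Parseval check at 0.1 %); the denoiser uses symmetric
extension, the common choice for smooth reconstruction.

## Channel selection: improved crow search

Crows (candidate solutions) live in [0, 1]^d; a position decodes to the k
channels with the largest coordinates (ties toward the lower index). The
subset fitness is

    fitness = w1 · EN + w2 · (1 − CV),   w1 + w2 = 1 (defaults 0.5/0.5)

where EN is the mean per-channel amplitude entropy (64 bins, normalized by
ln 64) and CV the mean absolute pairwise Pearson correlation of the
selected channels. The redundancy orientation (1 − CV) is deliberate:
rewarding raw covariance would select duplicated channels, contradicting
the stated goal of salient, non-redundant subsets; a `cv_mode="reward"`
switch preserves the alternative reading. Both statistics are precomputed
once per trial set, making fitness evaluation O(k²).

Each iteration: every crow follows a random flock member's memory with
step r·fl (fl = 2.0) unless that member is "aware" (probability AP = 0.1),
in which case the crow relocates uniformly; a Lévy-flight elite step
perturbs the best solution along the best-to-second-best direction
(Mantegna sampler, β = 1.5) and is accepted greedily; the worst member is
always pulled onto the segment toward the best memory; memories update
greedily, so the best-memory fitness trace is non-decreasing. Defaults:
flock 20, 100 iterations, constant flight length. These swarm defaults are
unstated in the source description and follow common crow-search practice.

## Hybrid classifier

Input: the per-trial feature vector (527 × k values), min-max scaled to
[0, 1] on the training set; at prediction time values are clipped into
[0, 1] — unclipped out-of-training-range features (heavy-tailed statistics
such as skewness or spectral kurtosis can overshoot by an order of
magnitude) otherwise reach the network far outside its training box and
destroy inference-mode behavior.

Three parallel branches:

* **CNN** — the vector as a 1-channel 1-D sequence through three blocks of
  (3×1 convolution, batch normalization, ReLU, /2 max-pool) with
  64/128/256 filters; the last feature map is flattened.
* **BiLSTM** — the vector reshaped to one 527-long step per selected
  channel; two bidirectional layers of 50 units; the final forward and
  backward states are concatenated (100 values).
* **DBN** — three stacked sigmoid layers of 200/150/100 units, pretrained
  greedily as RBMs with one-step contrastive divergence (Gaussian–
  Bernoulli at the bottom with mean-field reconstruction, Bernoulli
  above), then fine-tuned end to end.

Branch outputs are concatenated, passed through dropout (0.5, training
only) and one fully connected layer to a 2-way softmax. Training is
mini-batch SGD (batch 16, partial last batch kept) with initial learning
rate 1e-3, momentum 0.9 and weight decay 1e-4 under cross-entropy, 200
epochs by default (desk-scale experiments use 10). All of this runs on a
small reverse-mode autodiff tape over numpy written for this package
(`_autodiff.py`); its gradients are verified against central finite
differences to 1e-4.

Batch-norm inference statistics: with few gradient steps the exponential
running average is still biased toward its initialization, so after
training the estimator recomputes pooled mean/variance over the whole
training set in one calibration pass and freezes those for inference.
Predictions are therefore batch-composition invariant.

The experiment orchestrator trains a 3-member seeded ensemble by default
and averages predicted probabilities. Rationale: at desk scale (tens of
trials, 10 epochs) a single run occasionally settles in a confidently
wrong basin; a small deep ensemble averages such a member away. Set
`ensemble: 1` to train a single model.

## Hyper-parameter tuning: employee optimization

A population of N = 20 members in [0, 1]^n decodes log-uniformly to
learning rate [1e-4, 1e-1] and weight decay [1e-6, 1e-2], and linearly to
momentum [0.5, 0.99]. Fitness is the validation error of a truncated
(5-epoch) training run on an internal stratified 80/20 split — full-length
training inside a 100-iteration loop is not a desk-scale operation; the
returned setting is meant for one final full training. Each iteration the
top 10 % pass unchanged; the rest step relative to a random peer
(exploration, probability annealing 1 → 0 over iterations) or to the best
member (exploitation), with greedy acceptance. The printed update rules
step *away* from the reference for positive step factors; they are
implemented literally (greedy acceptance still guarantees monotone
progress) and a `toward_reference` switch provides the attraction-style
variant.

## Evaluation

Stress is the positive class. Metrics: recall TP/(TP+FN), precision
TP/(TP+FP), F1 (harmonic mean), selectivity TN/(TN+FP), NPV TN/(TN+FN),
accuracy (TP+TN)/total. Zero denominators yield NaN with a warning.
Splitting is stratified 70:30 by default with the test count floored per
class. The canonical confusion column (TP=41, FN=1, FP=1, TN=31; 74 test
trials) reproduces recall/precision/F1 = 97.6 %, selectivity/NPV = 96.9 %,
accuracy = 97.3 % at the printed precision.

## Synthetic data: what it emulates and what it does not

Each trial is a sum of one sinusoid per EEG band (random phase, frequency
drawn 0.5 Hz inside the band edges so band power is attributable to its
band) plus white Gaussian sensor noise (default SD 5 µV). Class profiles
(sinusoid amplitudes, µV): calm δ20 θ15 α40 β10 γ5; stress δ20 θ15 α15
β25 γ12 — alpha suppression with beta/gamma elevation. Informative
channels draw independent per-channel phases; all remaining channels share
one common background source per trial (a volume-conduction analogue) plus
independent noise, which makes them mutually correlated the way reference
or distant electrodes are. Ratings are drawn inside the calm
(arl ∈ (1, 3.9), val ∈ (4.1, 5.9)) and stress (arl ∈ (5.1, 8),
val ∈ (0.5, 2.9)) label regions so the rule fires on every trial.

The generator does *not* emulate 1/f background spectra, non-stationarity,
ocular/muscle artifacts, inter-subject variability, or volume-conducted
mixtures of the informative sources themselves. Passing tests on this data
therefore demonstrate that the pipeline's machinery is correct and that it
recovers planted band-power structure; they say nothing about accuracy on
real recordings.

## Problem sizes used in the checks

Desk-scale settings keep the full test suite and the acceptance script in
the minutes range on one CPU: end-to-end runs use 20 trials/class,
8 channels (4 informative), k = 4, 10 training epochs; selection property
checks use 6–20 channels with 60–200 iterations over 10 seeds; denoising
and oracle checks use 100 seeded replicates. The published architecture
constants (filter counts, unit counts, RBM sizes, dropout, learning rate,
batch size) are never scaled down.

## Known limitations

* The DEAP-scale experiment (32 subjects, 40 channels, 200 epochs) is
  supported by the code paths (container reader, defaults) but is not part
  of the test surface; the published headline accuracies on DEAP/SEED are
  not reproduced here.
* The CD-1 pretrainer is a desk-scale implementation (no persistent chains,
  no minibatch momentum schedule); with tens of samples its statistical
  benefit is limited and training works with `pretrain=False` as well.
* LNDP follows one reasonable reading of an operator that is not defined
  precisely in the source description.
* Constant feature columns scale to 0 and are carried (not dropped), which
  is functionally equivalent for the network but wastes a few parameters.
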