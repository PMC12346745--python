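# Methods

## Problem and scope

`ecgfusion` implements single-label arrhythmia classification of 10-second,
12-lead ECGs in the PTB-XL data dialect. A record carries a waveform
(millivolts, leads I, II, III, aVR, aVL, aVF, V1–V6), patient age and sex,
a set of SCP diagnostic statement codes with likelihoods in [0, 100], and a
stratification fold 1–10. The package covers the full pipeline: corpus
reading, label resolution through the five-superclass / 23-subclass
diagnostic taxonomy, task (scenario) construction, waveform augmentation,
two dual-branch neural architectures fusing ECG with demographics, micro/
macro evaluation, and per-lead Shapley attribution. A synthetic corpus
generator with planted, recoverable class structure makes every stage
testable without downloading data.

## Label resolution

PTB-XL records are multi-label; the classification tasks here are
single-label. A record's codes at or above a likelihood threshold (default
100, the most conservative reading) are mapped through the taxonomy:
exactly one superclass yields a label, zero yields "unlabeled", more than
one yields "ambiguous". Unlabeled and ambiguous records are excluded from
every scenario and the exclusions are logged. Both the threshold and the
exclusion behavior are configurable.

## Scenarios

* **Binary, case 1** — NORM vs one of {CD, HYP, MI, STTC} (superclass).
* **Binary, case 2** — NORM vs one of nine disease subclasses
  (STTC, AMI, IMI, LAFB/LPFB, LVH, IRBBB, CLBBB, ISCA, CRBBB).
* **Binary, case 3** — NORM vs abnormal, where abnormal is any record with
  a single resolved disease of any superclass. (The alternative reading —
  only diseases from an enumerated subclass list — is strictly narrower;
  the inclusive reading matches the definition of the label-resolution
  step, which already enforces "a single underlying disease".)
* **Multiclass** — the 5 superclasses in the fixed order
  [NORM, MI, CD, STTC, HYP], or NORM plus the top-(k−1) disease subclasses
  by frequency for k ∈ {10, 15}.

Top-k selection counts are computed on the **training folds only**, so held
-out data cannot influence class selection; ties at the cutoff break by
taxonomy order (deterministic, logged). When the selected set coincides
with the reference 10-/15-class lists, the published class order is used so
confusion matrices stay comparable; otherwise classes are ordered NORM
first, then by descending count.

Splits follow the curators' fold convention: folds 1–8 train, 9
validation, 10 test. Scenario definitions serialize to YAML.

## Synthetic corpus generator

Each class plants a 12-vector lead signature (mV) on a periodic train of
Gaussian bumps (width 50 ms) at a class-specific dominant frequency in the
heart-rate band (1.0–1.5 Hz stepped per class by default), plus i.i.d.
Gaussian noise, default s.d. 0.05 mV against 1 mV signatures — strong but
not trivial separation. Age is drawn from N(55, 17²) clipped to 18–95
years (an adult clinical cohort) with an optional per-class shift; sex is
Bernoulli with base ~52% male and an optional per-class log-odds shift.
Folds are uniform on 1–10 (one record per synthetic patient, so patient
stratification is moot). The corpus is a pure function of its config,
including the seed.

Two canned condition sets drive the tests: *disjoint-lead* corpora (class i
occupies only lead i; closed-form separable via per-lead energy) and
*demographics-only* corpora (identical waveform distributions across
classes, age shifted by 20 years and male log-odds by 1.5 per class, so
only the demographic branch can beat chance; the induced Bayes accuracy is
roughly 0.72–0.75).

What the generator does **not** emulate: P-QRS-T morphology, inter-lead
correlation structure, heart-rate variability, baseline wander, pathology-
specific waveform changes, or PTB-XL's empirical class prevalences. Tests
passing on these corpora demonstrate that the pipeline is wired correctly
and that each component recovers the structure it claims to recover — they
say nothing about clinical accuracy on real ECGs.

## Augmentation

Three operators, applied offline to the ECG branch of training records
only: Gaussian noise (mean 0, s.d. 0.01 mV), amplification by k = 1 + x and
attenuation by k = 1 − x with x ~ Uniform[0.001, 0.01] drawn per copy.
Noise is applied to all 12 leads independently. The default policy
("triple") adds one copy per operator, quadrupling every class count; a
"balance-to-majority" policy is available for imbalance experiments.
Labels and demographics are never altered, and augmented copies never
cross partitions.

## Architectures

Both models are dual-branch: a 1-D convolutional branch over the raw
(time × 12) signal and a dense branch over the encoded (age, sex) pair,
concatenated into a dense head [10, 10, K] with dropout 0.2 and K-way
softmax. ReLU throughout.

* **custom_cnn** — conv filters [32, 64, 128, 256, 512], kernel 3×1,
  max-pool 2×1 after each conv, batch normalization after each pool;
  flatten; dense [100, 32] with dropout 0.4.
* **vgg_style** — conv filters [64, 64, 128, 128, 256, 256, 512, 512],
  kernel 3×1, pooling after every conv layer; global average pooling;
  dense [512, 512] with dropout 0.5.

The demographic branch is dense [100, 64, 32, 16] with dropout 0.4
(9,372 trainable weights from a 2-feature input). Convolutions use "same"
padding so the time axis halves exactly at each pool; the input length must
be at least 2^(pool count). Age is z-scored with training-set statistics;
sex is encoded {0 male, 1 female}; missing demographics either exclude the
record or (by flag) impute the training median age and 0.5 sex.

Design notes. Where the custom CNN's dense stack meets the conv stack we
flatten; the VGG variant global-average-pools, which is what keeps its 512-
wide dense layers affordable and matches the architectural tradition it is
named for. Pooling after *every* VGG conv layer (rather than per pair) is
a choice; with 10 s × 100 Hz inputs it leaves a 3-sample map before GAP.
Binary tasks use a 2-way softmax with cross-entropy rather than a sigmoid,
keeping one head across all K.

## Training

Adam (lr 0.001), categorical cross-entropy, batch 16, at most 60 epochs.
Callbacks: early stopping (patience 10, min-delta 1e-4 on validation
loss), learning-rate halving on plateau (patience 5, floor 1e-5), and
best-checkpoint restoration at the epoch of minimum validation loss.
Patience/factor values are conventional defaults, exposed in `TrainConfig`.
The engine is a compact NumPy implementation (im2col-free shifted-matmul
convolutions, standard batch-norm backprop, inverted dropout, float32
arithmetic) and is fully deterministic given the config seeds. History
accuracies for training epochs are computed in training mode (dropout
active), as is conventional; quoted "training accuracy" results are
evaluation-mode accuracy on the training set.

## Evaluation

Confusion matrices are rows-actual × columns-predicted. Reports pair
micro-averaged precision/recall (algebraically equal to accuracy for
single-label tasks — the package asserts this identity) with macro-averaged
F1 and full per-class values, so the averaging convention behind every
number is explicit. 0/0 precision or recall is defined as 0 with a warning.

## Lead attribution

Leads are players in a cooperative game; v(S) is the model's probability of
the target class with leads outside S replaced by a baseline (zeros by
default; a training-mean signal is available). Demographic inputs are never
masked. With 12 players, exact Shapley values are computed by enumerating
all 4096 coalitions — this is the oracle — and a permutation-sampling
estimator provides the cheap route, unbiased and seeded. Per-class
importance is the mean of **absolute** per-record attributions (the signed
mean is an option), optionally normalized to sum to one per class for
cross-class comparison. The attributed probability is the record's actual
class, computed over (a subsample of) the test records of that class.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale: 64-record
binary corpora for capacity checks, 400–500-record corpora for scenario,
training and ablation checks, 100 Hz sampling (1000-sample inputs), and
sampled attribution with 16 permutations over ≤8 records per class. The
ablation margin is measured on a 400-record corpus drawn independently
from the same generative model rather than on the ~40-record fold-10
partition, trading no bias for a ~3× smaller sampling error on the margin.
Efficiency of the exact Shapley oracle is asserted to 1e-6; metric
identities to 1e-12; WFDB round-trips to the 0.5 µV quantization bound of
format 16 at gain 1000.

## Known limitations

* The training engine is CPU-bound NumPy; it is meant for the bundled
  desk-scale corpora and protocol fidelity, not for GPU-scale throughput
  on the full 21k-record corpus (the optional reproduction script will be
  slow there).
* Waveform synthesis is deliberately non-physiological (see above).
* No denoising/filtering is applied to input signals, and the form/rhythm
  statement hierarchies of the SCP standard are ignored — only the
  diagnostic axis is modeled.
* No multi-label evaluation and no ROC/AUC; tasks are single-label by
  construction.
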