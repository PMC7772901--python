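# Methods

## Problem and models

The package classifies short segments of wearable physiological recordings
into affective conditions. Two tasks are supported: binary stress detection
(stress vs. non-stress, where non-stress pools baseline and amusement) and
3-class emotion classification (baseline / stress / amusement). Two
architectures are provided, one per sensor site.

**Chest 1-D CNN.** The chest-worn device samples eight channels at 700 Hz:
ECG, EDA, EMG, respiration, skin temperature and the three accelerometer
axes (each axis is a separate input). Each channel's 5 s window (a
3500-sample vector) enters its own copy of one identical convolutional
block:

| stage | filters | kernel | stride | pool | pool stride |
|------:|--------:|-------:|-------:|-----:|------------:|
| 1     | 8       | 15     | 2      | 4    | 4           |
| 2     | 16      | 7      | 2      | 4    | 4           |
| 3     | 32      | 3      | 1      | 2    | 2           |

All convolutions use ReLU and valid (no-padding) arithmetic with floor
rounding, `out = ⌊(in − k)/s⌋ + 1`, giving the chain
3500 → 1743 → 435 → 215 → 53 → 51 → 25: the block emits 32 feature maps of
length 25. A widely-quoted figure for this block is 32 maps of length 17;
that length is not reachable from the table above under any standard padding
convention, but becomes exact if the final pooling stage uses size/stride 3
instead of 2. Both configurations ship
(`CHEST_BLOCK_DEFAULT`, `CHEST_BLOCK_SHORT_OUTPUT`); the default follows the
stated hyperparameters and neither is silently corrected. Block outputs are
flattened time-major, concatenated in channel order, and fused by dense
32 → dense 16 → output head. With ACC the model has 8 branches and 226,275
parameters (3-class); without ACC, 5 branches.

**Wrist MLP.** The wrist device samples BVP at 64 Hz, ACC at 32 Hz, EDA and
skin temperature at 4 Hz. At 5 s windows: BVP 320 samples → dense 64 → 32;
the three ACC axes are flattened axis-major into one 480-vector → dense 32;
those two branch outputs are concatenated with the raw 20-sample EDA and
TEMP vectors (width 32+32+20+20 = 104) and fused by three dense layers whose
middle width is 8. The first fused width is not pinned down by the
architecture description; the package default is 64 (configurable in
`WristConfig`).

For both models the binary head is 1 sigmoid unit and the 3-class head is
3 softmax units; that last layer is the *only* structural difference
between the tasks (checked by `graph_diff`).

## Training protocol

Adam (learning rate 0.001 — unstated by the protocol, this is the
conventional default), binary or categorical cross-entropy bound to the
task, 100 epochs, batch size 40. The pooled window set is randomly
scrambled and split 7:3; the protocol additionally runs tenfold
cross-validation. The relationship between the hold-out and the CV is not
specified by the protocol; the package's reconciliation is: folds are built
on the 70 % training portion as model-selection telemetry, the network is
refit on the full training portion, and the reported metrics come from the
30 % hold-out. `ProtocolResult` exposes all three readings (hold-out, CV
mean, best fold).

The split is window-level by default — scrambling the pooled windows means
one subject's windows can land on both sides, which inflates accuracy
relative to subject-independent evaluation. A stricter `level="subject"`
split is provided.

No deep-learning framework is used: `stresswear.nn` is the package's own
NumPy engine (im2col valid convolution, max-pool with argmax scatter,
dense layers, log-sum-exp cross-entropy, Adam), with hand-written backward
passes. It is fully seeded — weight draws come from one
`default_rng(seed)` stream in declared branch order, batch order from a
derived stream — so two runs with the same seed and data produce
bit-identical reports on the same machine.

**Normalization.** Per-channel z-scoring is applied by default, with scalar
mean/sd per channel estimated on the training split only; raw channels
differ in scale by orders of magnitude (ECG ~1 unit, temperature ~34 °C)
and unnormalized training diverges or stalls at these learning rates. A
global per-channel statistic (not per-window) preserves the between-window
mean differences that carry condition information. `normalize=False`
preserves the literal raw-input reading.

## Windowing

5 s windows, stride 5 s (non-overlapping) by default; both configurable.
A window is emitted only if every channel has a full-length slice at its
native rate and the 700 Hz label slice is acceptably pure: the modal code
must be a study condition (codes 1/2/3 of the dataset's documented set
0–7) and occupy at least `purity` of the slice. Default purity is 1.0 —
single-condition windows only — so transition windows are dropped rather
than ambiguously labelled; a majority rule is available by lowering
`purity`. Channels are never resampled; each branch consumes its native
rate.

## Metrics

accuracy = (TP + TN) / total; precision = TP/(TP+FP); recall = TP/(TP+FN);
F1 = 2PR/(P+R). Binary reports use exactly these with class 1 (stress)
positive. Multi-class reports compute per-class one-vs-rest scores and
report the macro average as the headline F1 (the averaging rule is
unstated upstream; macro is the conservative choice), with micro and
weighted variants alongside. Zero-denominator conventions: precision or
recall is 0 when undefined, F1 is 0 when precision + recall = 0.

## Synthetic data generator

The generator's job is statistical structure at the right shapes and rates,
not biophysical fidelity: chest channels at 700 Hz, wrist at 64/32/4/4 Hz,
and a 700 Hz label track following the (condition, duration) schedule
exactly. Signal models per channel: ECG/BVP are Gaussian pulse-template
trains at the condition's heart rate (template width 20 ms chest / 80 ms
wrist, 2 % beat-interval jitter); EDA is a tonic level plus
Poisson-arriving phasic events with 2 s exponential decay; respiration is a
sinusoid at the breathing rate; EMG and ACC are variance-coded noise (plus
a unit gravity offset on ACC_Z); temperature is a baseline with slow drift.
Gaussian sensor noise is added per channel.

Default condition parameters (chosen once for physiological plausibility;
no source states them):

| condition | HR (bpm) | EDA tonic (µS) | EDA events (/s) | resp (/min) | temp (°C) | ACC sd | EMG sd |
|-----------|---------:|---------------:|----------------:|------------:|----------:|-------:|-------:|
| baseline  | 65       | 2.0            | 0.05            | 14          | 34.0      | 0.05   | 0.10   |
| stress    | 90       | 8.0            | 0.30            | 20          | 34.4      | 0.15   | 0.30   |
| amusement | 75       | 5.0            | 0.15            | 16          | 34.4      | 0.10   | 0.15   |

Stress and amusement deliberately share the temperature baseline, so no
single slow channel separates them; they differ on EDA and pulse rate. The
task is therefore learnable but not single-channel trivial — a linear probe
on per-window channel means already beats chance, which is the point: the
end-to-end accuracy bars test the pipeline, not a miracle. Per-subject
parameter jitter (relative sd 0.05) models inter-subject variability.
Everything is deterministic per (seed, subject_index), with per-channel
seed keys that avoid Python string hashing so records are identical across
processes.

What the generator does **not** emulate: real ECG morphology (P-QRS-T),
motion artifacts, sensor drift and dropouts, the real dataset's
inter-subject distributions, or transient/meditation label periods.
Passing the synthetic benchmarks therefore demonstrates that the pipeline,
architectures and training loop work end to end — not that the headline
accuracies on the real dataset are reproduced. The `reproduce-wesad` CLI
command runs the full experiment grid (2 models × 2 tasks × ±ACC, full
protocol) on a locally downloaded copy of the dataset for that purpose.

## Benchmark problem sizes

The package's standard end-to-end benchmark (`synthetic_benchmark`) uses
6 subjects × 60 s per condition (216 five-second windows, 151 train /
65 test) and 20 epochs — large enough that the chest CNN reaches ≥ 0.95
3-class hold-out accuracy and the wrist MLP ≥ 0.90, small enough that a
chest run takes well under a minute on one CPU. The label-permuted control
(labels shuffled once before the split) lands at chance (1/3 ± 0.10). The
tenfold-CV telemetry is exercised in unit tests at small size and skipped
in the benchmark (`cv_folds=0`).

## Numerical choices and degenerate inputs

- Valid convolution/pooling only; a kernel longer than its input raises,
  naming the failing stage.
- Softmax is max-shifted; cross-entropy is computed in log-sum-exp form;
  sigmoid is split-branch stable. A non-finite loss aborts training with a
  diagnostic rather than continuing.
- Weight init: Glorot variance-scaling uniform, biases zero.
- Binary decoding threshold 0.5; 3-class decoding argmax (ties broken to
  the lowest index by `argmax`).
- 7:3 split size is `round(0.7·n)`, clamped so neither side is empty;
  fold sizes differ by ≤ 1, the earlier folds taking the remainder.
- The fixture text format stores floats via `repr`, the shortest exact
  round-trip representation, so write→read is bit-lossless.
- Empty test sets, unmapped window sets, task/graph mismatches and unknown
  condition codes raise with the offending name in the message.

## Known limitations

- Window-level splitting mixes subjects across train and test; reported
  hold-out numbers are optimistic relative to leave-subject-out protocols.
- The NumPy engine is single-threaded-deterministic but not fast; it is
  sized for the benchmark and the real-data experiment at 100 epochs, not
  for large-scale sweeps.
- The generator's minimal realism means synthetic results say nothing
  quantitative about real-world stress-detection accuracy.
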