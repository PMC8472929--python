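# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `gasfnet`.

## GASF encoding

A segment is min–max rescaled per segment to [−1, 1] (per-segment rather
than per-record, so every image uses the full dynamic range; the
alternative is exposed simply by rescaling before segmentation). A
constant segment has no span and maps to all zeros by convention (logged
as a warning) — this keeps arccos defined and encodes "no information"
as the mid-range angle π/2. Piecewise aggregate approximation splits the
series into S frames whose lengths differ by at most one, remainder
frames leading, and takes frame means; the default image side is 224
(the canonical ResNet-50 input), and the desk-scale benchmark uses 64.
Values within 1e-12 of ±1 are clamped before arccos; anything further
out is rejected. Only the summation field is implemented; the difference
field adds nothing to this classification pipeline and is out of scope.
PNG export quantizes [−1, 1] to 8 bits for visualization only — training
always consumes the float matrices.

## Network architectures

`build_baseline_resnet50` is canonical ResNet-50: a 7×7/2 stem
convolution + BN + activation + 3×3/2 max pool, four stages of
post-activation bottleneck blocks (3, 4, 6, 3; mid/out channels
64/256, 128/512, 256/1024, 512/2048), stride 2 on the first 1×1 trunk
convolution of each downsampling block, 1×1/2 projection bypasses, and
a global-average-pool + linear head. With a 3-channel input and 1000
classes its parameter count is 25,557,032, matching the published size
of the reference architecture, which the test suite checks against an
independent per-layer enumeration.

`build_improved_resnet` applies four changes. (1) Pre-activation
bottlenecks: BN → activation → conv, three times per trunk. (2) The
stride-2 of a downsampling block sits on the 3×3 convolution (a strided
1×1 discards three quarters of its input); the 1×1 convolutions keep
stride 1. (3) The bypass of each downsampling block is a 2×2/2 average
pool followed by a stride-1 1×1 convolution; the first stage changes
channels but not spatial size, so it keeps a plain 1×1 projection.
(4) Five auxiliary shortcut groups, all 1×1 convolutions followed by BN
(no activation, keeping the branches near-linear): one per stage with
strides 1, 2, 2, 2 mapping the stage input to the stage output shape,
and one global branch with stride 8 mapping the stem output (64
channels, side/4) to the final stage's output (2048 channels, side/32).
Each branch output is added at the end of the span it bridges; the
global sum is taken before the final BN + activation that pre-activation
networks require ahead of the head. The junction placement (before the
final activation) is a design choice; the alternative (after) is a
one-line change in `NumpyModel.forward` and was not found to matter at
desk scale.

GASF images are single-channel, so the stem convolution takes one input
channel by default (`in_channels` is configurable; replicating to three
channels is equivalent up to stem weights). The head and loss —
global average pool, linear layer, softmax cross-entropy — are the
standard choice. Weight initialization is Gaussian fan-in scaling: gain
√2 for ReLU networks, 1 (LeCun) for SELU networks, as the
self-normalizing fixed point assumes.

Both builders accept a reduced `blocks` plan and a channel `width`
multiplier for small experiments; the defaults are the canonical
(3, 4, 6, 3) at full width.

## Numpy training core

No deep-learning framework is used: `gasfnet._nn` implements im2col
convolution, batch normalization (momentum 0.1, eps 1e-5), ReLU/SELU,
max/average pooling, a linear head, softmax cross-entropy and Adam
(β = 0.9/0.999, eps 1e-8), each with an explicit backward pass verified
against central-difference gradients in the test suite. Float32 is the
working precision; float64 is available for gradient checking.
Determinism is per-machine: the same seed, data and config reproduce the
same history bit-for-bit on one machine, but cross-BLAS bit equality is
not promised.

The training loop mirrors the study configuration: Adam, learning rate
1e-4, batch size 32, 150 epochs, per-class 8:2 split with the *floor on
the training side* — the only rounding rule consistent with the
reference per-class allocation (e.g. 328 → 262/66, 2106 → 1684/422).
Test accuracy is recorded every epoch, i.e. the test set doubles as a
monitoring set; there is no third held-out partition, so per-epoch test
accuracy is an optimistic monitoring quantity, reproduced as in the
study design.

## Evaluation

Confusion matrices are oriented rows = real, columns = predicted.
Per-class metrics are exact `Fraction`s until display; percentages are
rounded to one decimal, half away from zero. A zero denominator (e.g.
specificity of a one-class matrix, precision of a never-predicted
class) yields an explicit *undefined*, which propagates into the
macro average rather than being imputed as zero. The support-weighted
mean of per-class sensitivities equals the micro accuracy (trace over
total) — an algebraic identity used as a property test.

## Synthetic rhythm generator

The generator is phenomenological, not physiological: each beat is a sum
of Gaussian bumps (P, QRS with an S-dip, T) at fixed onset delays
(0.12 s, 0.25 s, 0.45 s, compressed proportionally when the cycle is
shorter than 0.6 s), with widths given as full width at half maximum in
milliseconds. Anchoring the complex at the cycle onset — rather than at
a fixed phase fraction — makes QRS-to-QRS intervals reproduce the drawn
RR sequence exactly, which is what rhythm statistics measure.

Class definitions (defaults, all configurable per `RhythmSpec`):

| class | rate band (bpm) | RR CV | QRS FWHM | distinguishing features |
|-------|-----------------|-------|----------|-------------------------|
| N     | 62–98   | 0.03 | 80 ms  | P waves, regular |
| SBR   | 40–57   | 0.03 | 80 ms  | slow, regular |
| AT    | 155–215 | 0.02 | 80 ms  | fast, narrow, regular |
| VT    | 150–200 | 0.03 | 150 ms | fast, wide, no P |
| AF    | 95–135  | 0.22 | 80 ms  | irregular RR, no P, 4–9 Hz fibrillatory baseline |
| PAC   | 62–98   | 0.03 | 80 ms  | early narrow beats (p = 0.18/cycle) |
| PVC   | 62–98   | 0.03 | 150 ms (ectopic) | early wide, large beats (p = 0.18/cycle) |

Premature beats arrive at 0.62 of the expected interval and are followed
by a compensatory pause; strips of the ectopic classes always contain at
least one ectopic beat, mirroring how labeled excerpts are selected from
annotated recordings. Measurement noise is white Gaussian with standard
deviation 2% of the QRS amplitude. Each strip draws its mean rate
uniformly from the class band and is fully reproducible from its seed.
Default class proportions mirror the reference dataset distribution
(AF 1841, AT 500, N 4800, PAC 328, PVC 2106, SBR 1855, VT 294) at a
configurable scale.

A deliberately trivial rule classifier (QRS-width fraction, RR
coefficient of variation, deviant-interval fraction, rate, P-amplitude
estimate over beats preceded by at least the median RR) reaches ~98% on
generated data; its role is to certify that the classes are separable
from first-principles rhythm statistics, so that success or failure of
the networks reflects the learning pipeline rather than unlearnable
data. What passing these tests does **not** show: robustness to real
morphological variability, baseline wander, electrode noise, inter-
patient variation, or any clinical performance — the generator has none
of these.

## Desk-scale benchmark

The published full-scale experiment (11,724 strips, 150-epoch ResNet-50
training on database extractions whose windowing and labeling rules are
not published) is out of reach of a desk run; the package instead fixes
a scaled-down benchmark chosen once: reference class proportions at 1%
(117 strips), 8-second strips of 1000 samples at 125 Hz, 64×64 GASF
images, the improved variant at block plan (1, 1, 1, 1) and full
channel width, Adam at learning rate 3e-4 (the 1e-4 default is tied to
a 150-epoch budget; 3e-4 suits 30 epochs), batch 16, 30 epochs, fixed
seed. Under these conditions the improved-SELU network reaches ≥ 90%
held-out accuracy (96.2% at the recorded seed) in about four minutes on
one CPU.

"Training loss drops rapidly and stabilizes" is tested operationally on
the 10-epoch moving average of the epoch loss: no step-increase larger
than 10% of the initial moving-average level, and a final level below
half the initial. Strict monotonicity is not attainable for stochastic
minibatch training once the loss plateaus near zero, where batch noise
exceeds the remaining decline.

## Formats and conventions

All indices are 0-based; windows are half-open `[start, start + window)`
with the window defaulting to 2000 samples and the stride to the window
(non-overlapping). Multi-channel records use channel 0 unless told
otherwise. The WFDB reader handles headers, signal formats 16 and
212, and MIT-style `.atr` beat annotations; other signal formats raise
an error naming the code. The annotation-symbol → class map is an
editable table (defaults: 'N' → N, 'A' → PAC, 'V' → PVC, plus
rhythm-label symbols), with majority voting per window and ties broken
by the canonical class order (AF, AT, N, PAC, PVC, SBR, VT); segments
with no mapped annotation are dropped and counted.

## Known limitations

* The synthetic generator's idealized morphology makes the desk-scale
  task easier than real ECG classification; reported desk-scale
  accuracies certify the pipeline, not clinical performance.
* The numpy core is CPU-only and unoptimized beyond BLAS matmuls; a
  full-scale 150-epoch run at 224×224 is possible but slow.
* Filtering, denoising, resampling and QRS detection are out of scope
  (assumed done upstream); the rule classifier's peak detector is a
  test instrument, not a clinical QRS detector.
* The published per-class metric table is not fully consistent with the
  published confusion matrix it accompanies; the evaluation module
  recomputes everything from counts and reports the recomputed values
  (e.g. micro accuracy 2305/2347 = 98.2% versus the printed 98.3%).
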