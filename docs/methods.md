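# Methods

## Signal chain and its assumptions

The detection pipeline treats the instrumented vertebra as a linear,
time-invariant transfer path from the excitation point (spinous process) to
the sensor (screw head), probed by a sine sweep. Loosening is assumed to
change that path — and to add nonlinear contact effects — in ways that are
visible in a time–frequency representation of the response. The classifier
makes no mechanistic assumptions; it learns the fixed/loose contrast from
labeled spectrograms, and the leave-one-specimen-out protocol measures
whether what it learns transfers to an unseen specimen.

### Excitation

A linear chirp from 10 to 500 Hz over 2.5 s at 44.1 kHz, zero initial phase.
The capture protocol the package models does not specify the sweep's
amplitude or frequency law; we default to a linear law (the plainest reading
of a stated frequency range) with an exponential option, and a peak of 0.8
full scale so that simulated resonant gain has headroom before clipping.

### Log-mel front end

`X(m,k) = Σₙ x(n+mH) w(n) exp(−2πikn/N)` with a periodic Hann window,
N = 2048 and hop H = 256, centered frames (reflect padding by N/2); then 256
unit-peak triangular mel filters between 0 Hz and the Nyquist frequency, and
`10 log₁₀(·²)` on the filtered magnitudes with an amplitude floor of 1e-10
(absolute reference, no peak-relative rescaling or top-dB clipping).

Two reconciliations were needed:

- **Frame count.** A 2.5 s, 44.1 kHz waveform framed at hop 256 yields ~431
  frames, not the 218 columns of the published feature shape. The pipeline
  therefore resamples to 22 050 Hz and trims/zero-pads to a canonical 55 552
  samples, which makes centered framing produce exactly
  `1 + 55552/256 = 218` frames. This is one consistent reconstruction of an
  unstated resampling step; it preserves the full 0–500 Hz excitation band
  and the harmonics that matter up to 11 kHz.
- **Operation order.** The dB map is applied after the mel filterbank
  (mel on magnitudes, then dB), the order used by standard log-mel
  implementations; applying dB first would make the triangular filters
  average log-amplitudes instead of energies.

`N` is read as the window/FFT length, not the full signal length. The mel
formula is the 2595·log₁₀(1 + f/700) convention, used exactly, with its
algebraic inverse.

Normalization is global standardization by a scalar mean and standard
deviation. Default scope is *train-only* (statistics fitted inside each
training fold, no leakage); an *entire-dataset* scope is provided and used
when reproducing the original protocol, which computed the statistics over
the whole dataset.

### Augmentation

Pitch shift with a semitone offset drawn uniformly (continuously) from
[−3, 3] and time stretch with a factor drawn from {0.9, 1.1}, applied to the
raw waveform and re-trimmed to the original length. Whether the original
protocol drew integer or continuous semitones is unstated; continuous is the
more general reading. Both operations run through an STFT phase vocoder
(2048/512); pitch shifting resamples by 2^(s/12) and restores duration with
the vocoder. Augmented copies are created for training folds only, each
training sample contributing its original plus `n_augment` copies.

### Classifier

An 18-weighted-layer residual network: 3×3 stride-1 stem convolution (the
published figure states 3×3 filters everywhere, overriding the canonical 7×7
stem), batch norm, ReLU, 2×2 max pool; four stages of two residual blocks
with stage widths (64, 128, 256, 512) — the canonical 18-layer widths, since
the per-block counts in the figure are not fully legible; each block is
conv-BN-ReLU, conv-BN, squeeze-and-excitation (reduction r = 8, placed after
the second convolution and before the shortcut addition, as in the reference
SE-ResNet arrangement), shortcut add, ReLU; stride-2 1×1 projection
shortcuts at stage transitions; global average pooling and a single-logit
head. `use_se=False` gives the plain residual baseline for the ablation.

Training: Adam, binary cross-entropy on logits, learning rate 1e-5 for 10
epochs (the published recipe, kept as the default), batch size 16 (unstated
in the original; chosen to fit desk-scale memory). The decision threshold is
0.5 with *loose* as the positive class; a probability exactly at the
threshold classifies as fixed (the decision requires strictly exceeding it).

The network and its training loop are implemented in float32 numpy with
manual backpropagation (layers in `nn.py`). Convolutions are evaluated as
shifted GEMMs; batch-norm running statistics are warm-started from the first
batch so that inference statistics are meaningful even after short trainings.
All randomness flows through seeded generators, making training runs
bit-reproducible.

## Synthetic data generator

The generator's job is to produce data with the statistical structure the
method assumes, not anatomically faithful bone acoustics.

- **Transfer path:** seven damped modes between ~90 and ~1100 Hz with
  damping ratios 0.025–0.07 and decreasing gains. Each specimen jitters
  frequencies (log-normal, σ = 8 %), dampings (σ = 15 %), and gains
  (σ = 20 %), plus a bone-quality damping multiplier drawn from
  U(0.8, 1.3) — a stand-in for anatomical variation between specimens.
- **Loosening contrast** (each component scaled by `separation` ∈ [0, 1]):
  mode frequencies shift by −12 %, damping scales by 0.6 (a looser screw
  rings longer), cubic "rattle" waveshaping at relative amplitude 0.15
  (odd harmonics of the excitation), and high-passed (>600 Hz) broadband
  noise at 8 % of signal RMS. These magnitudes are free parameters chosen
  once to reproduce the only stated empirical signature — loose responses
  carry more high-frequency and more distributed spectral energy — and are
  not cadaver-validated. `separation=0` makes the conditions *exactly*
  identical (same bytes for matched seeds), giving a built-in null
  experiment.
- **Per-sweep variability:** the capture protocol lifted and replaced the
  shaker between sweeps; this is emulated with a gain jitter of ±10 % and a
  random onset delay up to 5 ms, plus measurement noise at 30 dB SNR.
- **Seeding:** a single master seed plus the record's metadata tuple
  deterministically derives every per-record stream (`SeedSequence` with
  integer tag paths), so datasets are bit-reproducible and independent of
  generation order.
- **Trajectories:** triangular flexion–extension cycles at 5°/s over a ±15°
  range of motion (a fixed-range emulation of the torque-limited endpoints
  of the biomechanical protocol), 30 cycles at 30 Hz. The rod reference
  point sits 40 mm from the vertebral point; toggling is modeled as a
  relative displacement proportional to the applied angle with amplitude
  0.5 mm in the fixed condition, multiplied by `loosening_gain` (default 4,
  in the range of the reported per-screw ratios) when loose; i.i.d. Gaussian
  tracking noise (0.05 mm per axis) is added to every body. Only
  reference-point positions are generated — the movement statistic uses
  only a point distance, so full 6-DoF poses are unnecessary.

What passing tests on these data do *not* show: robustness to real
anatomical variability, soft-tissue damping, sensor coupling variation, or
any loosening signature other than the modeled one. They show that the
pipeline recovers a contrast of the assumed form when present and finds
nothing when it is absent.

## Loosening statistic

`Δxᵢ = ‖x_L2 − x_rod‖` on a synchronized grid (linear interpolation onto the
overlap of the two time ranges at the coarser rate; the original tracking
alignment is not described), then the mean absolute deviation
`x̂ = (1/n) Σ |Δxᵢ − mean(Δx)|`, then `R_lf = x̂_loose / x̂_fixed` with a
strict threshold at 2. The statistic's index overloading in the original
formulation (screw index vs. time index) is resolved as: one x̂ per screw,
computed over its time-indexed distance series. x̂ is invariant to constant
marker offsets and linear in toggling amplitude, so on noiseless synthetic
trajectories the computed ratio equals the injected gain to machine
precision; with the default tracking noise it stays within a few percent
(the noise inflates both numerator and denominator slightly).

A known inconsistency in the source material: the published per-screw ratios
are not the quotients of the published displacement summaries (e.g.
2.5323/0.5998 ≈ 4.22 vs. a printed 6.9462), implying the displacement table
reports a different summary than x̂. The package implements the defining
formulas literally and does not attempt to reproduce one table from the
other.

## Evaluation conventions

- Folds split at the specimen level; each test fold is one specimen's full
  recording set (both sensors, both conditions).
- Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy from each
  fold's pooled confusion counts, all as percentages.
- Aggregation is mean ± **population** (ddof = 0) standard deviation across
  folds: applied to the published per-fold columns this reproduces the
  published 91.50 ± 6.58 and 91.10 ± 2.27 exactly at two decimals, whereas
  the sample convention (ddof = 1) would give ±7.59/±2.62. One published
  fold specificity (87.76 %) is not an integer percentage of a balanced
  100-negative test set, implying an unstated test composition; synthetic
  folds here are balanced and the discrepancy is documented, not emulated.

## Problem sizes for the checks

The published configuration (50 sweeps per screw, stage widths 64–512, 10
epochs at lr 1e-5) is the package default. The training-based checks in the
test suite and acceptance script run a *desk-scale* configuration chosen
once: 10 sweeps per screw (160 recordings), stage widths (8, 16, 32, 64),
3 epochs at lr 1e-3, batch 16, one augmented copy per training sample, with
the full 256 × 218 features. The ablation and augmentation-retention
property checks use a further-reduced 64 × 55 front end (hop 1024, 64 mel
bins — full bandwidth and duration, coarser resolution). These sizes are the
package's choice of a configuration that a single CPU evaluates comfortably
while leaving the learning problem qualitatively intact (at full separation
the desk-scale model reaches 100 % LOSO accuracy; at zero separation it sits
at chance).

## Numerical choices

- WAV quantization: signed 24-bit full scale of 2²³; round-trip error is
  bounded by 2⁻²³. Readers accept 16/24/32-bit PCM and float WAVs; only mono
  is valid.
- Amplitude floor 1e-10 before the log keeps silent inputs finite
  (constant −400 dB matrices).
- Degenerate inputs raise rather than propagate: zero-variance
  normalization, single-class training sets, empty waveforms, a zero fixed
  movement (the ratio is refused, not returned as infinity).
- Ties at decision boundaries resolve to the negative class (probability
  exactly 0.5 → fixed; ratio exactly 2 → not loose).
- Mode parameters are clipped to (20, 4000) Hz and damping to
  (0.005, 0.2) after jitter/condition shifts.

## Known limitations

- The simulator is a mechanistic stand-in; none of its parameters are fitted
  to measurements, so absolute performance numbers on synthetic data say
  nothing quantitative about cadaveric or in-vivo performance.
- The numpy network trains at desk scale only; the full-width published
  configuration is buildable and trainable but slow without a GPU framework.
- Phase-vocoder augmentation introduces mild transient smearing; identity
  parameters short-circuit to an exact copy, and the label-retention
  property is verified on the synthetic task.
- The CLI's `train` command fits one model on a whole dataset (no held-out
  specimen); specimen-level claims should always come from `crossval`.
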