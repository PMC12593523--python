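# Methods

This note records the scientific and numerical choices behind the
package: the signal model, each pipeline stage's assumptions and
parameters, what the synthetic cohort does and does not emulate, and the
places where the architecture description left genuine design freedom.

## Signal model and preprocessing

### Wiener denoising

The observed signal is modeled as `x(n) = d(n) + v(n)` with `d` the clean
biosignal and `v` additive noise uncorrelated with `d`. The length-`p`
FIR filter minimizing `E[(y − d)²]` solves the Wiener–Hopf system
`R_xx Ψ = r_xd` with `R_xx` the `p×p` Toeplitz autocorrelation matrix.
`r_xd` involves the unobservable clean signal; under the additive model
`r_xd = r_xx − r_vv`. Two noise models are provided:

* `white_mad` (default): white noise, so `r_vv = σ̂²·e₀`, with
  `σ̂ = MAD(Δx)/(√2·0.6745)`. Differencing suppresses the smooth signal;
  the `√2` accounts for the variance of a difference of two i.i.d.
  samples and 0.6745 converts MAD to a Gaussian standard deviation. A
  noiseless signal (identically zero MAD of differences, e.g. a ramp)
  yields exactly the identity tap vector `e₀`.
* `reference_segment`: `r_vv` estimated from a user-marked noise-only
  slice, for structured noise.

Parameters: filter order `p = 32` and whole-signal autocorrelation by
default (the order/window of this filter family is reported as
empirically determined; both are configuration knobs, and a frame-based
variant with per-frame taps is available). The Toeplitz system is solved
by Levinson recursion (`scipy.linalg.solve_toeplitz`); a condition number
above 1e12 triggers a ridge of `1e-8·r_xx(0)` with a logged warning.
Autocorrelations are biased FFT estimates, which keep `R_xx` positive
semi-definite.

### Normalization

Min–max normalization maps the observed range linearly onto
`[new_min, new_max]` (default [0, 1]). It is applied **per segment**, not
per record, so window amplitudes are comparable across a recording whose
gain drifts; the transformation itself is silent on scope, and this choice
is the package's. Constant input is degenerate and maps to `new_min` with
a logged warning rather than dividing by zero.

### False-peak elimination

Candidates are local maxima of `|x|` above the adaptive threshold
`θ(t) = median_w(|x|) + c·MAD_w(|x|)` with `w = 2 s` windows (evaluated
block-wise at 1-s hops and linearly interpolated) and `c = 4`. Each
candidate is scored with: robust z-scores of its shortest inter-peak gap
and of its absolute amplitude (both relative to the candidate population,
scale 1.4826·MAD); variance, skewness and kurtosis in a ±100 ms window;
the fraction of spectral power outside the modality's physiological band
(ECG 0.5–40 Hz, PCG 25–400 Hz); and, when a time-aligned paired modality
is supplied, a cross-channel correlation feature. A peak is flagged false
when at least 2 features pass their cutoffs (|z| > 3, kurtosis > 8,
out-of-band ratio > 0.5). The feature families are prescribed by the
method description; the numeric cutoffs, the 2-s window, `c = 4` and the
2-vote rule are this package's calibration, chosen so that a clean
synthetic ECG produces zero false flags while 5×-amplitude spikes are
caught with ≥ 90% sensitivity.

Repair replaces ±100 ms around each flagged peak with a
**shape-preserving cubic** (PCHIP) fitted to the flanking 100 ms on each
side. A natural cubic spline overshoots badly between oscillatory
heart-sound flanks (observed excursions of 5× the signal range on PCG,
which destroyed the murmur-band class signal); PCHIP is bounded by the
flank values. A peak too close to a signal edge to have flanks on both
sides is filled with the available flank's median instead of letting a
polynomial extrapolate. The voting rule makes single-feature outliers
(e.g. a genuine R peak whose interval was shortened by an adjacent
artifact) survive, which is what keeps R-peak retention above 95%.

A pipeline-level guard is tested: the murmur-band (120–400 Hz)
power-fraction AUC between classes must move by less than 10% across the
whole preprocessing chain — denoising is not allowed to erase the class
signal it is supposed to expose.

### Segmentation

Fixed 8-s windows; stride 8 s for positive-class records (including the
AD/MVP/MPC subtypes) and 3 s for negative ones, giving
`⌊(L−w)/s⌋ + 1` windows and roughly 1:1 segment-level class balance from
a 2.4:1 cohort. Records shorter than 8 s produce an empty archive with a
logged skip.

## Synthetic cohort

The generator emulates a screening population of paired single-channel
ECG/PCG recordings:

* **Durations**: lognormal with log-mean `ln 31.7` and log-sd 0.15,
  clipped to [9, 36] s — matching a duration profile with mean ≈ 31.7 s
  inside a 9–36 s envelope while keeping every record segmentable.
* **ECG**: per-beat Gaussian components (P 0.12 mV, Q −0.10, R 1.0,
  S −0.15, T 0.30; widths 10–60 ms) on an RR grid with between-subject
  heart rate 70 ± 7 bpm and within-subject RR jitter of 3%. Ground-truth
  R-peak indices ride along in record metadata.
* **PCG**: Gaussian-windowed sinusoid bursts — S1 (90 Hz, 100 ms) at each
  R peak, S2 (120 Hz, 80 ms) at `R + 0.35·RR` (end of systole;
  configurable). The positive-class effect is band-limited (120–400 Hz)
  noise in the systolic interval at 0.5× the measured S1 power, which
  separates the classes in murmur-band power with effect size d ≫ 2.
  With subtype labels enabled, AD/MVP/MPC murmurs occupy different
  sub-bands.
* **Corruption**: baseline wander (random 0.2–0.5 Hz sinusoid, 10% of
  peak), 50 Hz powerline (5% of peak), white noise at a target SNR
  (default 15 dB), and Poisson-placed spike artifacts (default 0.1/s,
  4-ms Gaussians at 5× peak amplitude) whose positions are the ground
  truth for the false-peak tests.

All randomness flows through `numpy.random.default_rng` seeded with
`[cohort_seed, subject_stream]`, so one seed reproduces a bit-identical
cohort. What the generator does **not** emulate: realistic ECG/PCG
morphology variation and pathology beyond the murmur band-power effect,
respiration coupling, multi-lead montages, or recording-device transfer
functions. Passing tests on this cohort therefore demonstrate that the
pipeline machinery works and that a strong, physiologically plausible
class effect is recovered — not clinical-grade performance on real
stethoscope data.

## Feature volumes

An 8-s, 2 kHz segment → Hann-windowed STFT (`n_fft = 256`, hop 128) →
`T = 124` frames × 128 non-Nyquist bins → uniform averaging to `B = 32`
bins → `log1p` magnitude → frames tiled row-major onto a 12×12 grid
(edge-padded with the last frame) → per-volume min–max to [0, 1]. The
mapping from a 1-D signal to the 3-D input cube is not fixed by the
architecture description; this tiling was chosen because it makes the
`(1,1,k)` "spectral" kernels act purely on frequency and the `(k,k,1)` /
`(k,1,1)` kernels act on time-frame structure, consistent with the
printed kernel shapes. An all-zero segment maps to an all-zero volume
(degenerate-range guard).

## Network architecture choices

Decisions made where the description left freedom, all configurable:

* **Dense concatenation** inside a pyramidal block (input + three layer
  outputs) is forced by the channel formula `γ = η + 3γ′` and is asserted
  at runtime for every constructed block.
* **Spatial/temporal kernel ladders** mirror the printed spectral ladder
  (7/5/3) along their own axes; only the spectral sizes are printed.
* **Initial branch convolutions** use the branch's own kernel shape at
  stride 1; spectral compression is done upstream by bin averaging rather
  than by striding the first convolution.
* **Convolutions are bias-free** wherever a batch norm follows (the BN
  shift makes a bias redundant); batch-norm ε = 1e-4, scale/shift
  initialized to 1/0, running statistics with momentum 0.1 for inference.
* **Attention descriptors**: the per-position channel vector is averaged
  over the spectral axis before the dense score (the positional maps are
  defined on the H×W grid); the per-channel descriptor is the global
  average. The dense biases sit inside softmaxes and are therefore
  provably gradient-free (softmax is shift-invariant); they are kept for
  fidelity to the printed dense form but excluded from the gradient-flow
  test.
* **Weight maximization** is read as
  `max(Att_spe ⊗ Att_temᵀ, Att_spa)` — preserving both the printed
  product and a two-argument max — and the printed self-referential
  definition of the maximization path's feature map is resolved as
  `concat(Att_max ⊙ β, β)`. The remark that maximization "doubles the
  horizontal/vertical coefficients" is exposed as an off-by-default
  scale option since no formula accompanies it.
* **The addition-path convolution** has no stated kernel; default
  `(3,3,3)`, same padding. Fusion pools with `(2,2,1)`, skipping axes
  smaller than the pool with a warning.
* **EnDe-CNN encoder** stages use spectral `(1,1,7)/(1,1,5)/(1,1,3)`
  kernels with `(1,1,2)` pooling between stages; all three stages are
  tapped, pooled to the deepest spectral size, and concatenated into the
  latent. The decoder mirrors with transposed convolutions sized to
  invert the pooling exactly. The garbled printed size formula is
  implemented as the standard convolution arithmetic
  `⌊(M + 2p − k)/s⌋ + 1`, asserted against runtime shapes.
* **Self-supervision** is joint training: `CE + λ·L_rec` with one
  reconstruction patch per sample, plus an optional
  reconstruction-only warm-up (`pretrain_epochs`). The reconstruction
  term sums squared errors over ~2·10⁴ patch elements, so at desk scale
  its weight is λ = 1e-3 (library default 0.1 at reference widths) to
  keep it from drowning the cross-entropy gradient.
* **Modality fusion** concatenates the per-modality attention outputs
  channel-wise before the encoder; each modality has its own SST-PNet and
  attention parameters.

## Training, evaluation, validation

Adam (β = 0.9/0.999), step-decay schedule `lr₀·0.1^⌊epoch/Δ⌋` with
`lr₀ = 1e-3`; reference configurations decay every 50 of 150 epochs (ECG)
and every 80 of 160 (PCG). The statement that the PCG rate "increases by
0.1" is implemented as the same ×0.1 decay, consistent with the ECG rule.
Desk-scale default: 10–20 epochs, batch 16.

Metrics are computed in two labeled forms. The verbatim formula set of
this model family defines accuracy as `(TP+FP)/n` — an evident misprint
that equals the positive-prediction rate and scores 0.5 on balanced random
data — and labels `TP/(TP+FP)` "specificity" although it is algebraically
precision. Both verbatim values are reported (`verbatim_accuracy`,
`verbatim_specificity`) next to the standard definitions, and the headline
metric everywhere is `standard_accuracy`. The verbatim F1 of
("specificity", sensitivity) is algebraically identical to the standard
F1 of (precision, recall); the suite asserts this to 1e-12. Zero
denominators yield `None` plus an `undefined` flag, never a silent 0.
Wilson 95% intervals accompany each defined proportion.

Cross-validation is stratified **subject-level** k-fold (all segments of
a recording stay together; per-class subject counts differ by ≤ 1 across
folds), repeated with reseeded shuffles; both five-fold and ten-fold
usage exist in this model family's reporting, and `folds` is a
configuration knob defaulting to 5.

## Numerical engine and problem sizes

The networks run on a small reverse-mode autodiff engine over numpy
(`cardiopyramid.nn`): broadcast arithmetic, matmul, reductions, softmax,
Mish/ReLU/tanh/softplus, fused batch norm, 3-D convolution via a cached
im2col laid out so every per-offset copy moves contiguous spectral runs
and the contraction is a single BLAS GEMM, zero-insertion transposed
convolution (the exact adjoint), and non-overlapping max pooling. Every
operator's gradient is validated against central finite differences.
Backward tears the tape down as it is consumed, keeping peak memory near
a single graph traversal; inference runs under a no-grad mode.

Desk-scale study conditions used by the examples and the acceptance run:
50+50 subjects (≈ 590 segments), 8×8×16 feature volumes
(`n_fft 256, hop 256, 16 bins`), branch widths `η = 3, γ′ = 1`,
`K_add = 4`, encoder channels (8, 8, 8), 10 epochs, batch 16 — about two
minutes of training per seed on one CPU, reaching ≥ 0.95 held-out
accuracy on the separable cohort. The module defaults
(12×12×32 volumes, `η = 16, γ′ = 8`) define the reference architecture;
they are exercised structurally in the tests and train identically, only
slower.

## Known limitations

* The synthetic positive class is defined by a single dominant effect
  (murmur-band power); real inter-subject pathology variation is far
  broader, so reported accuracies characterize the pipeline, not clinical
  performance.
* The Wiener filter is linear and time-invariant per record (or per
  frame); transient noise is left to the false-peak stage.
* False-peak feature cutoffs are calibrated on the synthetic artifact
  model; real electrode artifacts may need recalibrated cutoffs or votes.
* WFDB support covers header/format-16 single-record pairs only.
* The autodiff engine is single-threaded numpy; it is sized for
  desk-scale experiments, not GPU-scale training.
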