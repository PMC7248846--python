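# Methods and numerical conventions

This document records the mathematical conventions, the default parameters
with their rationale, and the scope and limitations of each stage.

## 1. Continuous wavelet transform (`sleepsig.tfa`)

* **Wavelet.** Analytic Morlet with centre frequency μ = 6 rad/s:
  ψ̂(ξ) = π^(−1/4) √2 · exp(−(ξ−μ)²/2) for ξ > 0, zero otherwise.
  The analytic (one-sided) form makes the candidate instantaneous
  frequency single-signed.
* **Computation.** FFT-based: W(a, b) = ifft( fft(s) · √a · ψ̂(a ξ_k) ),
  over a dyadic scale grid a_j = 2^(j/n_voices) Δt with `n_voices = 32`
  voices per octave. The grid covers the requested frequency band with a
  1.4× margin on both sides so band-edge ridges are not truncated; the
  frequency associated with scale a is f = μ / (2π a).
* **Minimum length.** Inputs shorter than 2·n_voices samples are rejected
  (the scale grid would not be meaningful).

## 2. Synchrosqueezing

* **Candidate IF.** ω(a, b) = Im( (∂W/∂b) / W ) / 2π, with the time
  derivative by `np.gradient` per scale. Coefficients with
  |W| ≤ 10⁻⁸ · max|W| are masked out (phase is numerically meaningless
  there).
* **Reassignment.** On a uniform frequency-bin grid (default 128 bins across
  the analysis band), each coefficient is moved to the bin whose half-open
  interval [ω_l − Δω/2, ω_l + Δω/2) contains its candidate IF and
  accumulated with weight a^(−3/2) Δa; the sum is divided by Δω. Δa uses
  forward differences with Δa₀ = a₀(1 − a₀/a₁). Accumulation is done with
  `np.bincount` on real and imaginary parts; the unit-test oracle re-derives
  the same quantity with explicit per-element loops and matches bit for bit.
* **Inverse (ISSWT).** r(t) = (2 / R_ψ) · Re( Σ_l T(ω_l, t) Δω ) over bins
  within ±2 bins of a ridge, with R_ψ = ∫₀^∞ ψ̂(ξ)/ξ dξ evaluated once by
  adaptive quadrature. Note the admissibility constant here is the plain
  integral **without** a 1/2π factor: with the discrete FFT convention used
  for the forward transform the 2π cancels, which was verified by the
  round-trip criterion (relative RMSE ≈ 1 % for in-band tones; the
  acceptance bound is 5 %).

## 3. Ridge extraction

A Viterbi dynamic program over bins maximises accumulated normalised energy
minus a curvature penalty λ(Δbin)² with λ = 0.1. Energy is normalised by
the global spectrum maximum so λ is scale-free. Transitions are restricted
to ±2·ceil(√(2/λ)) bins per step: since the per-step energy gain is at most
1, a larger jump can never pay for its penalty, so the restriction is
lossless and makes the (numba-compiled) DP linear in grid size. Columns
with no usable energy are marked degenerate; a ridge with > 50 % degenerate
columns is flagged degenerate overall.

## 4. Iterative R-peak detection (`sleepsig.rpeak`)

Per 120 s window:

1. Mean-subtract; flip polarity if |min| > |max| (R peaks assumed the
   dominant deflection).
2. SSWT ridge in 0.5–2 Hz → reference heart-rate series f₁(t), one value
   per sample.
3. Threshold sweep: 9 levels, median + [0.2 … 0.8]·(max − median) of the
   window. For each, peaks are local maxima above the threshold with a
   0.3 s refractory period; the peak-derived rate series is fⱼ(t) = 1/RRⱼ
   placed at the later peak of each interval.
4. Both series are linearly resampled to 4 Hz (constant extrapolation
   beyond the first/last sample) and compared by mean absolute difference;
   the threshold with the smallest disagreement wins (ties go to the larger
   threshold).
5. **Noisy flags.** A window is rejected when (a) the ridge is degenerate,
   (b) every threshold yields < 2 peaks, (c) the selected peak count is
   below 0.6 · duration · median ridge frequency, or (d) the minimum
   disagreement exceeds 0.2 Hz. Rule (d) extends the quantified rules
   because broadband noise can incidentally satisfy (a)–(c); measured
   separation is ≤ 0.03 Hz for clean ECG (even at 5 dB SNR) versus
   ≈ 0.55 Hz for white noise, so 0.2 Hz sits far from both populations.

## 5. Features (`sleepsig.features`)

* **EMG (per 20 s sub-window).** Population moments (no bias correction;
  kurtosis without the −3 offset, so a Gaussian scores 3) and dispersion
  entropy. Dispersion entropy: map samples through the Gaussian CDF of the
  sub-window itself, classify into c classes by z = round-half-up(c·y + 0.5)
  clipped to [1, c], embed with dimension m and delay d (defaults m = 2,
  c = 5, d = 1), and take the Shannon entropy (natural log) of the pattern
  frequencies. Bounds: [0, m ln c]; invariant under increasing affine
  transforms. DE = 0 is attained exactly only by inputs with a single
  embedded word, because classes are defined by the signal's own CDF.
* **ECG (per 120 s window).** R-R interval max/min/mean; the R-peak
  amplitude series (respiration surrogate) max/min/mean; and the breathing
  instantaneous frequency — the amplitude series is resampled to 4 Hz,
  transformed by SSWT in 0.05–1 Hz, and the ridge's max/min/mean/sd taken
  over the interior 90 % of samples (the outer 5 % per side lie in the
  wavelet cone of influence).

## 6. Windowing and rejection (`sleepsig.dataset`)

120 s windows, 60 s stride; EMG trial = first 24 s of each window, three
20 s sub-windows at 2 s stride → a 5 × 3 feature tensor. A window is
dropped when R-peak detection is noisy, any EMG sub-window saturates
(> 1 % of samples at the recorded extremes) or is constant, or any feature
is non-finite. On default synthetic cohorts ≈ 100 % of windows are kept;
the rejection paths are exercised by constructed inputs in the tests.

## 7. Synthetic cohort (`sleepsig.synthetic`)

Integrate-and-fire beats (rate ~ N(hr_mean, hr_sd) per interval, clipped
to [0.4, 3] Hz); a fixed QRS-like kernel whose deposited amplitude is
1 + depth·sin(breathing phase); the breathing phase integrates a frequency
track with ± 2 % slow drift. Apnea episodes arrive as a Poisson process,
suppress the modulation depth to 2 % of nominal, double the beat jitter,
and shift the post-episode breathing rate by ± 30 % (smoothed over 5 s) —
modelling the irregular resumption of breathing that makes the breathing-IF
sd discriminative. EMG is band-limited (20–95 Hz) Gaussian noise; RLS
profiles add raised-cosine burst envelopes (≈ every 10 s ± 20 %, 2 s long,
4× baseline sd) gating extra band-limited activity. Per-subject profiles
are perturbed around the group templates so cross-subject evaluation is
meaningful. All truth (R-peak indices and amplitudes, breathing track,
apnea and burst intervals) is exact by construction.

Scope: the generator reproduces the statistical structure the pipeline
measures, not clinical morphology — no P/T waves, no electrode artifacts,
no sleep staging, and group differences are idealised.

## 8. Model and evaluation (`sleepsig.model`)

Implemented in numpy with hand-derived gradients (verified against central
finite differences in the tests). Defaults: two stacked 5-unit tanh
recurrent layers (EMG branch, 3 time steps), 10 → 20 ReLU (ECG branch),
25-wide merge with inverted dropout 0.4, ReLU stack 25 → 15 → 15 → 10 → 4,
softmax + NLL, full-batch Adam (lr 0.01), at most 2000 epochs. Early
termination: every 100 epochs the dropout-free loss is checkpointed and
training stops when it has not improved by > 10⁻³ (with a pre-training
baseline, so disabled learning stops at exactly epoch 100). Features are
z-scored with training-set statistics stored in the trained model.

Cross-subject CV partitions subjects (stratified by group) into k folds —
with 10 subjects per group and k = 10, one held-out subject per group per
fold — and asserts train/test subject disjointness on every fold. Metrics:
accuracy and support-weighted F1/precision/recall per fold plus a pooled
confusion matrix. The `tune` function is a compact tree-structured Parzen
estimator: trials are split at the 0.25 quantile of validation accuracy,
per-dimension Gaussian-kernel densities l(x)/g(x) are fitted, and
candidates drawn from l maximise the ratio; integer and log-scaled
dimensions are handled in their natural space.

Only tanh recurrent cells are provided; gated cells (GRU) were left out to
keep the hand-derived gradient surface small. The configuration exposes
layer count and width should variants be added.

## 9. Determinism

Every stochastic step takes an explicit seed (generator, model
initialisation, dropout, fold shuffling, tuner). Cohort generation derives
per-subject seeds from one master generator, bounded below 2³¹. Repeated
runs are byte-identical (asserted in the CLI tests).
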