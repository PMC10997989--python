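# Methods

This note records the models implemented by `emgonset`, the conventions
that had to be fixed where the published descriptions leave freedom, and
what the simulated benchmark does and does not establish.

## Trial model

A trial is 13 s at 1 kHz: samples 0–7999 are the rest phase, 8000–12999
the move phase.  Three windows partition the analysis (all detectors and
the scorer share them):

* 0–3 s — baseline: the detector estimates its threshold
  h = μ_g + α·σ_g from the test function here (sample SD, n−1
  denominator, warm-up samples excluded).
* 3–8 s — false-positive window: r_FP is the fraction of detector-on
  samples, normalized by this window's 5000 samples.  The printed
  definition normalizes by the whole 8 s rest phase, but the procedural
  description and the figure restrict estimation to the post-baseline
  5 s; we follow the procedure, as the more specific statement.
* 8–13 s — move phase: r_FN is the fraction of detector-off samples and
  Δt the delay to the first detection; no detection means Δt = none and
  a saturated latency penalty f = 1.

Cost: C = max(r_FP, r_FN, f(Δt)) with f(Δt) = Δt/250 ms on [0, 250) ms,
1 at or above 250 ms, 0 below 0.  C ≤ 0.2 is then *exactly* equivalent to
r_FP ≤ 0.2 ∧ r_FN ≤ 0.2 ∧ Δt ≤ 50 ms (property-tested exhaustively).
Acceptance comparisons use ≤ (inclusive).

## Signal models

**Phenomenological (Gaussian / Laplacian).**  Unit-variance white noise
(Laplace scale b = 1/√2 so the variance is 1) multiplied by
σ(n) = 1 in rest and √(1 + σ₁²) in move, σ₁² = 10^(SNR_dB/10); then an
8th-order (9-tap) Hamming windowed-sinc FIR "bandpass" at 10–450 Hz
applied forward–backward (zero phase).  The unit-variance calibration is
pre-filter.  Note that 9 taps cannot realize a 10 Hz edge at 1 kHz: the
filter has unit mid-band gain but only mild attenuation at DC (~0.91) and
towards Nyquist.  We implement the stated design rather than an
idealized band, and since the input is zero-mean the residual DC gain has
no effect on the statistics.  Zero-phase filtering happens only at
generation time; every detector-side filter is causal.

**Biophysical.**  Move-phase activity is a superposition of motor-unit
action-potential trains; rest is exact silence (0 N force).

* Pool: Q = 100 units, recruitment thresholds spread exponentially over
  [0, 8 N] (size principle), all units recruited at the 10 N move-phase
  force.  Firing rate per unit: 8 Hz at recruitment plus a linear gain in
  excess force, with the gain solved in closed form so the pool's mean
  rate at 10 N is exactly 16.4 Hz; inter-spike intervals are Gaussian
  with CV 0.15.
* Unit potential: single-fibre wave p(t) = t·exp(−(t/τ)²), τ = 2 ms,
  convolved with a 3 ms Gaussian dispersion kernel (endplate scatter and
  per-fibre conduction differences within the unit), then passed through
  the bipolar electrode model — subtraction of a copy delayed by
  10 mm / 4 m s⁻¹ = 2.5 ms.  Without the dispersion stage the bipolar
  comb concentrates energy near 200 Hz; with it the move-phase spectrum
  is dominated by components below 100 Hz, the qualitative signature
  that distinguishes this model from the flat phenomenological ones.
* Amplitudes: units are physical millivolts; a unit's amplitude is its
  (lognormally scattered) fibre count × 1 μV per fibre, giving surface
  MUAP peaks of tens of μV.  Amplitude units matter only for the fuzzy
  entropy detector (below); every other detector is scale-invariant.
* Noise: white Gaussian with σ₀² = σ₁²/10^(SNR_dB/10), where σ₁² is the
  measured move-phase power of the noise-free signal; the sum is then
  bandpass filtered like the phenomenological signals.

Reproducibility: trial i of a set uses a counter-based Philox stream
keyed on (seed, i); identical seeds give bit-identical sets.

## Detector conventions

All thirteen detectors share: causal conditioning, a test function over a
trailing window, the baseline threshold h = μ_g + α·σ_g, and a strict
decision g(n) > h.  Conventions fixed here (the published per-detector
supplement is not available):

* Warm-up: g(n) = 0 for n below the window/filter warm-up and those
  samples are excluded from baseline statistics.
* Double threshold (Lidierth, Modified Lidierth, Bonato, TKEO with
  m = 1): y(n) = 1 iff ≥ m of the trailing T1 samples are supra-threshold;
  m and T1 are given in ms and converted at the sampling rate.  Bonato's
  statistic lives on a half-rate time base (sums of successive
  whitened-sample pairs over the baseline variance); m and T1 are halved
  there and decisions are held over each pair.
* Adaptive whitening (Bonato, AGLR-G, AGLR-L): AR(6) Yule–Walker fit on
  the 3 s baseline, prediction-error filter applied causally to the whole
  trial; order 6 suffices to flatten the 10–450 Hz shaping colour.
* AGLR statistics use a fixed trailing window (approximated GLR):
  Gaussian, g = (W/2)(σ̂²/σ₀² − ln σ̂²/σ₀² − 1); Laplacian,
  g = W(b̂/b₀ − ln b̂/b₀ − 1).  Both are ≥ 0 with equality exactly at the
  baseline match, and both are thresholded through the same α mechanism
  as every other detector.
* TKEO uses the causal one-sample-delayed energy operator
  ψ(n) = x̃(n−1)² − x̃(n−2)·x̃(n) (the printed form of the operator is
  garbled in the source material; this is the standard causal form).
* Sample entropy: embedding m = 2, Chebyshev distance, tolerance
  r = ρ·SD of the current window (sample SD), self-matches excluded,
  undefined values capped at ln(W(W−1)).
* Fuzzy entropy: embedding m = 2, mean-subtracted templates, membership
  exp(−d²/r).  The tolerance is r = 0.2·SD of the 3 s baseline,
  calibrated once per trial.  This is a deliberate choice: with r tied to
  the sliding window's own SD the statistic is scale-invariant to first
  order and cannot see a pure variance step at all, which contradicts
  both the benchmark's reported success of this detector on the
  phenomenological models and the published account of it tracking
  overall amplitude changes.  A baseline-anchored tolerance is causal and
  amplitude-sensitive.  The membership exponent d²/r is dimensional, so
  this detector — uniquely — depends on the absolute units of the signal;
  that dependence is a property of the statistic, not of this
  implementation.
* CWT: magnitude of the causal correlation with a Mexican-hat (second
  derivative of Gaussian) wavelet as the MUAP-shape proxy, one scale,
  taps de-meaned so a constant input is rejected exactly.  The published
  operating points list no scale; the package default is 16 ms (about
  one MUAP width).
* SSA: lag ℓ = W/2 trajectory matrix from the baseline, left singular
  subspace capturing 90 % of baseline energy; g is the squared residual
  of the current lagged vector after projection, normalized by the
  vector's own energy (so g ∈ [0, 1] and the statistic is
  scale-invariant); threshold weight fixed at α = 1.
* RMS: causal 4th-order Butterworth bandpass conditioning, RMS over the
  trailing W ms recomputed every p ms and held between updates; the
  temporal threshold m is enforced as ⌈m/p⌉ consecutive supra-threshold
  updates.

## Optimization and benchmark

Grid search scores each parameter combination by
P = √(median(C)² + IQR(C)²) over the training trials (quartiles by linear
interpolation; ties broken by enumeration order over the sorted
parameter names; a detector failure on a trial counts as cost 1 and is
logged).  The benchmark splits each 100-trial set into training and
validation halves *by generation order* — the trials are i.i.d., so an
order split is equivalent to a random one and exactly reproducible.  The
published operating points for all 13 detectors and 6 conditions are
bundled (`PUBLISHED_PARAMS`) so the benchmark can skip the search; the
original search grids are not public, and the package's default grids are
documented supersets of the published optima, not reconstructions.

## Problem sizes used by the test and acceptance suites

The acceptance suite evaluates the full 13 × 6 matrix at the published
protocol size (100 trials per condition, 50-trial validation halves) from
one shared fixture; unit and property tests use short synthetic records
(hundreds of samples) against brute-force oracles.  The acceptance script
evaluates the targeted cells at the same 100/50 protocol.

## Known limitations

* The simulators assume a fixed-variance step and constant activation;
  real patient sEMG arrives in bursts with time-varying amplitude.
  Passing the benchmark shows behaviour under idealized, controlled
  conditions only — a detector failing here is expected to fail on real
  data, but the converse is not established.
* The biophysical pool parameters (fibre counts, geometry, exact SFAP)
  are package defaults honouring the documented constraints (10 mm
  inter-electrode distance, 16.4 Hz at 10 N, silent rest); the original
  simulator's parameter table is not available, so biophysical-model
  cells reproduce published values more loosely than the fully specified
  phenomenological cells.
* The fuzzy entropy detector's absolute-unit dependence (above) means
  its biophysical-model performance is sensitive to the amplitude-unit
  convention; with the defaults here it does not reach the published
  biophysical success, and its cost there does not follow the usual
  SNR-degradation direction.
* The AGLR-L / Laplacian / −3 dB cell sits exactly at the acceptance
  knife edge (median latency ≈ 50 ms, median error rates ≈ 0.17): its
  acceptance proportion has high seed-to-seed variance by nature.
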