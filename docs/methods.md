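# Methods

## Signal model and what the simulator emulates

Cutaneous EGG is modelled as a mixture of sinusoids in the gastric range
plus linear drift and white Gaussian noise, optionally quantized to an
ADC grid:

```
x(t) = Σ_k A_k sin(2π f_k t + φ_k) + s·t + ε(t),   ε ~ N(0, σ²)
```

with `f_k` in cpm (valid range 0–30 cpm), sampled at 1000 Hz and 16 bits
by default, matching common acquisition hardware. The model was chosen
over autoregressive noise shaping because every component has a
closed-form band-power contribution: a tone of amplitude `A` contributes
power `∝ A²`, so scenario generation can solve amplitudes from target
percentages (`A_b ∝ √pct_b`, corrected by the offline filter's gain at
the tone frequency) and tests can compare analysed output against known
inputs.

What the simulator does **not** emulate: respiratory and cardiac
artifacts, electrode pops, colored (1/f) noise, amplitude/frequency
modulation of the slow wave, multi-channel spatial structure, and any
mechanistic ICC-network dynamics. Passing tests therefore demonstrate
that the *processing* is correct and self-consistent, not that the
pipeline is robust to every artifact class found in real abdominal
recordings — real data still warrant the artifact flagger plus visual
inspection.

Scenario presets (normo/brady/tachy targets): `fasted` 40/35/25,
`post_water` 70/20/10, `fullness` 50/30/20. These are illustrative
percentages encoding the expected within-session trajectory (normogastria
lowest fasted, highest after 250 ml of water during training, partially
reduced after drinking to fullness); they are not estimates from any
participant dataset. Tones sit at 1.5, 3 and 6 cpm — band centres chosen
so Hann main lobes stay inside their bands. Scenario noise defaults to
σ = 0.1 (tone amplitudes are O(1); broadband noise contributes little
in-band power after decimation and bandpass) with a small drift
(10⁻⁴ units/s) so detrending does real work.

## Offline pipeline

`analyze_recording` = decimate to 10 Hz → linear detrend → zero-phase
Butterworth bandpass → Hann window → zero-pad to 2^k → FFT → percent band
power. Choices:

* **Decimation**: 8th-order Butterworth low-pass at 0.8 × target Nyquist
  (4 Hz for the 10 Hz rate), zero-phase, then take every q-th sample.
  Zero-phase doubles the attenuation: a 6 Hz tone that would alias to
  4 Hz survives at < 0.2% amplitude.
* **Detrend**: linear least squares. Removes electrode drift without
  attenuating 1 cpm content (a polynomial of higher order would begin to
  track bradygastric cycles over 15 min).
* **Bandpass**: 4th-order Butterworth, 0.016–0.16 Hz, run forward and
  backward (`sosfiltfilt`). Zero-phase matters offline only for
  waveform-domain uses; for band power it simply squares the magnitude
  response. Passband gain at 0.05 Hz is within 5% of unity; 0.5 Hz is
  attenuated > 35 dB per pass.
* **PSD scaling**: density normalization `|FFT(w·x)|² / (fs·Σw²)`,
  one-sided. Percentages are ratios, so any fixed scaling convention
  yields identical summaries (tested).
* **Band integration**: trapezoid rule over bins whose centre falls in
  `[lo, hi)` cpm (the tachygastric band closed at 10 cpm); the total is
  the sum of the three band integrals, so percentages sum to 100 exactly.
  Bands outside 1–10 cpm do not enter the total. If a band spans fewer
  than two bins the rectangle rule (power × bin width) is used.
* **Stage order**: detrend before bandpass by default; the alternative
  order is exposed (`detrend_first=False`) and differs only through the
  filter's finite DC rejection (≪ 1 percentage point on test signals).
* **Minimum duration**: 120 s (two cycles of the slowest band edge);
  shorter inputs raise an error rather than returning unstable
  percentages.

Degenerate inputs: a signal with zero in-range power (all-zero or pure
DC) raises `UndefinedResultError` — callers must decide what an undefined
percentage means for them. Dominant-frequency ties break toward the
lower frequency, deterministically.

## Streaming engine

The causal chain mirrors the offline pipeline: causal decimation to
10 Hz, causal bandpass, then per-hop (default 1 s) frames.

* **Pacemaker**: raised cosine `(1 − cos(2π·cpm·t/60))/2` at 3 cpm —
  empty at t = 0, full at 10 s, one cycle per 20 s.
* **Direct feedback**: the latest filtered sample mapped affinely to
  [0, 1] by the min/max over a trailing 60 s window. Self-calibrating
  across electrode gains; a constant window parks the sphere at 0.5.
  How the original hardware normalized this sphere is unknowable, so the
  trailing min–max is a design choice, configurable via
  `StreamConfig.direct_norm_s`.
* **Spectral branch**: sliding 240 s window, detrended, Hann+FFT, band
  percentages; `normo_fraction = pct_normo/100` drives the environment.
  The branch filters the stream with the causal bandpass **twice**: the
  resulting magnitude response equals the offline zero-phase filter's
  |H|², so streamed and offline band ratios agree (phase delay is
  irrelevant to a power spectrum) while every sample used still precedes
  the frame timestamp.
* **Window length**: a Hann window of length T confines a tone's main
  lobe to ±2/T Hz. The narrowest band (bradygastria) is 1 cpm wide, so
  resolving it requires 2/T ≤ 0.5 cpm ⇒ T ≥ 240 s. Shorter windows
  (60–120 s) are configurable but smear bradygastric power into
  neighbouring bands and bias the normogastric fraction upward by
  several points; with 240 s the streamed time-average matches the
  offline percentage to well under 1 point on stationary signals.
* **Warm-up**: until one full window has accumulated, frames carry
  `warmed_up=False`, an undefined `normo_fraction` and a neutral
  environment (all parameters 0.5) — partial spectra would otherwise
  show misleading weather.
* **Environment mapping**: linear; `cloud_density = 1 − nf`,
  `water_clarity = nf`, `wind_gain = 1 − nf`,
  `water_sound_gain = 0.25 + 0.75·nf` (a floor keeps the lake audible).
  Higher normogastria ⇒ sunnier, clearer, calmer. No temporal smoothing
  is applied to `normo_fraction` by default; the 240 s window already
  low-passes the estimate.

Causality is a tested invariant: truncating the input at time T never
changes frames timestamped ≤ T − hop.

## Session summaries and group statistics

A session is a fasted 15 min baseline, a 10 min training after 250 ml of
water, and a 15 min post recording after a water-load to fullness.
`summarize_session` analyses each timepoint with the offline pipeline
(the streaming aggregate is available as an alternative view of the
training period) and reports per-band differences (during − pre,
post − during). Missing or off-plan recordings (> 5% duration deviation)
produce flags, not errors.

`winsorize_by_group` clamps values beyond ±3 sample SDs (ddof = 1,
matching SPSS/R conventions) of the group mean, computed once from the
input and not iterated. Note the output is not a fixed point of the
operation — clamping shifts the mean and SD — but it never contains a
value outside the original ±3 SD envelope (asserted exactly). Note also
that with very small groups (n ≤ 9) no single value can exceed 3 SDs,
since the maximum achievable z-score is (n−1)/√n; the rule only bites at
realistic group sizes. Winsorization is applied per band × timepoint ×
group cell. Group-level inference (mixed-effects models, post-hoc
comparisons, effect sizes) is deliberately out of scope; the tidy CSV
export (`session_to_frame`) is the hand-off point to external statistics
packages.

The artifact flagger is plumbing, not science: it reports windows with
> 1% of samples pinned at the range extremes (saturation) and
sample-to-sample jumps beyond 6 robust SDs (1.4826 × MAD). Thresholds
are configurable defaults; the flagger never modifies data.

## Numerical and testing notes

* All filters are designed and applied in second-order sections; the
  0.016–0.16 Hz band at 10 Hz is narrow enough that transfer-function
  (b, a) forms would be ill-conditioned.
* The spectrum estimator is verified against an O(n²) matrix-DFT oracle
  (same window, padding and scaling, built independently in the test
  suite) to 1e-9 relative error on inputs up to 4096 samples.
* Simulations in the test suite use 300–900 s recordings and ≤ 20 seeds
  per property — long enough for 0.07–0.3 cpm spectral resolution and
  stable percentages, small enough that the whole suite runs in well
  under a minute.
* Determinism: a fixed simulator seed gives bit-identical recordings;
  `analyze_recording` and `stream_process` are deterministic functions of
  their inputs.

## Known limitations

* Percent band power on 10–15 min windows cannot detect short-lived
  rhythm irregularities; wave-by-wave cycle detection is out of scope.
* Single-channel only; no electrode-placement or volume-conduction
  modelling, and raw units are treated as arbitrary (the ADC transfer
  function is not modelled — a configurable mV scale travels as
  metadata).
* The direct-feedback sphere's 60 s min–max normalization makes its
  excursions relative, not absolute: it always explores most of [0, 1]
  even for weak signals.
* The streaming spectral branch has an intrinsic 240 s warm-up and, like
  any sliding-window estimate, lags physiological change by up to one
  window length.
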