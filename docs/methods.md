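# Methods

## The analysis model

`fesfatigue` treats muscle fatigue as an amplitude phenomenon: the windowed
RMS of the sEMG grows as motor-unit recruitment and synchronization rise
with fatigue.  Two regimes are modelled.

**Voluntary sustained contraction.**  Over the final 60 s before task
failure, the normalized RMS trend is summarized by a two-parameter power
law iRMS = a·t^b (b > 0 for a fatiguing muscle).  The model is deliberately
minimal: it captures monotone accelerating/decelerating growth with one
shape parameter and admits a closed-form fit.

**FES-evoked response.**  The evoked RMS envelope over a whole stimulation
session is "M"-shaped.  Its polynomial fit is split at critical points into
four physiologically interpreted stages — activation (rise to the first
local maximum), recovery (fall to the next local minimum), fatigue (rise to
the global maximum) and excessive fatigue (decline).  The global-maximum
time is the maximum stimulation time t_max: the model's safe-duration
estimate for that current.  Across currents, t_max is modelled as
t = k/(I − i0), k > 0, i0 ≥ 0.  The offset i0 lets a rheobase-like minimum
effective current be represented; i0 = 0 recovers strict inverse
proportionality.

Assumptions worth keeping in mind: a single channel over one muscle;
uniform sampling; fatigue expressed in amplitude only (no spectral
compression indices); the evoked response treated as a band-limited
stochastic process whose local variance carries the envelope.

## Separation by single-scale CWT

The evoked estimate is the CWT coefficient series
WT(a, τ) = a^(−1/2) Σ_t f(t) ψ((t − τ)/a) Δt, with Δt = 1/fs, the dilation
argument expressed in samples, evaluated at every τ on the input grid by
zero-padded FFT convolution.  This is a linear, zero-phase band-pass
projection: for an amplitude-modulated noise process its windowed RMS is
proportional to the local envelope, while the two-sample, charge-balanced
artifact transients contribute only sparse spectral lines.  No inverse
transform is applied — the coefficient series itself is the evoked signal
estimate, and downstream features (RMS, fits, stages) are invariant to its
overall scale.

The scale is fixed at a = 128.  The analyzing wavelet is a design choice:
the default is a zero-mean Gabor atom
ψ(x) = (cos(2π·f_c·x) − C)·exp(−x²/2σ²) with f_c = 20 cycles and σ = 0.03,
chosen so that at a = 128 and fs = 1000 Hz the equivalent passband centres
at f_c·fs/a ≈ 156 Hz with spectral std fs/(2π·a·σ) ≈ 41 Hz — inside the
20–450 Hz band where the evoked energy lives, and wide enough that 1-s RMS
windows of the filtered noise have only a few percent estimator variance.
The constant C = exp(−(2π f_c σ)²/2) enforces exact admissibility.
Mexican-hat and classic Morlet wavelets are available by name; at scale 128
and 1 kHz their passbands fall below 10 Hz, far outside the sEMG band, so
analyses selecting them should choose scales accordingly.  Every test that
depends on ψ pins it explicitly.

Boundary handling is zero extension; `edge_margin_samples` reports how many
samples at each end are edge-affected (⌈a · support⌉, with support 8σ for
the Gabor atom).

## Tunable parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| band-pass corners | Hz | 20–450 | conventional sEMG band |
| filter order | – | 4 | conventional; doubled by forward–backward |
| terminal window | s | 60 | fatigue develops near task failure |
| RMS window / hop | samples | 1000 / 1000 | 1 s at 1 kHz; non-overlapping |
| wavelet scale a | – | 128 | fixed operating point of the separation |
| Gabor f_c, σ | cycles, – | 20, 0.03 | passband ≈156 ± 41 Hz at a=128, 1 kHz |
| polynomial degree | – | 6 | 4-stage curve has 3 interior critical points (needs ≥4); 6 leaves slack for asymmetry without chasing window noise |
| i0 bound | mA | [0, min I) | offset must stay below the smallest tested current |
| reference protocol | mA, Hz, µs | 12, 24, 200 | centre of the protocol grid for one-factor sweeps |

## Numerical choices

- **Power fit**: solved in log–log space (closed-form simple regression),
  not iteratively — deterministic and oracle-checkable.  Non-positive
  values are excluded from the regression with a warning (≥3 positive
  points required): min–max normalization always maps one point to exactly
  zero, and flooring it at machine epsilon would hand a single log(ε)≈−36
  point overwhelming leverage.  Constant curves fit exactly (b = 0) with
  R² = 1 and an undefined F-test (reported as NaN).
- **Polynomial fit**: `numpy.polynomial.Polynomial.fit` with its internal
  domain mapping for conditioning; coefficients are reported converted to
  the ordinary power basis.  R² is clipped to [0, 1]; the P value is the
  overall regression F-test.
- **Stage boundaries**: roots of the fitted polynomial's derivative,
  classified by the derivative's sign on either side (saddle points are
  ignored).  Ties between equal-height maxima break toward the earlier
  time — the conservative, shorter safe-stimulation choice.  A curve with
  fewer than three usable critical points raises a shape error carrying
  the points found.
- **Inverse fit**: trust-region nonlinear least squares with
  xtol = ftol = gtol = 1e−14, started from the closed-form i0 = 0 solution
  k = Σ(t/I)/Σ(1/I²), bounded 0 ≤ i0 < min(I); on failure it falls back to
  that closed form.  A non-negative rank correlation between I and t
  triggers a warning rather than an error.
- **Degenerate inputs**: constant RMS curves cannot be normalized (the
  Eq.-denominator is zero) and raise a dedicated error; records shorter
  than one window, tables without rows, and confounded effect designs all
  raise typed exceptions rather than producing silent nonsense.

## The synthetic generator

What it emulates: 1 kHz single-channel recordings; band-limited (20–450 Hz)
Gaussian carriers whose windowed RMS follows the planted envelopes
(power-law for voluntary trials, the four-stage M shape for FES); a
periodic biphasic artifact train at the protocol frequency, rendered by
integrating each 200 µs phase into adjacent sample bins (±A·(w/2)/fs — the
aliased spike a 1 kHz recording actually shows, proportional to pulse
width); evoked bursts gated ~5 ms after each pulse; broadband background
noise; and a cohort-level dose–duration law t = k/(I − i0) with additive
frequency (≤0 s/Hz) and pulse-width (≥0 s/µs) slopes and per-subject
multiplicative log-normal jitter (peak times are positive, so jitter is
multiplicative).  All randomness derives from one seeded generator per
trial, spawned from a single cohort seed.

Defaults define the emulated study conditions: 10 subjects, currents
2–15 mA in 1 mA steps, 24 Hz / 200 µs protocol, k = 120 mA·s, i0 = 0,
5% subject jitter, frequency slope −0.15 s/Hz, pulse-width slope
0.02 s/µs, stage-duration template 5/10/25/20 s scaled to each planted
peak time.  A `carrier="tone"` variant replaces the stochastic carrier
with a deterministic unit-RMS 150 Hz sinusoid — the fully noiseless
condition used to check strict monotonicity of extracted t_max, since a
stochastic carrier is itself a noise source.

What it does **not** emulate — and therefore what passing tests do not
show about real data: motor-unit action-potential trains and their
physiological spectra; electrode-contact drift and motion artifact;
powerline interference; stimulator-specific artifact waveforms (real
artifacts are not ideal charge-balanced rectangles); force or torque; and
between-muscle variability.  Parameter recovery here demonstrates that the
pipeline's inference is correct when its signal model holds, not that the
signal model captures every property of clinical recordings.

## Problem sizes

The default verification runs use one canonical 60 s trial for the stage
count, a 10-subject × 14-current cohort (≈140 trials, 8–90 s each) for
dose–duration recovery, a single-subject noiseless cohort for
monotonicity, and 4-level one-factor sweeps for effect signs.  At these
sizes the whole suite completes in well under a minute on one core.

## Known limitations

- t_max resolution is bounded by the 1-s RMS window and the smoothness of
  the degree-6 fit; on the canonical trial the planted 40 s peak is
  recovered at ≈42 s.  The bias is smooth and nearly proportional across
  currents, so cohort-level k inflates by a few percent rather than
  distorting the law's shape.
- The degree-6 polynomial smooths narrow recovery troughs; the recovery/
  fatigue boundary can sit a few seconds late relative to the generating
  envelope even when it matches the fitted curve's own minimum exactly.
- The separation returns wavelet coefficients, not a reconstructed
  waveform; quantities that depend on absolute evoked amplitude (rather
  than envelope shape) are out of reach by design.
- The inverse-proportional model is descriptive; i0 is a fitting offset,
  not a measured rheobase.
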