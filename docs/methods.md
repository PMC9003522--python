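# Methods

## The measurement model

A surgically created arteriovenous fistula (AVF) on a dialysis patient's
forearm is imaged by a fixed RGB camera at 40 frames per second for 10 s.
Each pixel's luminance varies with the cardiac cycle, not through the
absorbance change exploited by contact photoplethysmography but through
*displacement*: as arterial blood distends the anastomosis, the vessel's
parietal surface moves toward the camera and reflects more light, while
the vessel's shadow on the laterally adjacent skin grows, darkening
those pixels in anti-phase. The per-pixel pulse wave decomposes into a
heartbeat component and a thrill component — the palpable 5–10 Hz
vibration caused by turbulent flow at the anastomosis:

    W_AVF(t) = W_heartbeat(t) + W_thrill(t)

`avfpulse` implements the full analysis chain for such recordings:
channel conversion, spatial moving-average denoising, band-power SNR
quantification (SNAVF), hemodynamic color mapping, and cohort
summarization — plus a synthetic phantom so every stage is testable
without clinical video.

## Spatial moving-average filtering

Each frame `f(i,j)` is correlated with an N×M kernel of weights
`h(m,n)` (uniform `1/(N·M)` by default), sliding one pixel at a time:

    g(i,j) = Σ_m Σ_n h(m,n) · f(i+m, j+n)

with offsets running over the centred window `−(N−1)/2 … +(N−1)/2`.
Averaging K pixels that carry the pulse in the same phase preserves the
pulse amplitude while reducing i.i.d. noise variance by `1/K` — for a
uniform N×N kernel, by `1/N²` — the same mechanism as additive
averaging of repeated sweeps in evoked-potential measurement. Kernel
size is therefore the single denoising knob, and is swept over odd
sizes 1, 3, …, 201 (at 0.08 scale units per pixel, extents 0.08 to
16.08).

Boundary handling is *valid-region only*: output pixels exist only
where the kernel fits entirely inside the frame. The region of
interest sits near the anastomosis, away from frame edges, and any
padding would bias the SNR near boundaries. A reflect-padding mode
exists but is off by default. Filtering every frame and then reading
one pixel is mathematically identical to averaging many single-pixel
traces (linearity); the implementation filters frames, and the kernel
sweep uses per-frame integral images so each N×N box mean costs O(1)
— verified in tests against both the convolution route and a
double-loop oracle.

## SNAVF quantification

A 256-sample segment of the (kernel-averaged) trace is analysed with a
rectangular-window FFT after mean removal (the static baseline would
otherwise dwarf the band powers; the analysis concerns luminance
*change*). Powers are one-sided periodogram bins scaled so they sum to
the segment's mean square (Parseval); an on-grid tone of amplitude *a*
carries `a²/2`. Any fixed normalization cancels in the ratio below.

* **Signal band 1–5 Hz** — resting heart rates of 60–100 bpm plus
  margin. The fundamental is the largest bin in the band; the signal
  power AVFs adds the largest bin within ±1 bin of twice the
  fundamental frequency. The second harmonic is counted even when it
  falls above 5 Hz, because the pulse wave is defined as fundamental
  plus second harmonic, not as everything in-band.
* **Noise band 10–19 Hz** — above the 5–10 Hz thrill band (so the
  thrill does not count as noise) and below the 20 Hz Nyquist limit of
  a 40 fps camera. The noise power AVFn is the sum of the two largest
  bins in the band.

The statistic is the ratio maximized over the kernel sweep:

    SNAVF = max_N  AVFs(N) / AVFn(N)

and the arg-max N is the *optimal kernel*. On in-phase vessel pixels
the ratio grows roughly as N² while the window stays inside the
vessel, then falls once it swallows the anti-phase shadow — the
rise-then-fall SNR curve is itself an acceptance property of the
implementation.

Numerical choices:

* Rectangular window by default so on-grid tones are exact bin
  impulses (a Hann window would trade that for lower leakage; the
  band-pass masks operate on raw bins).
* Ties between ratios at different N are broken toward the smallest
  (cheapest) kernel; "tie" includes equality within 1e−12 relative, so
  the ~1e−16 roundoff of the integral-image fast path cannot break an
  exact tie arbitrarily.
* A noise-band power below 1e−24 of the segment's total power is
  treated as numerically zero (noise-free synthetic input); the ratio
  is then reported as +infinity with a warning rather than raising.
  Exact zero is unreachable in floating FFT arithmetic — the residual
  bins of an exact tone sit around 1e−13 in amplitude — so a
  machine-precision floor is the faithful reading of "noise-free".
  Real recordings never trigger it.
* `band_pass` zeroes half-spectrum bins outside the (inclusive) band
  and inverse-transforms, so output is real and in-band on-grid tones
  pass bit-exactly.

The sweep quantifies one analysis point (the ROI); maximizing over all
valid pixels per kernel size is a possible extension that was left out
— it changes the statistic's distribution under noise (max over many
correlated pixels) and the single-ROI reading matches how the
measurement is made, with the ROI placed on the anastomosis.

## Channel choice

Luminance is the ITU-style weighted sum `0.299R + 0.587G + 0.114B`.
The acquisition hardware does not define its luminance computation, so
a fixed documented formula keeps outputs reproducible; the weights are
overridable, including a blue-channel-only mode (`weights=(0,0,1)`)
relevant when the scene is lit by a blue illuminator. Hue and
saturation use the standard hexcone (HSV) conversion; hue of
achromatic pixels (mathematically undefined) is set to 0 so no NaN
reaches the FFT. For a fixed skin chromaticity the displacement signal
modulates brightness only, so the luminance trace carries the pulse
while hue/saturation stay nearly flat — `peak_to_peak` quantifies that
comparison.

## Color mapping

Band-passed luminance change is quantized linearly to 256 levels
(round-half-up on the 0–255 scale, out-of-domain values clamped) and
painted with a diverging palette, blue at the positive (tense, vessel
distended) end and red at the negative (relaxed) end. The built-in
`blue-red` palette sets level *i* to `(255−i, 255−|2i−255|, i)`; the
red channel falls by exactly one count per level, which guarantees 256
distinct 8-bit colors. Matplotlib palettes are accepted and validated
for the same property. The default domain is the sequence-global
amplitude symmetrized about zero (`vmin = −vmax = max|value|`) so zero
change sits at the palette centre and the same value maps to the same
color in every frame.

## Cohort summary

Raw SNAVF values are positive ratios whose scale depends on
acquisition conditions, so a cohort is balanced by its average:
`n_i = (v_i − mean)/mean`, giving mean exactly 0 and invariance to any
common positive rescaling. This relative-deviation rule is an
inference: it is the simplest "balanced by the average" rule under
which a raw maximum of 0.18 maps to a normalized maximum of 1.44
(implying a raw mean of 0.18/2.44 ≈ 0.074 — exposed as
`implied_mean_raw`). A z-score alternative is available. Quartiles
follow the lower/upper-half-median rule (Moore–McCabe): Q2 is the
median, Q1/Q3 are medians of the halves below/above it (overall median
excluded for odd counts), and the "fourth quartile" is reported as the
maximum. Published cohort summaries also quote a median (−0.37)
differing from the quoted Q2 (−0.60); those two cannot both be the
median under one definition, so neither is asserted against — the
rules here are tested against their own brute-force oracles instead.

## The synthetic phantom

`PhantomConfig` renders a vertical vessel strip (parietal region,
halfwidth 20 px) flanked by shadow bands (halfwidth 30 px) on a
uniform background, 221×221 px — the smallest frame that comfortably
holds the valid region of the full 201-px sweep — at 40 fps for 10 s:

| parameter | default | meaning |
|---|---|---|
| `f0` | 1.25 Hz | heartbeat fundamental (75 bpm; on-grid at 256-pt FFT @ 40 fps) |
| `heartbeat_amp` | 5 | fundamental amplitude, 8-bit luminance units |
| `harmonic_ratio` | 0.3 | 2nd-harmonic amplitude relative to fundamental |
| `thrill_freq`, `thrill_amp` | 7 Hz, 1 | single-tone thrill, mid 5–10 Hz band, parietal only |
| `shadow_gain` | 0.5 | anti-phase amplitude ratio in the shadow bands |
| `baseline`, `noise_sigma` | 120, 2 | mean luminance; i.i.d. Gaussian pixel noise |
| `tint` | (1.0, 0.82, 0.70) | fixed skin-like chromaticity |

Parietal pixels carry `baseline + heartbeat + thrill + noise`, shadow
pixels `baseline − shadow_gain·heartbeat + noise` (anti-phase,
thrill-free), background `baseline + noise`. Frames are rounded to
uint8 by default; `quantize=False` keeps float64 so exact spectral
identities can be tested. Validation warns if the deterministic swing
plus a 3σ noise allowance could clip at [0, 255], since clipping
distorts spectra. All randomness flows from one seed; identical
configs give bit-identical stacks.

What the phantom does *not* emulate: photorealistic skin texture,
motion of subject or camera, illumination drift beyond an optional
sinusoidal term, spatially correlated sensor noise, vessel curvature
or perspective, and broadband thrill. Passing tests therefore
demonstrate the correctness of the *algorithms* under the stated
signal model, not clinical performance; the published patient-cohort
numbers are not reproducible without patient video and are not
asserted anywhere in the suite.

## Problem sizes used by the test suite

The SNR-curve-shape and kernel-recovery checks run the full default
phantom and complete 1–201 sweep over 20 seeds (shared fixture);
kernel recovery asks the median |optimal N − 41| over seeds to stay
within 8 px of the 41-px in-phase width. The noise-power law is
measured at N ∈ {3, 9, 15} over 50 seeds of 8-frame 31×31 noise
stacks; filter-vs-oracle equivalence uses 200 random frames up to
15×15; quartile and spectral identities use 1000 and 100 random cases
respectively. `scripts/acceptance.py` repeats the headline
computations at 10 sweep seeds / 5 phase seeds / 50 noise seeds,
deriving all child seeds from `--seed`.

## Known limitations

* Single-ROI quantification; no spatial scan of the statistic.
* Ideal (rectangular-mask) FFT band-pass only; no FIR/IIR option.
* Video-container I/O depends on an ffmpeg-capable imageio backend and
  is lossy-codec dependent; TIFF and the raw-RGB dialect are the
  lossless formats.
* No stenosis classification: the statistic quantifies, thresholds for
  clinical judgement are out of scope.
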