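# Methods

## Signal model and workflow

A recording is a stack of grayscale frames `F(t, y, x)` in arbitrary units
of fluorescence (AUF), sampled uniformly at a user-declared frame rate
(typical optical-mapping cameras run 0.5–2 kHz). Each tissue pixel carries a
periodic transient riding on a baseline F0: an action potential (fast
upstroke, slower repolarization; with potentiometric dyes often a *downward*
deflection) or a calcium transient (slower upstroke and reuptake). The
pipeline conditions each pixel's series, then reads landmark times off
smoothed derivatives:

* **activation** — argmax of the smoothed first derivative (dF/dt max)
  between the start marker and the peak;
* **peak** — argmax of the trace in the analysis window;
* **downstroke** — argmin of the first derivative after the peak;
* **end** — argmax of the second derivative after the downstroke.

Durations (APD_x / CaD_x) run from activation to the first *interpolated*
downward crossing of `F0 + (1 − x/100)·amplitude` after the peak; linear
interpolation between the bracketing samples gives sub-frame resolution,
which matters whenever the frame interval is comparable to the millisecond
precision of reported durations. The decay constant τ is the interpolated
time from the peak to the loss of a (1 − 1/e) amplitude fraction, which for
an ideal mono-exponential decay equals its time constant. The diastolic
interval is the gap between one beat's x% recovery and the next beat's
activation. dF/F0 is computed on the raw (un-normalized, un-detrended)
trace, since both normalization and detrending destroy the baseline
reference.

### Baseline definition

F0 is the mean of the diastolic samples between the start marker and the
**upstroke onset**, estimated as the last pre-activation sample where the
smoothed derivative is below 10% of its value at activation. Ending the
baseline at dF/dt-max instead (the naive reading of "baseline period")
includes the foot of the upstroke, inflates F0, and shifts the recovery
level upward; on long-duration transients with shallow tails this shortens
measured durations by several ms. The onset time is recorded on
`TransientFeatures.onset_time`.

### Transience guard

Per-pixel map generation runs the detector over thousands of pixels, many
signal-free (background, injured tissue), so the guard against analyzing
noise must have a low false-positive rate under the actual noise the
detector sees: low-pass-filtered, hence autocorrelated, Gaussian noise. A
threshold of k·SD referenced to the pre-activation baseline is fragile
there — the SD estimate from a short correlated segment is biased low and
highly variable, giving ~20–25% false detections in simulation. The guard
therefore accepts a window if its maximum exceeds either

* the window **median** by `threshold_sd` robust noise SDs
  (1.4826 × median absolute deviation over the window) — robust both to the
  transient (a minority of a well-placed window) and to baseline wander; or
* the pre-activation baseline mean by `2.4 × threshold_sd` sample SDs, with
  at least 10 baseline samples — covering windows whose transient
  legitimately dominates the samples (where the MAD is inflated); the
  stricter multiplier compensates the small-sample, autocorrelation-biased
  SD estimate.

With the default `threshold_sd = 5` the measured false-detection rate on
filtered pure-noise traces is at the percent level, while the weakest
transient in a usable recording (SNR ≈ 20 before filtering) clears the
guard with a several-fold margin.

## Conditioning

* **Temporal filter** — low-pass Butterworth, default order 4 and cutoff
  100 Hz (a conventional choice for 1 kHz acquisition; species and camera
  rate may warrant other cutoffs, which are left to the user rather than
  auto-selected). Applied forward and backward (`sosfiltfilt`), so the net
  phase is zero — landmark times shift by less than half a frame — and the
  effective magnitude response is the squared one-pass response (amplitude
  1/2 at the cutoff). Edge transients are absorbed by odd signal-extension
  padding.
* **Spatial filter** — per-frame normalized convolution with a box or
  Gaussian kernel. Where a mask is present, weights are renormalized over
  foreground neighbors so tissue edges are not dragged toward the zeroed
  background; the same mechanism handles the image border.
* **Detrending** — per-pixel least-squares polynomial over the full
  recording, subtracted. Order n exactly annihilates polynomial drift of
  degree ≤ n (the fit is a projection); typical photobleaching is handled
  by order 1–2.
* **Normalization** — per-pixel affine map of the min/max to [0, 1].
  Constant foreground pixels carry no signal and are zeroed (excluded from
  maps) rather than raising an error for the whole stack.

The recommended order is mask → spatial → temporal → detrend → normalize,
but each step is independent and optional; all steps preserve stack
dimensions and frame count.

## Segmentation

Masks are computed from the first frame and applied to all frames
(background set exactly to 0; downstream analysis treats zeros as "no
data"). Four algorithms: exact Otsu (exhaustive maximization of
between-class variance over unique-value midpoints — exact rather than
histogram-binned, so the threshold is the true argmax on continuous data),
brightest-fraction with morphological closing → opening → dilation (square
element; kernel 1 = no-op; ties in the intensity sort break in raster order
for determinism), random-walker diffusion labeling (scikit-image, edge
weight β = 130 on contrast-normalized intensities; seeds auto-placed on the
brightest/darkest deciles of an Otsu pre-labeling when not supplied), and
global-mean thresholding. Pixels exactly at a threshold are background
(strict inequality for foreground). The structuring element is square; the
shape is a documented parameterization choice, not a claim about any
particular instrument.

## SNR estimation

SNR = transient amplitude / SD of the diastolic baseline (sample SD, n−1).
The amplitude references the baseline mean; the peak is read from a copy of
the trace smoothed by a 5-sample centered moving average, because the raw
maximum of a noisy trace is inflated by the expected extreme of the noise
(≈ +12% at SNR 25 in simulation), which would bias the estimator exactly
where calibration matters most. With the smoothed peak, Monte-Carlo means
over 100 phantom traces sit within a few percent of the generator target at
SNR 25–100.

## Maps

Activation maps subtract the earliest defined activation, so values are
propagation delays in ms (color scales start at 0, consistent with
isochronal-map convention). Undefined pixels — background, failed
detection, duration not reached within `max_interval` — are NaN in memory,
blank fields in CSV and white in PNG renders, never 0 (0 would read as
early activation). A map computation fails outright if more than half the
foreground pixels fail detection. All pixels share one analysis window;
there is no per-pixel window adaptation. `total_activation_time` is the
full range (max − min) of defined values.

## Phantom generator

The phantom is the package's ground-truth oracle; it is piecewise analytic
rather than a biophysical ionic model precisely so that landmark times are
known in closed form. Per beat:

* **upstroke**: half-cosine rise of duration `u` (defaults 10 ms voltage,
  20 ms calcium), whose derivative maximum — the activation time — is
  exactly at the midpoint `u/2`;
* **repolarization**: logistic ("exponential-shouldered") decay. With
  `D = apd80 − u/2` and width `w = repol_width_frac · D` (default 0.15,
  giving a plateau-then-fall shape like a cardiac action potential), the
  midpoint solves in closed form so that the first crossing of 20%
  amplitude after the peak falls exactly `apd80` after activation:
  `exp((t_peak − t_r)/w) = 4 / (exp(D/w) − 5)`, which requires
  `w < D/ln 5`.

Defaults emulate a rat heart at 1 kHz on a 64×64 sensor over a ~2 cm field:
baseline F0 = 100 AUF, amplitude 8 AUF (dF/F0 = 0.08, a typical fractional
dye signal), background 10 AUF, APD80 = 57 ms (voltage) / CaD80 = 90 ms
(calcium) — rat-scale values — stimulus onset at 50 ms, planar propagation
at 50 cm/s. Voltage phantoms are emitted inverted (downward deflection) by
default, as potentiometric dyes produce. Noise is i.i.d. Gaussian per pixel
per frame with SNR = amplitude/noise_sd; drift is polynomial and/or
exponential photobleaching added after the clean waveform. An optional
restitution rule (`apd_k = apd80·(1 − c·exp(−DI/τ_rest))`, defaults
c = 0.35, τ_rest = 60 ms) shortens beats after short diastolic intervals,
for rate-dependence studies. Fixed seeds give bit-identical output.

What the phantom does **not** emulate: shot (signal-dependent) noise,
motion/contraction artifact, optical point-spread blurring, dye
internalization dynamics, ionic-model waveform detail, and alternans beyond
the simple restitution rule. Passing the phantom suite therefore
demonstrates the correctness of the *analysis* (geometry, timing,
interpolation, filters, statistics) under controlled conditions, not
robustness to every artifact of experimental recordings.

## Problem sizes and numerical choices

The validation suite uses 64×64 (and smaller) grids, ≤ ~500 frames and 100
Monte-Carlo replicates per condition — sizes chosen so ground truth is
sharp and the full suite runs in seconds on one CPU; the pipeline itself is
vectorized per-frame/per-pixel and handles sensor-scale stacks (e.g.
2016×2016) identically. Other choices: argmax/argmin ties break toward the
earliest sample; derivative smoothing is a centered moving average of width
5 (no phase lag); crop rectangles are half-open, 0-based, row-major; only
lossless quarter-turn rotations are offered (arbitrary angles would
interpolate intensities); polarity inversion is about the per-pixel
(min+max)/2 so heterogeneous illumination cannot clip signals; frame timing
derives solely from the declared fps (TIFF timing metadata is ignored);
TIFF round trips are lossless (integer inputs widened to float without
rescaling).

"End time" is implemented as the maximum of the second derivative in the
post-downstroke window (not the second local maximum of d², an alternative
reading of the same landmark); the two coincide on clean transients.
F0 is per-beat, not per-recording, so drifting multi-beat traces remain
analyzable beat by beat; beats whose detection fails are skipped with a
logged warning rather than aborting the trace.

## Known limitations

Conduction-velocity vector fields, alternans classification, SNR maps,
phase/spiral-wave analysis, ratiometric and panoramic imaging are out of
scope. Multi-beat windows assume beats are separable by peak prominence;
heavily fused beats (very fast pacing) defeat the per-beat slicing. The
random-walker's β and the morphology element shape are parameterized
defaults, not tuned per dataset.
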