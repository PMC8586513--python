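# optomap

Analysis of cardiac optical-mapping recordings: from raw fluorescence image
stacks of dye-loaded heart tissue to per-pixel activation (isochronal) and
duration maps, and per-transient metrics.

Optical mapping (optocardiography) images cardiac electrical and calcium
activity with parameter-sensitive fluorescent dyes and fast cameras. A
recording is a multi-page TIFF stack; each pixel carries a time series of
action potentials (V_m, usually a downward deflection requiring polarity
inversion) or calcium transients (Ca²⁺, slower kinetics). `optomap` is a
scriptable library plus CLI for the standard analysis workflow:

1. **Image properties** — import the TIFF stack with user-declared frame
   rate (fps), spatial scale (px/cm) and signal kind; crop, rotate by
   quarter turns, invert polarity about each pixel's central value.
2. **Processing** — segment tissue from background (Otsu, intensity
   fraction, random-walker or mean thresholding, with morphological
   smoothing), spatial box/Gaussian filtering, zero-phase (bidirectional)
   low-pass Butterworth temporal filtering, per-pixel least-squares
   polynomial detrending (photobleaching), and 0–1 normalization.
3. **Analysis** — per trace: activation (time of dF/dt max), peak,
   downstroke (dF/dt min), end (second-derivative maximum), baseline F0;
   derived metrics APD_x/CaD_x (time from activation to x% recovery,
   sub-frame via linear interpolation), diastolic interval, mono-exponential
   decay time τ (time to lose a 1−1/e amplitude fraction), fractional
   amplitude dF/F0, and SNR (amplitude / baseline SD). Per stack: activation
   maps re-zeroed to the earliest pixel, duration maps at any percentage,
   ROI ensemble traces. Exports to CSV/PNG/TIFF.

Because public per-pixel ground truth does not exist for experimental
recordings, the package ships a **phantom generator** (`optomap.phantom`)
producing synthetic stacks with analytically known activation times,
durations, amplitudes and SNR — planar/radial wavefronts at a set conduction
velocity, tissue ellipse over dark background, optional "ablation" disk,
Gaussian noise and baseline drift. The whole test suite validates the
pipeline against these phantoms.

## Worked example

```python
import numpy as np
import optomap as om

# synthesize a noisy rat-like voltage recording (1 kHz, 64x64, SNR 100)
spec = om.PhantomSpec(noise_sd=0.08, seed=1)
stack, truth = om.make_stack(spec)

stack = om.invert_polarity(stack)                    # voltage dyes deflect downward
mask = om.mask_otsu(stack.frames[0])                 # tissue vs background
stack = om.apply_mask(stack, mask)
stack = om.temporal_filter(stack, cutoff_hz=100.0)   # zero-phase Butterworth
stack = om.normalize(stack)

window = om.AnalysisWindow(start_marker=0.0, end_marker=float(stack.times_ms[-1]),
                           max_interval=400.0, percent=80.0)
amap = om.activation_map(stack, window)
dmap = om.duration_map(stack, window)

roi = om.ROI(center=(32, 32), radius=3)
trace = om.ensemble_trace(stack, roi)
f = om.detect_features(trace, window)

print(f"tissue pixels:          {mask.n_foreground}")
print(f"total activation time:  {om.total_activation_time(amap):.1f} ms")
print(f"mean APD80 (map):       {np.nanmean(dmap.values):.1f} ms")
print(f"ROI activation time:    {f.activation_time:.1f} ms")
print(f"ROI APD80:              {om.duration(trace, f, window):.1f} ms")
print(f"ROI decay tau:          {om.decay_tau(trace, f):.1f} ms")
```

prints

```
tissue pixels:          2608
total activation time:  36.0 ms
mean APD80 (map):       56.8 ms
ROI activation time:    75.0 ms
ROI APD80:              57.0 ms
ROI decay tau:          43.3 ms
```

The phantom propagates a planar wave at 50 cm/s across a tissue ellipse
spanning ~1.8 cm, so the activation map ranges over ~36 ms; the generator's
APD80 target of 57 ms (a rat-like scale) is recovered both in the map mean
and at the center ROI, whose wavefront arrival (75 ms: 50 ms stimulus delay
+ upstroke midpoint + 1 cm of propagation) matches the geometry.

From the shell, the same workflow is:

```sh
optomap phantom --out phantom.tif
optomap analyze --config run.yaml     # flat YAML: input, fps, mask, filters, markers
```

Each run writes `activation_map.csv`/`duration_map.csv` (blank fields mark
undefined pixels), optional PNG renders, and a `manifest.txt` recording
every parameter plus the input checksum, sufficient to re-run the analysis
identically.

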