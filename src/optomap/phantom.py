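"""Synthetic optical-mapping phantoms with analytically known ground truth.

Every pipeline stage is verified against stacks and traces generated here,
since real optical-mapping recordings ship no per-pixel ground truth. The
waveform is piecewise analytic rather than a biophysical ionic model, so the
landmark times are known exactly:

* upstroke — a half-cosine rise of duration ``u`` ms, whose maximum first
  derivative (the activation time) falls exactly at its midpoint;
* repolarization — a logistic ("exponential-shouldered") decay whose
  midpoint and width are solved in closed form so that the first crossing of
  ``F0 + 0.2 * amplitude`` after the peak occurs exactly ``apd80`` ms after
  the activation time. The logistic width defaults to 15% of the
  activation-to-APD80 interval, giving a plateau-then-fall shape like a
  cardiac action potential; calcium defaults are slower (longer upstroke and
  duration) than voltage, as in real dye recordings.

Spatial stacks delay each pixel's waveform by a geometric activation offset
(planar wavefront at a set conduction velocity, radial spread from an
origin, or simultaneous), on a bright tissue ellipse (or full frame) over a
dark background, with optional amplitude-zeroed "ablation" disk, additive
i.i.d. Gaussian noise at a target SNR = amplitude / noise_sd, and slow
polynomial / exponential-photobleach baseline drift. Voltage phantoms are
emitted inverted (downward deflections) by default, as potentiometric dyes
produce. A fixed seed reproduces stacks bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .conditioning import Trace
from .errors import ValidationError
from .stack_io import ImageStack

__all__ = ["PhantomSpec", "GroundTruth", "make_trace", "make_stack"]

_DEFAULTS = {
    # upstroke ms, duration-at-80% ms: rat-like voltage vs slower calcium
    "voltage": {"upstroke_ms": 10.0, "apd80_ms": 57.0},
    "calcium": {"upstroke_ms": 20.0, "apd80_ms": 90.0},
}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic recording; defaults emulate a rat heart
    imaged at 1 kHz on a 64 x 64 sensor covering a 2 cm field."""

    shape: Tuple[int, int] = (64, 64)
    scale: float = 32.0              # px/cm
    fps: float = 1000.0
    signal_kind: str = "voltage"
    n_beats: int = 1
    cycle_length_ms: Union[float, Sequence[float]] = 250.0
    first_onset_ms: float = 50.0
    duration_ms: Optional[float] = None   # recording length; auto if None
    upstroke_ms: Optional[float] = None   # default by signal_kind
    apd80_ms: Optional[float] = None      # default by signal_kind
    repol_width_frac: float = 0.15        # logistic width / (apd80 - u/2)
    f0: float = 100.0                     # baseline fluorescence, AUF
    amplitude: float = 8.0                # transient amplitude, AUF (dF/F0 = 0.08)
    background: float = 10.0              # non-tissue intensity, AUF
    noise_sd: float = 0.0                 # AUF; SNR = amplitude / noise_sd
    drift_poly: Tuple[float, ...] = ()    # AUF/ms, AUF/ms^2, ... added drift
    bleach: Optional[Tuple[float, float]] = None  # (amplitude AUF, tau ms)
    propagation: str = "planar"           # planar | radial | simultaneous
    velocity: float = 50.0                # cm/s, for propagating modes
    origin: Tuple[int, int] = (0, 0)      # radial origin (row, col), px
    geometry: str = "ellipse"             # ellipse | full
    ablation: Optional[Tuple[int, int, float]] = None  # (row, col, radius px)
    apd80_span_ms: Optional[Tuple[float, float]] = None  # linear col gradient
    emit_inverted: Optional[bool] = None  # default: True for voltage
    restitution: bool = False
    restitution_c: float = 0.35
    restitution_tau_ms: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_kind not in _DEFAULTS:
            raise ValidationError(f"unknown signal_kind {self.signal_kind!r}")
        if self.upstroke_ms is None:
            self.upstroke_ms = _DEFAULTS[self.signal_kind]["upstroke_ms"]
        if self.apd80_ms is None:
            self.apd80_ms = _DEFAULTS[self.signal_kind]["apd80_ms"]
        if self.emit_inverted is None:
            self.emit_inverted = self.signal_kind == "voltage"
        if not self.apd80_ms > self.upstroke_ms / 2:
            raise ValidationError("apd80_ms must exceed half the upstroke")
        if not 0 < self.repol_width_frac < 1 / np.log(5):
            raise ValidationError(
                "repol_width_frac must lie in (0, 1/ln 5) for the 20% "
                "crossing to exist"
            )
        cycles = self.cycle_lengths
        if len(cycles) != max(self.n_beats - 1, 0):
            raise ValidationError(
                f"need {self.n_beats - 1} cycle lengths for {self.n_beats} "
                f"beats, got {len(cycles)}"
            )
        if any(c <= self.apd80_ms + self.upstroke_ms for c in cycles):
            raise ValidationError(
                "cycle_length_ms must exceed apd80_ms + upstroke_ms"
            )
        if self.propagation not in ("planar", "radial", "simultaneous"):
            raise ValidationError(f"unknown propagation {self.propagation!r}")
        if self.propagation != "simultaneous" and not self.velocity > 0:
            raise ValidationError("velocity must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def cycle_lengths(self) -> Tuple[float, ...]:
        """Inter-beat intervals, one per gap between consecutive beats."""
        n = max(self.n_beats - 1, 0)
        if np.isscalar(self.cycle_length_ms):
            return (float(self.cycle_length_ms),) * n
        return tuple(float(c) for c in self.cycle_length_ms)[:n]

    @property
    def snr(self) -> float:
        return self.amplitude / self.noise_sd if self.noise_sd > 0 else np.inf


@dataclass
class GroundTruth:
    """Analytic truth accompanying a phantom trace or stack."""

    f0_true: float
    amplitude_true: float
    snr_true: float
    onset_times_ms: np.ndarray            # beat onsets
    activation_times_ms: np.ndarray       # per-beat dF/dt-max times (trace)
    apd80_per_beat_ms: np.ndarray
    activation_map_true: Optional[np.ndarray] = field(default=None, repr=False)
    duration80_true: Optional[np.ndarray] = field(default=None, repr=False)
    tissue_mask_true: Optional[np.ndarray] = field(default=None, repr=False)
    ablation_mask_true: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def activation_time_ms(self) -> float:
        """First-beat activation time (convenience for single-beat phantoms)."""
        return float(self.activation_times_ms[0])

    @property
    def apd80_ms(self) -> float:
        return float(self.apd80_per_beat_ms[0])


def _beat_shape(trel, u: float, D, w_frac: float):
    """Normalized waveform s in [0, 1] at time ``trel`` ms after beat onset.

    Half-cosine upstroke on [0, u]; logistic decay afterwards, solved so the
    first downward crossing of s = 0.2 occurs at trel = u/2 + D (i.e. D ms
    after the activation time u/2).
    """
    trel = np.asarray(trel, dtype=float)
    D = np.asarray(D, dtype=float)
    w = w_frac * D
    # closed form: exp((t_peak - t_r)/w) = 4 / (exp(D/w) - 5)
    y = 4.0 / (np.expm1(D / w) - 4.0)
    t_r = u - w * np.log(y)
    g_peak = 1.0 / (1.0 + y)
    expo = np.clip((trel - t_r) / w, -700.0, 700.0)
    tail = 1.0 / (1.0 + np.exp(expo)) / g_peak
    up = 0.5 * (1.0 - np.cos(np.pi * np.clip(trel, 0.0, u) / u))
    return np.where(trel <= 0, 0.0, np.where(trel < u, up, tail))


def _beat_schedule(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Beat onsets and per-beat APD80 targets, applying restitution if set.

    The restitution rule shortens a beat's duration as the preceding
    diastolic interval shrinks: apd_k = apd80 * (1 - c * exp(-DI / tau)).
    """
    onsets = np.empty(spec.n_beats)
    apds = np.empty(spec.n_beats)
    onsets[0] = spec.first_onset_ms
    apds[0] = spec.apd80_ms
    cycles = spec.cycle_lengths
    u2 = spec.upstroke_ms / 2
    for k in range(1, spec.n_beats):
        onsets[k] = onsets[k - 1] + cycles[k - 1]
        if spec.restitution:
            di = (onsets[k] + u2) - (onsets[k - 1] + u2 + apds[k - 1])
            if di <= 0:
                raise ValidationError("restitution schedule overlaps beats")
            apds[k] = spec.apd80_ms * (
                1.0 - spec.restitution_c * np.exp(-di / spec.restitution_tau_ms)
            )
        else:
            apds[k] = spec.apd80_ms
    return onsets, apds


def _times(spec: PhantomSpec, extra_ms: float = 0.0) -> np.ndarray:
    if spec.duration_ms is not None:
        total = spec.duration_ms
    else:
        onsets, apds = _beat_schedule(spec)
        total = (
            onsets[-1] + spec.upstroke_ms + 2.0 * apds.max() + 60.0 + extra_ms
        )
    n = int(np.ceil(total * spec.fps / 1000.0))
    return np.arange(n) * 1000.0 / spec.fps


def _drift(spec: PhantomSpec, t: np.ndarray) -> np.ndarray:
    d = np.zeros_like(t)
    for k, c in enumerate(spec.drift_poly, start=1):
        d += c * t**k
    if spec.bleach is not None:
        amp, tau = spec.bleach
        d += amp * (np.exp(-t / tau) - 1.0)
    return d


def _clean_sum(t, onsets, apds, spec: PhantomSpec):
    """Sum of beat shapes at times ``t`` (any broadcastable shape)."""
    s = np.zeros(np.broadcast_shapes(np.shape(t), np.shape(apds[0] * 1.0)))
    u2 = spec.upstroke_ms / 2
    for onset, apd in zip(onsets, apds):
        D = np.asarray(apd, dtype=float) - u2
        s = s + _beat_shape(t - onset, spec.upstroke_ms, D, spec.repol_width_frac)
    return s


def make_trace(spec: PhantomSpec) -> Tuple[Trace, GroundTruth]:
    """Generate one pixel's trace (no geometry/background) plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    t = _times(spec)
    onsets, apds = _beat_schedule(spec)
    s = _clean_sum(t, onsets, apds, spec)
    values = spec.f0 + spec.amplitude * s
    if spec.emit_inverted:
        values = spec.f0 + spec.amplitude * (1.0 - s)
    values = values + _drift(spec, t)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    truth = GroundTruth(
        f0_true=spec.f0,
        amplitude_true=spec.amplitude,
        snr_true=spec.snr,
        onset_times_ms=onsets,
        activation_times_ms=onsets + spec.upstroke_ms / 2,
        apd80_per_beat_ms=apds,
    )
    return Trace(values=values, fps=spec.fps), truth


def _geometry(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    if spec.geometry == "full":
        tissue = np.ones((h, w), dtype=bool)
    elif spec.geometry == "ellipse":
        a, b = 0.45 * h, 0.45 * w
        tissue = ((rr - (h - 1) / 2) / a) ** 2 + ((cc - (w - 1) / 2) / b) ** 2 <= 1.0
    else:
        raise ValidationError(f"unknown geometry {spec.geometry!r}")
    ablated = np.zeros((h, w), dtype=bool)
    if spec.ablation is not None:
        r0, c0, rad = spec.ablation
        ablated = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        ablated &= tissue
    return tissue, ablated


def _activation_offsets(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.shape
    rr, cc = np.mgrid[0:h, 0:w]
    if spec.propagation == "simultaneous":
        return np.zeros((h, w))
    if spec.propagation == "planar":
        dist_cm = cc / spec.scale
    else:  # radial
        r0, c0 = spec.origin
        dist_cm = np.hypot(rr - r0, cc - c0) / spec.scale
    return dist_cm / spec.velocity * 1000.0


def make_stack(spec: PhantomSpec) -> Tuple[ImageStack, GroundTruth]:
    """Generate a full image stack plus per-pixel ground-truth maps."""
    rng = np.random.default_rng(spec.seed)
    offsets = _activation_offsets(spec)
    tissue, ablated = _geometry(spec)
    active = tissue & ~ablated
    if not active.any():
        raise ValidationError("phantom has no active tissue pixels")
    t = _times(spec, extra_ms=float(offsets[active].max()))
    onsets, apds_beat = _beat_schedule(spec)

    if spec.apd80_span_ms is not None:
        lo, hi = spec.apd80_span_ms
        h, w = spec.shape
        apd_map = lo + (hi - lo) * (np.arange(w) / max(w - 1, 1))
        apd_map = np.broadcast_to(apd_map, (h, w)).copy()
        if spec.restitution:
            raise ValidationError("apd80_span_ms and restitution are exclusive")
        apds: Sequence = [apd_map] * spec.n_beats
    else:
        apds = list(apds_beat)

    trel = t[:, None, None] - offsets[None, :, :]
    s = _clean_sum(trel, onsets, apds, spec)
    amp = np.where(active, spec.amplitude, 0.0)
    if spec.emit_inverted:
        clean = spec.f0 + amp[None] * (1.0 - s)
    else:
        clean = spec.f0 + amp[None] * s
    frames = np.where(tissue[None], clean, spec.background)
    frames = frames + _drift(spec, t)[:, None, None]
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)

    act_true = np.where(active, offsets + onsets[0] + spec.upstroke_ms / 2, np.nan)
    act_true = act_true - np.nanmin(act_true)
    dur_true = np.where(
        active,
        apds[0] if spec.apd80_span_ms is not None else float(apds_beat[0]),
        np.nan,
    )
    truth = GroundTruth(
        f0_true=spec.f0,
        amplitude_true=spec.amplitude,
        snr_true=spec.snr,
        onset_times_ms=onsets,
        activation_times_ms=onsets + spec.upstroke_ms / 2,
        apd80_per_beat_ms=apds_beat,
        activation_map_true=act_true,
        duration80_true=dur_true,
        tissue_mask_true=tissue,
        ablation_mask_true=ablated,
    )
    stack = ImageStack(
        frames=frames,
        fps=spec.fps,
        scale=spec.scale,
        signal_kind=spec.signal_kind,
        inverted=False,
    )
    return stack, truth
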