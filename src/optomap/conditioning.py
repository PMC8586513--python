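"""Signal conditioning: spatial/temporal filtering, detrending, normalization
and signal-to-noise estimation.

Fluorescence recordings carry spatial "salt-and-pepper" noise, high-frequency
temporal noise, and slow baseline drift from photobleaching. The standard
remedies implemented here are

* spatial convolution with a normalized box or Gaussian kernel (applied
  frame-by-frame; at tissue edges the kernel is renormalized over foreground
  neighbors so masked zeros do not bleed into the signal),
* a bidirectionally applied low-pass Butterworth filter (forward then
  backward, hence zero net phase: landmark times are not shifted),
* subtraction of a per-pixel least-squares polynomial fit of user-chosen
  order, and
* per-pixel normalization from arbitrary units (AUF) to [0, 1].

All steps preserve stack dimensions and frame count, and each accepts either
a :class:`Trace` or an :class:`~optomap.stack_io.ImageStack`.

SNR is defined as the transient amplitude divided by the standard deviation
of the baseline during the diastolic interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple, Union

import numpy as np
from scipy import ndimage, signal

from .errors import DegenerateInputError, ValidationError
from .stack_io import ImageStack

__all__ = [
    "Trace",
    "SNRResult",
    "spatial_filter",
    "temporal_filter",
    "detrend",
    "normalize",
    "estimate_snr",
]


@dataclass
class Trace:
    """A uniformly sampled fluorescence time series (one pixel or an ROI mean).

    ``values`` are intensities in AUF or normalized units; ``fps`` the
    sampling rate in frames/s; ``t0`` the time of the first sample in ms.
    """

    values: np.ndarray
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trace values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to time ``t_ms``."""
        return int(round((t_ms - self.t0) / self.dt_ms))


@dataclass(frozen=True)
class SNRResult:
    """Amplitude, baseline noise and their ratio for one trace."""

    amplitude: float
    baseline_sd: float

    @property
    def snr(self) -> float:
        return self.amplitude / self.baseline_sd


def _min_samples(x: np.ndarray) -> None:
    if x.shape[0] < 8:
        raise ValidationError("filtering requires at least 8 samples")


def gaussian_kernel(kernel_size: int, sigma: float) -> np.ndarray:
    """Discretized, normalized 2-D Gaussian kernel."""
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def spatial_filter(
    stack: ImageStack,
    kind: str = "gaussian",
    kernel_size: int = 3,
    sigma: float = 1.0,
) -> ImageStack:
    """Convolve each frame with a normalized box or Gaussian kernel.

    Where a mask has been applied, kernel weights are renormalized over
    foreground neighbors (normalized convolution), so tissue edges are not
    pulled toward the zeroed background; background pixels remain exactly 0.
    The same renormalization handles the image border.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValidationError(
            f"kernel_size must be odd and >= 3, got {kernel_size}"
        )
    if kind == "box":
        kernel = np.full((kernel_size, kernel_size), 1.0 / kernel_size**2)
    elif kind == "gaussian":
        if not sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {sigma}")
        kernel = gaussian_kernel(kernel_size, sigma)
    else:
        raise ValidationError(f"unknown spatial filter kind {kind!r}")

    fg = (
        stack.mask.astype(float)
        if stack.mask is not None
        else np.ones(stack.frame_shape)
    )
    k3 = kernel[np.newaxis, :, :]
    num = ndimage.convolve(
        stack.frames * fg[np.newaxis], k3, mode="constant", cval=0.0
    )
    den = ndimage.convolve(fg, kernel, mode="constant", cval=0.0)
    out = np.zeros_like(stack.frames)
    valid = (fg > 0) & (den > 0)
    out[:, valid] = num[:, valid] / den[valid]
    return replace(stack, frames=out)


def temporal_filter(
    stack_or_trace: Union[ImageStack, Trace],
    cutoff_hz: float = 100.0,
    order: int = 4,
) -> Union[ImageStack, Trace]:
    """Zero-phase low-pass Butterworth filter along the time axis.

    The filter is applied forward then backward (``sosfiltfilt``), so the
    effective magnitude response is the squared one-pass response — amplitude
    at the cutoff is 1/2 — and the net phase shift is zero. Edge transients
    are handled by signal-extension padding.
    """
    if isinstance(stack_or_trace, Trace):
        fps, x, axis = stack_or_trace.fps, stack_or_trace.values, 0
    else:
        fps, x, axis = stack_or_trace.fps, stack_or_trace.frames, 0
    if not 0 < cutoff_hz < fps / 2:
        raise ValidationError(
            f"cutoff must lie in (0, Nyquist={fps / 2} Hz), got {cutoff_hz}"
        )
    if order < 1:
        raise ValidationError(f"order must be >= 1, got {order}")
    _min_samples(x)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fps, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=axis)
    return replace(stack_or_trace, **(
        {"values": y} if isinstance(stack_or_trace, Trace) else {"frames": y}
    ))


def detrend(
    stack_or_trace: Union[ImageStack, Trace], poly_order: int = 1
) -> Union[ImageStack, Trace]:
    """Subtract a per-pixel least-squares polynomial of the given order.

    The fit spans the entire recording. Order ``n`` exactly annihilates any
    polynomial input of degree <= ``n`` (output is numerically zero), which
    removes slow photobleaching drift while leaving transients centered on a
    flat baseline.
    """
    if poly_order < 0:
        raise ValidationError(f"poly_order must be >= 0, got {poly_order}")
    is_trace = isinstance(stack_or_trace, Trace)
    x = stack_or_trace.values if is_trace else stack_or_trace.frames
    n = x.shape[0]
    if n <= poly_order + 1:
        raise ValidationError(
            f"need more than poly_order + 1 = {poly_order + 1} samples, got {n}"
        )
    t = np.arange(n, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)  # scaled for conditioning
    vand = np.vander(t, poly_order + 1, increasing=True)
    flat = x.reshape(n, -1)
    coef, *_ = np.linalg.lstsq(vand, flat, rcond=None)
    resid = (flat - vand @ coef).reshape(x.shape)
    return replace(stack_or_trace, **(
        {"values": resid} if is_trace else {"frames": resid}
    ))


def normalize(
    stack_or_trace: Union[ImageStack, Trace]
) -> Union[ImageStack, Trace]:
    """Rescale each pixel's time series to [0, 1] (min -> 0, max -> 1).

    Constant foreground pixels (max == min) carry no signal; for stacks they
    are set to 0 and thereby excluded from downstream maps, while a constant
    single trace is a degenerate input.
    """
    if isinstance(stack_or_trace, Trace):
        x = stack_or_trace.values
        lo, hi = x.min(), x.max()
        if hi <= lo:
            raise DegenerateInputError("constant trace cannot be normalized")
        return replace(stack_or_trace, values=(x - lo) / (hi - lo))
    stack = stack_or_trace
    lo = stack.frames.min(axis=0, keepdims=True)
    hi = stack.frames.max(axis=0, keepdims=True)
    span = hi - lo
    ok = span > 0
    out = np.zeros_like(stack.frames)
    np.divide(stack.frames - lo, span, out=out, where=ok)
    return replace(stack, frames=out)


def estimate_snr(
    trace: Trace,
    baseline_window: Tuple[float, float],
    peak_smooth_window: int = 5,
) -> SNRResult:
    """Estimate SNR = (peak - baseline mean) / baseline SD.

    ``baseline_window`` is a ``(t_start, t_end)`` interval in ms that must lie
    in a diastolic (pre-upstroke) segment and contain at least 5 samples; the
    baseline SD uses the n-1 denominator. The amplitude references the
    baseline mean; the peak is read from a copy of the trace smoothed with a
    short centered moving average (``peak_smooth_window`` samples, odd), so
    the amplitude reflects the transient rather than the single largest
    noise excursion — a raw maximum would bias the estimate upward by the
    expected extreme of the noise, noticeably so at low SNR.
    """
    t_start, t_end = baseline_window
    t = trace.times_ms
    sel = (t >= t_start) & (t <= t_end)
    if t_start < t[0] or t_end > t[-1] or t_start >= t_end:
        raise ValidationError(
            f"baseline window {baseline_window} outside trace span "
            f"[{t[0]}, {t[-1]}] ms"
        )
    if sel.sum() < 5:
        raise ValidationError("baseline window must contain at least 5 samples")
    if peak_smooth_window < 1 or peak_smooth_window % 2 == 0:
        raise ValidationError(
            f"peak_smooth_window must be odd and >= 1, got {peak_smooth_window}"
        )
    base = trace.values[sel]
    sd = float(np.std(base, ddof=1))
    if sd == 0:
        raise DegenerateInputError("baseline SD is zero (noiseless trace)")
    smoothed = ndimage.uniform_filter1d(
        trace.values, peak_smooth_window, mode="nearest"
    )
    amplitude = float(smoothed.max() - base.mean())
    return SNRResult(amplitude=amplitude, baseline_sd=sd)
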