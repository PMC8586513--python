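"""Per-pixel activation (isochronal) and duration maps, ROI ensemble traces,
and summary arithmetic.

An activation map assigns each foreground pixel the time of its upstroke
(dF/dt max) and re-zeroes the map to the earliest-activating pixel, so
isochrones read as milliseconds of propagation delay. Duration maps hold
APD/CaD at a requested recovery percentage. Undefined pixels — background,
or pixels where detection failed — are encoded as NaN in memory, blank in
CSV exports and white in PNG renders, never 0 (0 would read as early
activation).

All pixels share a single analysis window (one start/end marker pair); there
is no per-pixel window adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .conditioning import Trace
from .errors import MapError, OptomapError, ValidationError
from .stack_io import ImageStack
from .transients import (
    DEFAULT_SMOOTH_WINDOW,
    DEFAULT_THRESHOLD_SD,
    AnalysisWindow,
    detect_features,
    duration,
)

__all__ = [
    "ScalarMap",
    "ROI",
    "activation_map",
    "duration_map",
    "total_activation_time",
    "ensemble_trace",
    "percent_change",
]


@dataclass
class ScalarMap:
    """A per-pixel map of one derived quantity; NaN marks undefined pixels."""

    values: np.ndarray
    quantity: str  # activation | duration | tau | snr_amplitude
    percent: Optional[float] = None
    reference_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("map values must be 2-D")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


@dataclass(frozen=True)
class ROI:
    """A region of interest: an explicit pixel set or a (center, radius) disk."""

    pixels: Optional[Tuple[Tuple[int, int], ...]] = None
    center: Optional[Tuple[float, float]] = None
    radius: Optional[float] = None

    def indicator(self, shape: Tuple[int, int]) -> np.ndarray:
        sel = np.zeros(shape, dtype=bool)
        if self.pixels is not None:
            for r, c in self.pixels:
                if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                    raise ValidationError(f"ROI pixel {(r, c)} out of bounds")
                sel[r, c] = True
        elif self.center is not None and self.radius is not None:
            rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
            r0, c0 = self.center
            sel = (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius**2
        else:
            raise ValidationError("ROI needs either pixels or center+radius")
        if not sel.any():
            raise ValidationError("ROI selects no pixels")
        return sel


def _foreground(stack: ImageStack) -> np.ndarray:
    if stack.mask is not None:
        return stack.mask.astype(bool)
    return np.ones(stack.frame_shape, dtype=bool)


def _per_pixel(
    stack: ImageStack,
    window: AnalysisWindow,
    want_duration: bool,
    smooth_window: int,
    threshold_sd: float,
) -> np.ndarray:
    fg = _foreground(stack)
    out = np.full(stack.frame_shape, np.nan)
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValidationError("stack has no foreground pixels")
    n_fail = 0
    rows, cols = np.nonzero(fg)
    for r, c in zip(rows, cols):
        trace = Trace(values=stack.frames[:, r, c], fps=stack.fps)
        try:
            f = detect_features(trace, window, smooth_window, threshold_sd)
            out[r, c] = (
                duration(trace, f, window) if want_duration else f.activation_time
            )
        except OptomapError:
            n_fail += 1
    if n_fail > 0.5 * n_fg:
        raise MapError(
            f"detection failed on {n_fail}/{n_fg} foreground pixels "
            f"({100 * n_fail / n_fg:.1f}%)"
        )
    return out


def activation_map(
    stack: ImageStack,
    window: AnalysisWindow,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
) -> ScalarMap:
    """Isochronal map: per-pixel activation time, re-zeroed to the earliest.

    Requires a masked, conditioned stack with a single beat inside the
    window. Raises :class:`MapError` if more than half the foreground pixels
    fail detection.
    """
    vals = _per_pixel(stack, window, False, smooth_window, threshold_sd)
    ref = np.nanmin(vals)
    return ScalarMap(
        values=vals - ref, quantity="activation", reference_time=float(ref)
    )


def duration_map(
    stack: ImageStack,
    window: AnalysisWindow,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
) -> ScalarMap:
    """Per-pixel APD/CaD at ``window.percent``; undefined where not reached."""
    vals = _per_pixel(stack, window, True, smooth_window, threshold_sd)
    return ScalarMap(values=vals, quantity="duration", percent=window.percent)


def total_activation_time(map_: ScalarMap) -> float:
    """Range (max - min) of defined activation times, ms."""
    if map_.quantity != "activation":
        raise ValidationError("total activation time needs an activation map")
    if map_.n_defined < 2:
        raise ValidationError("need at least 2 defined pixels")
    vals = map_.values[map_.defined]
    return float(vals.max() - vals.min())


def ensemble_trace(stack: ImageStack, roi: ROI) -> Trace:
    """Per-frame arithmetic mean over the ROI pixels (all must be foreground)."""
    sel = roi.indicator(stack.frame_shape)
    fg = _foreground(stack)
    if not fg[sel].all():
        raise ValidationError("ROI includes background pixels")
    values = stack.frames[:, sel].mean(axis=1)
    return Trace(values=values, fps=stack.fps)


def percent_change(
    before: float, after: float, ndigits: Optional[int] = None
) -> float:
    """Signed percent change 100 * (after - before) / before.

    ``ndigits`` optionally rounds the result (0 = nearest whole percent).
    """
    if before == 0:
        raise ValidationError("percent change undefined for before = 0")
    pct = 100.0 * (after - before) / before
    return round(pct, ndigits) if ndigits is not None else pct
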