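"""Tissue/background segmentation of fluorescence frames.

The mask is computed from the *first* frame of a stack and then applied to
every frame: background pixels are set to zero for the whole recording while
the stack dimensions are preserved. Four algorithms are provided:

``otsu``
    Threshold maximizing between-class variance of the intensity histogram.
    Implemented exactly (exhaustive search over unique-value midpoints), so
    the chosen threshold is the true argmax also for continuous-valued data.
``fraction``
    Keep the brightest ``round(fraction * N)`` pixels, then smooth with
    morphological closing, opening and dilation (square element).
``random_walk``
    Random-walker diffusion labeling from foreground/background seeds; when
    seeds are not supplied they are auto-placed on the brightest/darkest
    deciles of an Otsu pre-labeling.
``mean``
    Global mean-intensity threshold.

Pixels exactly at a threshold are background (strict inequality for
foreground). Ties in the ``fraction`` sort break in raster order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
from skimage.morphology import closing as _closing
from skimage.morphology import dilation as _dilation
from skimage.morphology import opening as _opening
from skimage.segmentation import random_walker

from .errors import DegenerateInputError, ValidationError
from .stack_io import ImageStack

__all__ = [
    "Mask",
    "MorphologyParams",
    "mask_otsu",
    "mask_fraction",
    "mask_random_walk",
    "mask_mean",
    "smooth_mask",
    "apply_mask",
    "auto_seeds",
    "otsu_threshold",
    "save_mask",
    "load_mask",
]

SEED_UNLABELED, SEED_BACKGROUND, SEED_FOREGROUND = 0, 1, 2


@dataclass
class Mask:
    """Per-pixel foreground (tissue) / background labeling of one frame."""

    labels: np.ndarray  # 2-D bool, True = foreground
    method: str
    threshold_used: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 2:
            raise ValidationError("mask labels must be a 2-D boolean array")
        if not self.labels.any():
            raise DegenerateInputError("mask has no foreground pixels")

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class MorphologyParams:
    """Square structuring-element size for closing/opening/dilation."""

    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValidationError(
                f"kernel_size must be odd and >= 1, got {self.kernel_size}"
            )


def _as_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValidationError("expected a single 2-D frame")
    return frame


def otsu_threshold(frame: np.ndarray) -> float:
    """Exact Otsu threshold: maximize between-class variance.

    Candidate thresholds are the midpoints between consecutive distinct
    intensities; the between-class variance w0*w1*(mu0-mu1)^2 is evaluated at
    every candidate via cumulative sums, and the argmax (earliest on ties)
    is returned.
    """
    frame = _as_frame(frame)
    values = np.sort(frame.ravel())
    n = values.size
    distinct = np.unique(values)
    if distinct.size < 2:
        raise DegenerateInputError("constant frame: no threshold separates classes")
    # class 0 = values <= candidate, class 1 = values > candidate
    csum = np.cumsum(values)
    total = csum[-1]
    # index of last element <= each candidate midpoint
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    k = np.searchsorted(values, mids, side="right")  # size of class 0
    w0 = k / n
    w1 = 1.0 - w0
    mu0 = csum[k - 1] / k
    mu1 = (total - csum[k - 1]) / (n - k)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(mids[int(np.argmax(between))])


def mask_otsu(frame: np.ndarray) -> Mask:
    """Foreground = pixels strictly above the exact Otsu threshold."""
    frame = _as_frame(frame)
    thr = otsu_threshold(frame)
    return Mask(labels=frame > thr, method="otsu", threshold_used=thr)


def mask_fraction(
    frame: np.ndarray,
    fraction: float,
    morph: MorphologyParams = MorphologyParams(kernel_size=1),
) -> Mask:
    """Keep the brightest ``round(fraction * N)`` pixels, then smooth.

    Morphological closing, opening and dilation (in that order) with a square
    element of ``morph.kernel_size`` are applied after the intensity cut;
    ``kernel_size=1`` makes them a no-op. Ties in intensity break in raster
    order, so the result is deterministic.
    """
    frame = _as_frame(frame)
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n = frame.size
    k = int(np.floor(fraction * n + 0.5))
    k = max(k, 1)
    order = np.argsort(-frame.ravel(), kind="stable")
    labels = np.zeros(n, dtype=bool)
    labels[order[:k]] = True
    labels = labels.reshape(frame.shape)
    labels = _morph_smooth(labels, morph)
    # threshold_used: dimmest intensity included before morphology
    thr = float(frame.ravel()[order[k - 1]])
    return Mask(labels=labels, method="fraction", threshold_used=thr)


def mask_mean(frame: np.ndarray) -> Mask:
    """Foreground = pixels strictly above the global mean intensity."""
    frame = _as_frame(frame)
    if np.unique(frame).size < 2:
        raise DegenerateInputError("constant frame: mean threshold is degenerate")
    thr = float(frame.mean())
    return Mask(labels=frame > thr, method="mean", threshold_used=thr)


def auto_seeds(frame: np.ndarray) -> np.ndarray:
    """Auto-place random-walker seeds from an Otsu pre-labeling.

    The brightest decile of the Otsu foreground class is seeded foreground;
    the darkest decile of the background class is seeded background.
    """
    frame = _as_frame(frame)
    thr = otsu_threshold(frame)
    seeds = np.full(frame.shape, SEED_UNLABELED, dtype=np.int32)
    fg = frame > thr
    bg = ~fg
    if fg.any():
        q = np.quantile(frame[fg], 0.9)
        seeds[fg & (frame >= q)] = SEED_FOREGROUND
    if bg.any():
        q = np.quantile(frame[bg], 0.1)
        seeds[bg & (frame <= q)] = SEED_BACKGROUND
    return seeds


def mask_random_walk(
    frame: np.ndarray,
    seeds: Optional[np.ndarray] = None,
    beta: float = 130.0,
) -> Mask:
    """Random-walker segmentation from labeled seed pixels.

    Each unlabeled pixel receives the label (foreground or background) it has
    the highest probability of reaching first under intensity-weighted
    diffusion; seeds keep their labels. ``beta`` controls the edge-weight
    sharpness of the diffusion.
    """
    frame = _as_frame(frame)
    if seeds is None:
        seeds = auto_seeds(frame)
    seeds = np.asarray(seeds)
    if seeds.shape != frame.shape:
        raise ValidationError("seed array shape must match the frame")
    has_bg = (seeds == SEED_BACKGROUND).any()
    has_fg = (seeds == SEED_FOREGROUND).any()
    if not (has_bg and has_fg):
        raise ValidationError(
            "random-walker seeds must include at least one background (1) "
            "and one foreground (2) pixel"
        )
    if not (seeds == SEED_UNLABELED).any():
        labels = seeds == SEED_FOREGROUND
    else:
        # rescale intensities so beta acts on a normalized contrast scale
        lo, hi = frame.min(), frame.max()
        img = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
        out = random_walker(img, seeds.astype(np.int32), beta=beta, mode="bf")
        labels = out == SEED_FOREGROUND
    return Mask(labels=labels, method="random_walk", threshold_used=None)


def _morph_smooth(labels: np.ndarray, morph: MorphologyParams) -> np.ndarray:
    if morph.kernel_size == 1:
        return labels
    footprint = np.ones((morph.kernel_size, morph.kernel_size), dtype=bool)
    labels = _closing(labels, footprint)
    labels = _opening(labels, footprint)
    labels = _dilation(labels, footprint)
    return labels.astype(bool)


def smooth_mask(mask: Mask, morph: MorphologyParams) -> Mask:
    """Apply closing -> opening -> dilation smoothing to any mask."""
    return Mask(
        labels=_morph_smooth(mask.labels, morph),
        method=mask.method,
        threshold_used=mask.threshold_used,
    )


def apply_mask(stack: ImageStack, mask: Mask) -> ImageStack:
    """Zero background pixels in every frame; record the mask on the stack.

    Idempotent; downstream analysis treats zeroed background as "no data".
    """
    if mask.labels.shape != stack.frame_shape:
        raise ValidationError(
            f"mask shape {mask.labels.shape} does not match frame shape "
            f"{stack.frame_shape}"
        )
    frames = stack.frames * mask.labels[np.newaxis, :, :]
    from dataclasses import replace

    return replace(stack, frames=frames, mask=mask.labels.copy())


def save_mask(mask: Mask, path: Union[str, Path]) -> Path:
    """Write a mask as 8-bit TIFF (0/255) or CSV of 0/1, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, mask.labels.astype(int), fmt="%d", delimiter=",")
    else:
        tifffile.imwrite(str(path), (mask.labels.astype(np.uint8) * 255))
    return path


def load_mask(path: Union[str, Path]) -> Mask:
    """Read a mask written by :func:`save_mask`."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        labels = np.loadtxt(path, delimiter=",") > 0
    else:
        labels = tifffile.imread(str(path)) > 0
    return Mask(labels=labels, method="loaded", threshold_used=None)
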