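"""Image-stack input/output and geometric/polarity preprocessing.

An :class:`ImageStack` is the pipeline's central carrier: a time-ordered
series of 2-D fluorescence frames in arbitrary units (AUF), plus the
acquisition properties the user declares at import time — frame rate (fps),
spatial scale (px/cm) and signal kind (voltage or calcium). Voltage dyes
commonly produce *downward* deflections, so polarity inversion about each
pixel's central value is provided to bring all signals upright before
analysis.

Conventions: coordinates are 0-based, row-major, origin top-left; crop
rectangles are half-open; only lossless quarter-turn rotations are supported.
Frame timing derives solely from the declared fps — TIFF timing metadata is
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "ImageStack",
    "CropRect",
    "load_stack",
    "save_stack",
    "crop",
    "rotate_quarter",
    "invert_polarity",
]

SIGNAL_KINDS = ("voltage", "calcium")


@dataclass
class ImageStack:
    """A time-ordered stack of grayscale frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Fluorescence intensities in arbitrary units (AUF), floating dtype.
    fps : float
        Acquisition frame rate in frames per second; must be positive.
    scale : float, optional
        Spatial scale in pixels per cm.
    signal_kind : {"voltage", "calcium"}
    inverted : bool
        Whether polarity inversion has been applied to the data.
    mask : ndarray of bool, optional
        Foreground labeling recorded by ``segmentation.apply_mask``;
        ``None`` until a mask has been applied.
    """

    frames: np.ndarray
    fps: float
    scale: Optional[float] = None
    signal_kind: str = "voltage"
    inverted: bool = False
    mask: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError(
                f"frames must be a (n_frames, height, width) array with at "
                f"least one frame, got shape {self.frames.shape}"
            )
        if np.issubdtype(self.frames.dtype, np.integer):
            self.frames = self.frames.astype(np.float32)
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("frame intensities must all be finite")
        if not self.fps > 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.scale is not None and not self.scale > 0:
            raise ValidationError(f"scale must be > 0 px/cm, got {self.scale}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValidationError(
                f"signal_kind must be one of {SIGNAL_KINDS}, got "
                f"{self.signal_kind!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def frame_interval_ms(self) -> float:
        """Time between consecutive frames, ms (1000 / fps)."""
        return 1000.0 / self.fps

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times of each frame in ms, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_ms

    def pixel_trace(self, row: int, col: int):
        """Return the time series of one pixel as a :class:`~optomap.conditioning.Trace`."""
        from .conditioning import Trace

        return Trace(values=self.frames[:, row, col].copy(), fps=self.fps)


@dataclass(frozen=True)
class CropRect:
    """Half-open crop rectangle [row0, row0+height) x [col0, col0+width)."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError("crop origin must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValidationError("crop extent must be at least 1x1")


def load_stack(
    path: Union[str, Path],
    fps: float,
    scale: Optional[float] = None,
    signal_kind: str = "voltage",
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Integer pixel types are widened to floating point without rescaling, so
    intensities remain in the camera's native arbitrary units.
    """
    if not fps > 0:
        raise ValidationError(f"fps must be > 0, got {fps}")
    try:
        with tifffile.TiffFile(str(path)) as tif:
            photometric = tif.pages[0].photometric
            frames = tif.asarray()
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path!s}: {exc}") from exc
    if photometric not in (
        tifffile.PHOTOMETRIC.MINISBLACK,
        tifffile.PHOTOMETRIC.MINISWHITE,
    ):
        raise FormatError(
            f"{path!s}: only grayscale TIFFs are supported "
            f"(photometric={photometric!r})"
        )
    frames = np.asarray(frames)
    if frames.dtype == object:
        raise FormatError(f"{path!s}: pages have mixed sizes")
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3:
        raise FormatError(
            f"{path!s}: expected grayscale pages, got array of shape "
            f"{frames.shape} (RGB/multichannel TIFFs are not supported)"
        )
    if np.issubdtype(frames.dtype, np.integer):
        frames = frames.astype(np.float32)
    elif not np.issubdtype(frames.dtype, np.floating):
        raise FormatError(f"{path!s}: unsupported pixel dtype {frames.dtype}")
    return ImageStack(frames=frames, fps=fps, scale=scale, signal_kind=signal_kind)


def save_stack(stack: ImageStack, path: Union[str, Path]) -> Path:
    """Write the stack as a multi-page TIFF (lossless; floats kept as-is)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"destination directory does not exist: {path.parent}")
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")
    return path


def crop(stack: ImageStack, rect: CropRect) -> ImageStack:
    """Restrict every frame to ``rect``; metadata is unchanged."""
    n, h, w = stack.frames.shape
    if rect.row0 + rect.height > h or rect.col0 + rect.width > w:
        raise ValidationError(
            f"crop rect {rect} exceeds frame bounds {h}x{w}"
        )
    sub = stack.frames[
        :, rect.row0 : rect.row0 + rect.height, rect.col0 : rect.col0 + rect.width
    ].copy()
    mask = stack.mask
    if mask is not None:
        mask = mask[
            rect.row0 : rect.row0 + rect.height, rect.col0 : rect.col0 + rect.width
        ].copy()
    return replace(stack, frames=sub, mask=mask)


def rotate_quarter(stack: ImageStack, turns: int) -> ImageStack:
    """Rotate all frames by ``turns`` quarter turns (counter-clockwise)."""
    turns = int(turns) % 4
    rot = np.rot90(stack.frames, k=turns, axes=(1, 2)).copy()
    mask = stack.mask
    if mask is not None:
        mask = np.rot90(mask, k=turns).copy()
    return replace(stack, frames=rot, mask=mask)


def invert_polarity(stack_or_trace):
    """Invert signal polarity about each pixel's central value.

    Each pixel's time series ``x`` maps to ``min(x) + max(x) - x``, computed
    per pixel over the full duration, so upward and downward deflections are
    swapped without changing the per-pixel amplitude. The operation is an
    involution. The central value is per-pixel (not global), so heterogeneous
    illumination cannot clip signals.
    """
    from .conditioning import Trace

    if isinstance(stack_or_trace, Trace):
        x = stack_or_trace.values
        flipped = x.min() + x.max() - x
        return replace(stack_or_trace, values=flipped)
    stack = stack_or_trace
    lo = stack.frames.min(axis=0, keepdims=True)
    hi = stack.frames.max(axis=0, keepdims=True)
    return replace(
        stack, frames=lo + hi - stack.frames, inverted=not stack.inverted
    )
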