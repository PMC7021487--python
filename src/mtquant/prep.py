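"""Timelapse preprocessing: bleach correction, despeckling, segmentation.

These are the standard FIJI-style steps applied to photoconversion
timelapses before pixel counting: each frame is rescaled so its total
(optionally cell-masked) intensity matches frame 0, salt-and-pepper noise is
removed with a 3×3 median, and the converted-tubulin signal is binarized
with a threshold that is *fixed from frame 0* by default so that the
criterion does not drift as signal spreads and dilutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "Movie",
    "MaskStack",
    "DegenerateFrameError",
    "bleach_correct",
    "despeckle",
    "despeckle_movie",
    "segment_converted",
]


class DegenerateFrameError(ValueError):
    """A frame cannot be processed (zero intensity or flat histogram)."""


@dataclass
class Movie:
    """A single-channel timelapse with physical calibration.

    stack : (T, Y, X) non-negative intensities
    pixel_size : µm per pixel
    frame_interval : minutes per frame
    cell_mask : optional (Y, X) boolean restricting intensity bookkeeping
    """

    stack: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0
    cell_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[0] < 2:
            raise ValueError("stack must be T×Y×X with T >= 2")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
            if self.cell_mask.shape != self.stack.shape[1:]:
                raise ValueError("cell_mask must match frame shape Y×X")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class MaskStack:
    """Binary masks per frame plus a record of how each was thresholded."""

    masks: np.ndarray                    # (T, Y, X) bool
    source: list[dict] = field(default_factory=list)  # per-frame method record

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be T×Y×X")


def _masked_sum(frame: np.ndarray, cell_mask: Optional[np.ndarray]) -> float:
    return float(frame[cell_mask].sum() if cell_mask is not None
                 else frame.sum())


def bleach_correct(movie: Movie) -> Movie:
    """Simple-ratio bleach correction: scale frame t by S0/St.

    St is the summed intensity within the cell mask (whole frame when no
    mask is set) at frame t.  After correction every frame's masked sum
    equals S0, which removes exponential photobleaching exactly and is
    idempotent.
    """
    sums = np.array([_masked_sum(f, movie.cell_mask) for f in movie.stack])
    if sums[0] <= 0:
        raise DegenerateFrameError("frame 0 has zero total intensity")
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise DegenerateFrameError(
            f"frame {int(zero[0])} has zero total intensity; cannot correct")
    corrected = movie.stack * (sums[0] / sums)[:, None, None]
    return replace(movie, stack=corrected)


def despeckle(frame: np.ndarray) -> np.ndarray:
    """3×3 median filter (FIJI 'despeckle'), borders handled by replication."""
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("despeckle expects a single 2D frame")
    return ndi.median_filter(frame, size=3, mode="nearest")


def despeckle_movie(movie: Movie) -> Movie:
    """Apply :func:`despeckle` to every frame."""
    return replace(movie,
                   stack=np.stack([despeckle(f) for f in movie.stack]))


def _otsu(frame: np.ndarray) -> float:
    if float(frame.max()) == float(frame.min()):
        raise DegenerateFrameError(
            "degenerate histogram: frame has zero intensity range")
    return float(threshold_otsu(frame))


def segment_converted(
    movie: Movie,
    method: str = "otsu_frame0",
    *,
    value: Optional[float] = None,
    sigma: float = 1.0,
    cutoff: float = 0.5,
) -> MaskStack:
    """Binarize the converted-tubulin signal of every frame.

    Methods
    -------
    otsu_frame0 (default)
        Otsu threshold computed on frame 0 and applied to all frames, so the
        criterion stays fixed as signal spreads out of the conversion zone.
    otsu_global
        Otsu threshold on the pooled histogram of the whole stack.
    fixed
        User-supplied threshold ``value``.
    smooth_prob
        Per-frame Gaussian smoothing (``sigma``) followed by min–max
        rescaling to a pseudo-probability map in [0, 1], thresholded at
        ``cutoff``.  A deterministic replacement for trained pixel
        classifiers that produce probability maps.
    """
    stack = movie.stack
    source: list[dict] = []
    if method == "otsu_frame0":
        thr = _otsu(stack[0])
        masks = stack > thr
        source = [{"method": method, "threshold": thr}] * movie.n_frames
    elif method == "otsu_global":
        thr = _otsu(stack.reshape(-1))
        masks = stack > thr
        source = [{"method": method, "threshold": thr}] * movie.n_frames
    elif method == "fixed":
        if value is None:
            raise ValueError("method 'fixed' requires value=")
        masks = stack > float(value)
        source = [{"method": method, "threshold": float(value)}] * movie.n_frames
    elif method == "smooth_prob":
        masks = np.empty_like(stack, dtype=bool)
        for t, frame in enumerate(stack):
            sm = ndi.gaussian_filter(frame, sigma)
            rng_ = float(sm.max()) - float(sm.min())
            if rng_ == 0:
                raise DegenerateFrameError(
                    f"degenerate histogram: frame {t} has zero intensity range")
            prob = (sm - sm.min()) / rng_
            masks[t] = prob >= cutoff
            source.append({"method": method, "threshold": cutoff,
                           "sigma": sigma})
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return MaskStack(masks=np.asarray(masks, dtype=bool), source=list(source))
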