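"""Stack cleaning: outlier removal, background subtraction, alignment, crop.

The cleaning order is median filter → background subtraction → alignment.
All operations return new stacks; inputs are never modified in place.
Negative values produced by subtraction are clamped to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from ratioimg.core_io import ImageStack, Region

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "median_filter_3x3",
    "subtract_background",
    "subtract_background_image",
    "align_stack",
    "apply_shifts",
    "crop",
]


@dataclass
class AlignmentResult:
    """Per-frame translation estimates, in pixels.

    ``shifts[t] = (dx, dy)`` is the translation applied to frame ``t`` to
    register it onto the reference frame; the reference frame's shift is
    ``(0, 0)``.
    """

    shifts: list[tuple[float, float]]
    reference_frame: int = 0


def median_filter_3x3(stack: ImageStack) -> ImageStack:
    """3×3 median filter applied independently to every frame.

    Borders use edge replication, so a constant frame stays constant.
    """
    out = np.empty_like(stack.frames)
    for t in range(stack.n_frames):
        out[t] = ndi.median_filter(stack.frames[t], size=3, mode="nearest")
    return ImageStack(out, dtype_in=stack.dtype_in)


def subtract_background(stack: ImageStack, background: Region) -> ImageStack:
    """Subtract each frame's background-region median from that frame.

    The median is measured per frame (the background level can fluctuate
    between images); results below zero are clamped to 0. Returns the
    corrected stack; per-frame medians are logged at INFO.
    """
    mask = background.rasterize(stack.frame_shape)
    out = np.empty_like(stack.frames)
    medians = []
    for t in range(stack.n_frames):
        med = float(np.median(stack.frames[t][mask]))
        medians.append(med)
        out[t] = np.clip(stack.frames[t] - med, 0.0, None)
    logger.info("background medians per frame: %s", [f"{m:.3f}" for m in medians])
    return ImageStack(out, dtype_in=stack.dtype_in)


def subtract_background_image(stack: ImageStack, background_image: ImageStack) -> ImageStack:
    """Subtract a background image pixel-wise (clamped at 0).

    The background image must have one frame (broadcast to all) or exactly
    the stack's frame count, with the same (y, x) shape.
    """
    bg = background_image.frames
    if bg.shape[1:] != stack.frames.shape[1:]:
        raise ValueError(
            f"background frame shape {bg.shape[1:]} != stack frame shape {stack.frames.shape[1:]}"
        )
    if bg.shape[0] == 1:
        out = stack.frames - bg[0]
    elif bg.shape[0] == stack.n_frames:
        out = stack.frames - bg
    else:
        raise ValueError(
            f"background image has {bg.shape[0]} frames; expected 1 or {stack.n_frames}"
        )
    return ImageStack(np.clip(out, 0.0, None), dtype_in=stack.dtype_in)


def _estimate_shift(reference: np.ndarray, moving: np.ndarray, upsample: int) -> tuple[float, float]:
    """Translation (dy, dx) that registers ``moving`` onto ``reference``."""
    shift, _error, _phase = phase_cross_correlation(
        reference, moving, upsample_factor=upsample, normalization=None
    )
    return float(shift[0]), float(shift[1])


def apply_shifts(stack: ImageStack, result: AlignmentResult) -> ImageStack:
    """Warp each frame by its (dx, dy) with bilinear interpolation, zeros in."""
    out = np.empty_like(stack.frames)
    for t, (dx, dy) in enumerate(result.shifts):
        if dx == 0.0 and dy == 0.0:
            out[t] = stack.frames[t]
        else:
            out[t] = ndi.shift(stack.frames[t], (dy, dx), order=1, mode="constant", cval=0.0)
    return ImageStack(np.clip(out, 0.0, None), dtype_in=stack.dtype_in)


def align_stack(
    donor: ImageStack,
    acceptor: ImageStack,
    reference_frame: int = 0,
    upsample: int = 100,
) -> tuple[ImageStack, ImageStack, AlignmentResult]:
    """Rescue xy drift over the time series.

    Per-frame subpixel translations are estimated on the donor against the
    reference frame with upsampled cross-correlation and the same transform
    is applied to both channels (bilinear, zeros shifted in), so the
    donor/acceptor spatial correspondence is preserved.
    """
    if donor.shape != acceptor.shape:
        raise ValueError(f"donor shape {donor.shape} != acceptor shape {acceptor.shape}")
    if not (0 <= reference_frame < donor.n_frames):
        raise ValueError(f"reference_frame {reference_frame} out of range [0, {donor.n_frames})")
    ref = donor.frames[reference_frame]
    h, w = donor.frame_shape
    shifts: list[tuple[float, float]] = []
    for t in range(donor.n_frames):
        if t == reference_frame:
            shifts.append((0.0, 0.0))
            continue
        frame = donor.frames[t]
        if not frame.any() or not ref.any():
            logger.warning("frame %d: degenerate (all-zero) image; shift set to (0, 0)", t)
            shifts.append((0.0, 0.0))
            continue
        dy, dx = _estimate_shift(ref, frame, upsample)
        if abs(dx) >= w / 2 or abs(dy) >= h / 2:
            logger.warning(
                "frame %d: implausible shift (%.2f, %.2f); set to (0, 0)", t, dx, dy
            )
            shifts.append((0.0, 0.0))
            continue
        shifts.append((dx, dy))
    result = AlignmentResult(shifts=shifts, reference_frame=reference_frame)
    logger.info("alignment shifts (dx, dy): %s", [(f"{dx:.3f}", f"{dy:.3f}") for dx, dy in shifts])
    return apply_shifts(donor, result), apply_shifts(acceptor, result), result


def crop(stack: ImageStack, region: Region) -> ImageStack:
    """Extract the rectangle's half-open pixel range from every frame."""
    if region.kind != "rectangle":
        raise ValueError(f"crop requires a rectangle region, got {region.kind!r}")
    h, w = stack.frame_shape
    x0, y0, x1, y1 = region.bounds()
    cx0 = max(int(np.ceil(x0)), 0)
    cy0 = max(int(np.ceil(y0)), 0)
    cx1 = min(int(np.ceil(x1)), w)
    cy1 = min(int(np.ceil(y1)), h)
    if cx1 <= cx0 or cy1 <= cy0:
        raise ValueError(f"crop region {region.name!r} does not intersect the frame")
    return ImageStack(stack.frames[:, cy0:cy1, cx0:cx1].copy(), dtype_in=stack.dtype_in)
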