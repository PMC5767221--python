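"""Masked A/D division, display-range selection, pseudocolor rendering.

Zero is reserved as the background sentinel in ratio images: it marks
pixels removed by the donor mask and is rendered black, distinguishing
"no specimen" from "low ratio".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ratioimg.core_io import ImageStack, RatioStack

__all__ = [
    "DisplayRange",
    "DEFAULT_LUT16",
    "ratio_divide",
    "nearest_rank_permille",
    "display_range",
    "render_pseudocolor",
    "render_weighted",
    "stack_histogram",
]


@dataclass
class DisplayRange:
    """Bounds between which the pseudocolors are distributed (ratio units)."""

    low: float
    high: float
    low_permille: int = 5
    high_permille: int = 995

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low ({self.low}) must be <= high ({self.high})")
        if not (0 <= self.low_permille < self.high_permille <= 1000):
            raise ValueError(
                f"permilles must satisfy 0 <= low < high <= 1000, "
                f"got ({self.low_permille}, {self.high_permille})"
            )


# 16-step cold→hot ramp: blue → cyan → green → yellow → red.
DEFAULT_LUT16: tuple[tuple[int, int, int], ...] = (
    (0, 0, 255),
    (0, 68, 255),
    (0, 136, 255),
    (0, 204, 255),
    (0, 255, 238),
    (0, 255, 170),
    (0, 255, 102),
    (0, 255, 34),
    (34, 255, 0),
    (102, 255, 0),
    (170, 255, 0),
    (238, 255, 0),
    (255, 204, 0),
    (255, 136, 0),
    (255, 68, 0),
    (255, 0, 0),
)


def _check_lut(lut) -> np.ndarray:
    lut = np.asarray(lut, dtype=np.float64)
    if lut.shape != (16, 3):
        raise ValueError(f"LUT must be 16 RGB triples, got shape {lut.shape}")
    return lut


def ratio_divide(acceptor: ImageStack, donor_thresholded: ImageStack) -> RatioStack:
    """Pixel-by-pixel A/D, defined as exactly 0 wherever the donor is 0.

    The donor is expected to be masked already (zeros outside the
    specimen); those pixels would otherwise send the ratio to infinity.
    The result never contains infinities or NaNs.
    """
    if acceptor.shape != donor_thresholded.shape:
        raise ValueError(
            f"acceptor shape {acceptor.shape} != donor shape {donor_thresholded.shape}"
        )
    d = donor_thresholded.frames
    a = acceptor.frames
    out = np.zeros_like(d)
    np.divide(a, d, out=out, where=d > 0)
    out = np.clip(out, 0.0, None)  # negative A cannot occur post-clean, but be safe
    return RatioStack(out)


def nearest_rank_permille(values: np.ndarray, permille: int) -> float:
    """Nearest-rank k/1000 quantile: 1-based index ceil(k·n/1000) of sorted values."""
    values = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = values.size
    if n == 0:
        raise ValueError("no values to take a quantile of")
    idx = max(1, math.ceil(permille * n / 1000))
    return float(values[min(idx, n) - 1])


def _nonzero_values(frames: np.ndarray) -> np.ndarray:
    vals = frames.ravel()
    return vals[vals != 0]


def display_range(
    ratio: RatioStack, low_permille: int = 5, high_permille: int = 995
) -> DisplayRange:
    """Display bounds from the stack histogram, ignoring zero pixels.

    Pools the nonzero pixels of all frames and takes the nearest-rank
    permille quantiles, so adding any number of masked (zero) pixels leaves
    the range unchanged.
    """
    vals = _nonzero_values(ratio.frames)
    if vals.size == 0:
        raise ValueError("ratio stack has no nonzero pixels")
    low = nearest_rank_permille(vals, low_permille)
    high = nearest_rank_permille(vals, high_permille)
    return DisplayRange(low=low, high=high, low_permille=low_permille, high_permille=high_permille)


def _bin_indices(frame: np.ndarray, drange: DisplayRange) -> np.ndarray:
    span = drange.high - drange.low
    if span <= 0:
        raise ValueError("display range must satisfy low < high for rendering")
    bins = np.floor(16.0 * (frame - drange.low) / span)
    return np.clip(bins, 0, 15).astype(np.intp)


def render_pseudocolor(
    ratio_frame: np.ndarray, drange: DisplayRange, lut=DEFAULT_LUT16
) -> np.ndarray:
    """Render one ratio frame as an 8-bit RGB image.

    Nonzero pixel v maps to LUT bin ``floor(16·(v−low)/(high−low))`` clamped
    to [0, 15]; zero (background) pixels are black. Binning is unchanged if
    ratio, low and high are all scaled by the same positive constant.
    """
    lut = _check_lut(lut)
    ratio_frame = np.asarray(ratio_frame, dtype=np.float64)
    rgb = lut[_bin_indices(ratio_frame, drange)]
    rgb[ratio_frame == 0] = 0
    return np.rint(rgb).astype(np.uint8)


def render_weighted(
    ratio_frame: np.ndarray,
    donor_frame: np.ndarray,
    drange: DisplayRange,
    lut=DEFAULT_LUT16,
) -> np.ndarray:
    """Pseudocolor render with per-pixel brightness ∝ donor intensity.

    The brightness scale is donor / donor_display_max clamped to [0, 1],
    where donor_display_max is the 995th permille of the frame's nonzero
    donor pixels. Hides noise, but fades signal from low-expression areas.
    """
    lut = _check_lut(lut)
    ratio_frame = np.asarray(ratio_frame, dtype=np.float64)
    donor_frame = np.asarray(donor_frame, dtype=np.float64)
    if ratio_frame.shape != donor_frame.shape:
        raise ValueError(f"shape mismatch: ratio {ratio_frame.shape} vs donor {donor_frame.shape}")
    nz = _nonzero_values(donor_frame)
    if nz.size == 0:
        return np.zeros(ratio_frame.shape + (3,), dtype=np.uint8)
    dmax = nearest_rank_permille(nz, 995)
    scale = np.clip(donor_frame / dmax, 0.0, 1.0) if dmax > 0 else np.zeros_like(donor_frame)
    rgb = lut[_bin_indices(ratio_frame, drange)] * scale[..., np.newaxis]
    rgb[ratio_frame == 0] = 0
    return np.rint(rgb).astype(np.uint8)


def stack_histogram(
    ratio: RatioStack,
    bins: int = 64,
    low_permille: int = 5,
    high_permille: int = 995,
) -> pd.DataFrame:
    """Histogram of nonzero ratio pixels pooled over all frames.

    Bins span the nearest-rank permille bounds with half-open edges (top bin
    closed). Returns a table with ``bin_left``, ``bin_right``, ``count``.
    """
    vals = _nonzero_values(ratio.frames)
    if vals.size == 0:
        raise ValueError("ratio stack has no nonzero pixels")
    drange = display_range(ratio, low_permille, high_permille)
    lo, hi = drange.low, drange.high
    if lo == hi:
        hi = lo + 1e-12
    in_range = vals[(vals >= lo) & (vals <= hi)]
    counts, edges = np.histogram(in_range, bins=bins, range=(lo, hi))
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
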