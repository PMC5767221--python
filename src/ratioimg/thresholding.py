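"""Donor masking: global, local, and composite threshold methods.

All methods share one "keep" convention: a pixel survives iff its value is
strictly greater than the threshold. Masks are binary {0, 1}; multiplying a
mask with the original image zeroes irrelevant pixels without altering the
values of surviving ones.

Histogram methods (Otsu, Li) operate on a 256-bin histogram spanning each
frame's own [min, max]; they are implemented here directly (not delegated
to scikit-image) so the test oracles — naive exhaustive scans of the same
criteria — remain an independent path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from ratioimg.core_io import ImageStack, MaskStack, Region

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "threshold_constant",
    "threshold_median_roi",
    "threshold_otsu",
    "threshold_li",
    "li_fixed_point",
    "threshold_phansalkar",
    "threshold_chastagnier",
    "apply_mask",
    "make_mask_stack",
    "disk_footprint",
]

N_BINS = 256

PHANSALKAR_DEFAULTS = {"radius": 15, "k": 0.25, "r": 0.5, "p": 2.0, "q": 10.0}
# Tuned on the default decaying-neuron phantom: small enough that the soma
# interior cancels out of both difference images (its rim is recovered by the
# OR-with-Otsu), large enough that thin neurites survive the blur subtraction.
CHASTAGNIER_DEFAULTS = {"sigma_low": 2.0, "sigma_high": 5.0}


@dataclass
class ThresholdConfig:
    """Which mask method to run, and with which parameters."""

    method: str = "chastagnier"  # constant | median_roi | otsu | phansalkar | chastagnier
    constant_value: float = 0.0
    reference_region: Region | None = None
    radius: int = PHANSALKAR_DEFAULTS["radius"]
    k: float = PHANSALKAR_DEFAULTS["k"]
    r: float = PHANSALKAR_DEFAULTS["r"]
    p: float = PHANSALKAR_DEFAULTS["p"]
    q: float = PHANSALKAR_DEFAULTS["q"]
    sigma_low: float = CHASTAGNIER_DEFAULTS["sigma_low"]
    sigma_high: float = CHASTAGNIER_DEFAULTS["sigma_high"]

    def __post_init__(self) -> None:
        valid = ("constant", "median_roi", "otsu", "phansalkar", "chastagnier")
        if self.method not in valid:
            raise ValueError(f"unknown threshold method {self.method!r}; expected one of {valid}")
        if self.sigma_low >= self.sigma_high:
            raise ValueError(f"sigma_low ({self.sigma_low}) must be < sigma_high ({self.sigma_high})")
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.constant_value < 0:
            raise ValueError(f"constant_value must be >= 0, got {self.constant_value}")
        if self.method == "median_roi" and self.reference_region is None:
            raise ValueError("method 'median_roi' requires a reference_region")


# ---------------------------------------------------------------------------
# histogram machinery shared by Otsu and Li


def _frame_histogram(
    frame: np.ndarray, n_bins: int = N_BINS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram over the frame's own [min, max].

    Returns per-bin pixel counts, per-bin sums of the raw pixel values
    (exact first moments, so e.g. a spike of zeros carries zero moment),
    and the bin centers.
    """
    lo, hi = float(frame.min()), float(frame.max())
    vals = frame.ravel()
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    sums, _ = np.histogram(vals, bins=n_bins, range=(lo, hi), weights=vals)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(np.float64), sums.astype(np.float64), centers


def _empty_mask(frame: np.ndarray, reason: str) -> np.ndarray:
    logger.warning("%s; returning empty mask", reason)
    return np.zeros(frame.shape, dtype=np.uint8)


# ---------------------------------------------------------------------------
# global thresholds


def threshold_constant(stack: ImageStack, value: float) -> MaskStack:
    """Same static threshold for every frame: keep pixels strictly above it."""
    if value < 0:
        raise ValueError(f"threshold value must be >= 0, got {value}")
    return MaskStack((stack.frames > value).astype(np.uint8))


def threshold_median_roi(stack: ImageStack, reference: Region) -> MaskStack:
    """Per-frame threshold = median of the reference region in that frame.

    The reference area should contain roughly half pixels to keep and half
    to remove; its median then tracks the specimen/background boundary as
    global intensity decays over the time series.
    """
    roi = reference.rasterize(stack.frame_shape)
    masks = np.empty(stack.shape, dtype=np.uint8)
    thresholds = []
    for t in range(stack.n_frames):
        thr = float(np.median(stack.frames[t][roi]))
        thresholds.append(thr)
        masks[t] = stack.frames[t] > thr
    logger.info("median-ROI thresholds per frame: %s", [f"{v:.3f}" for v in thresholds])
    return MaskStack(masks)


def threshold_otsu(frame: np.ndarray, n_bins: int = N_BINS) -> tuple[float, np.ndarray]:
    """Global Otsu threshold for one frame.

    Chooses, over an ``n_bins``-bin histogram, the split minimizing the
    within-class (equivalently maximizing the between-class) variance.
    Returns ``(threshold, mask)`` with ``mask = frame > threshold``.
    A constant frame yields an empty mask with a warning.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() == frame.max():
        return float(frame.min()), _empty_mask(frame, "Otsu on a constant frame")
    counts, _sums, centers = _frame_histogram(frame, n_bins)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * centers)
    mu0 = np.where(w0 > 0, m0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (m0[-1] - m0) / np.where(w1 > 0, w1, 1), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # candidate k splits classes at bin k (inclusive below); last split is void
    between[-1] = -np.inf
    k = int(np.argmax(between))
    threshold = float(centers[k])
    return threshold, (frame > threshold).astype(np.uint8)


def _li_criterion(counts: np.ndarray, sums: np.ndarray) -> np.ndarray:
    """Li & Lee cross-entropy for every candidate split of a histogram.

    Candidate ``k`` puts bins ``0..k`` below and ``k+1..`` above; class
    moments come from the exact per-bin value sums, so pixels at 0 (a large
    clamped-background spike in difference images) carry no moment — the
    behavior of the classic integer-histogram implementations. Splits with
    an empty class or a non-positive class mean are invalid (+inf).
    """
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(sums)
    m1 = m0[-1] - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = m1 / w1
        crit = -(m0 * np.log(mu0) + m1 * np.log(mu1))
    crit = np.where((w0 > 0) & (w1 > 0) & (mu0 > 0) & (mu1 > 0), crit, np.inf)
    return crit


def threshold_li(frame: np.ndarray, n_bins: int = N_BINS) -> tuple[float, np.ndarray]:
    """Minimum-cross-entropy (Li) threshold for one nonnegative frame.

    The global minimizer of the cross-entropy criterion is found by an
    exhaustive scan of all ``n_bins`` candidate splits of the frame's
    histogram; :func:`li_fixed_point` provides the classic iterative scheme,
    which converges to the same split on well-behaved images.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if (frame < 0).any():
        raise ValueError("Li threshold requires nonnegative intensities")
    if frame.min() == frame.max():
        return float(frame.min()), _empty_mask(frame, "Li on a constant frame")
    counts, sums, centers = _frame_histogram(frame, n_bins)
    crit = _li_criterion(counts, sums)
    if not np.isfinite(crit).any():
        return float(frame.min()), _empty_mask(frame, "Li criterion undefined for all splits")
    k = int(np.argmin(crit))
    threshold = float(centers[k])
    return threshold, (frame > threshold).astype(np.uint8)


def li_fixed_point(
    frame: np.ndarray, tol_bins: float = 0.5, max_iter: int = 100
) -> tuple[float, int]:
    """Classic Li fixed-point iteration on the raw pixel values.

    Iterates ``t ← (μ_below − μ_above) / (ln μ_below − ln μ_above)`` from the
    frame mean until successive thresholds differ by less than ``tol_bins``
    histogram bins. Returns ``(threshold, n_iterations)``.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = float(frame.min()), float(frame.max())
    if lo == hi:
        return lo, 0
    tol = tol_bins * (hi - lo) / N_BINS
    eps = np.finfo(float).eps
    t = float(frame.mean())
    for it in range(1, max_iter + 1):
        below = frame[frame <= t]
        above = frame[frame > t]
        mu0 = below.mean() if below.size else eps
        mu1 = above.mean() if above.size else eps
        mu0 = max(mu0, eps)
        mu1 = max(mu1, eps)
        if mu0 == mu1:
            return t, it
        t_new = (mu0 - mu1) / (np.log(mu0) - np.log(mu1))
        if abs(t_new - t) < tol:
            return float(t_new), it
        t = float(t_new)
    return t, max_iter


# ---------------------------------------------------------------------------
# local thresholds


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean circular footprint of the given pixel radius."""
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def threshold_phansalkar(
    frame: np.ndarray,
    radius: int = PHANSALKAR_DEFAULTS["radius"],
    k: float = PHANSALKAR_DEFAULTS["k"],
    r: float = PHANSALKAR_DEFAULTS["r"],
    p: float = PHANSALKAR_DEFAULTS["p"],
    q: float = PHANSALKAR_DEFAULTS["q"],
) -> np.ndarray:
    """Phansalkar local threshold mask.

    With μ and σ the mean and standard deviation of the circular window of
    the given radius around each pixel (intensities normalized to [0, 1] by
    the frame max; reflective borders), the local threshold is

        t = μ · (1 + p·exp(−q·μ) + k·(σ/r − 1))

    and a pixel is kept iff its normalized value is strictly greater than t.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    frame = np.asarray(frame, dtype=np.float64)
    vmax = frame.max()
    if vmax <= 0:
        return np.zeros(frame.shape, dtype=np.uint8)
    img = frame / vmax
    fp = disk_footprint(radius).astype(np.float64)
    fp /= fp.sum()
    mean = ndi.correlate(img, fp, mode="reflect")
    mean_sq = ndi.correlate(img * img, fp, mode="reflect")
    sd = np.sqrt(np.clip(mean_sq - mean * mean, 0.0, None))
    t = mean * (1.0 + p * np.exp(-q * mean) + k * (sd / r - 1.0))
    return (img > t).astype(np.uint8)


def threshold_chastagnier(
    frame: np.ndarray,
    sigma_low: float = CHASTAGNIER_DEFAULTS["sigma_low"],
    sigma_high: float = CHASTAGNIER_DEFAULTS["sigma_high"],
) -> np.ndarray:
    """Composite local/global mask for one frame.

    Two contrast-enhanced images are built by subtracting a Gaussian-blurred
    copy of the frame from itself (clamped at 0) — a small sigma that is
    noise-prone and a large sigma that over-thickens structures — and each is
    binarized with Li's threshold. Their logical AND keeps pixels present in
    both. Holes between juxtaposed bright areas are recovered by OR-ing with
    the Otsu mask of the raw frame (globally high signal). Output is {0, 1}.
    """
    if sigma_low >= sigma_high:
        raise ValueError(f"sigma_low ({sigma_low}) must be < sigma_high ({sigma_high})")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.min() == frame.max():
        return _empty_mask(frame, "composite threshold on a constant frame")
    masks = []
    for sigma in (sigma_low, sigma_high):
        diff = np.clip(frame - ndi.gaussian_filter(frame, sigma), 0.0, None)
        if diff.min() == diff.max():
            masks.append(np.zeros(frame.shape, dtype=np.uint8))
        else:
            _, m = threshold_li(diff)
            masks.append(m)
    local = masks[0] & masks[1]
    _, otsu_mask = threshold_otsu(frame)
    return (local | otsu_mask).astype(np.uint8)


# ---------------------------------------------------------------------------
# masks on stacks


def apply_mask(stack: ImageStack, masks: MaskStack) -> ImageStack:
    """Zero out irrelevant pixels; surviving values are untouched."""
    if stack.shape != masks.shape:
        raise ValueError(f"stack shape {stack.shape} != mask shape {masks.shape}")
    return ImageStack(stack.frames * masks.frames, dtype_in=stack.dtype_in)


def make_mask_stack(stack: ImageStack, config: ThresholdConfig) -> MaskStack:
    """Dispatch the configured method over the stack.

    Per-frame methods (median_roi, otsu, phansalkar, chastagnier) recompute
    their thresholds independently at every time point, so the mask tracks
    the specimen as the signal decays.
    """
    if config.method == "constant":
        return threshold_constant(stack, config.constant_value)
    if config.method == "median_roi":
        return threshold_median_roi(stack, config.reference_region)
    masks = np.empty(stack.shape, dtype=np.uint8)
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        if config.method == "otsu":
            _, masks[t] = threshold_otsu(frame)
        elif config.method == "phansalkar":
            masks[t] = threshold_phansalkar(
                frame, radius=config.radius, k=config.k, r=config.r, p=config.p, q=config.q
            )
        else:
            masks[t] = threshold_chastagnier(
                frame, sigma_low=config.sigma_low, sigma_high=config.sigma_high
            )
    return MaskStack(masks)
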