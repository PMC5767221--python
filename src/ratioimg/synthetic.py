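"""Neuron-like two-channel time-lapse phantoms with known ground truth.

The phantom reproduces the statistical structure the pipeline assumes:
a homogeneous additive camera offset, multiplicative donor decay, rigid
(subpixel, bilinear-interpolated) xy drift, and additive Gaussian noise
(optional Poisson shot noise). The specimen mixes a bright soma, dim thin
neurites and small spines — the heterogeneous-volume regime the composite
threshold is designed for. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from ratioimg.core_io import ImageStack, Region

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "default_neuron_spec",
    "default_neuron_phantom",
    "default_neuron_regions",
]

# compartment labels in PhantomTruth.labels
BACKGROUND, SOMA, NEURITE, SPINE = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Geometry, photometry and acquisition parameters of a phantom.

    Coordinates are (y, x) pixel indices. ``neurites`` entries are
    ``(start, end, width, amplitude)`` polyline segments (width 1–2 px);
    ``spines`` entries are ``(center, radius, amplitude)`` disks.
    ``drift_per_frame`` is (dx, dy) in pixels, applied cumulatively.
    """

    frame_shape: tuple[int, int] = (256, 256)
    n_frames: int = 10
    soma_center: tuple[int, int] = (128, 128)
    soma_radius: float = 18.0
    soma_amplitude: float = 1000.0
    neurites: list = field(default_factory=list)
    spines: list = field(default_factory=list)
    soma_ratio: float = 0.50
    neurite_ratio: float = 0.55
    spine_ratio: float = 0.65
    donor_decay_tau: float = 8.0
    drift_per_frame: tuple[float, float] = (0.0, 0.0)
    camera_offset: float = 100.0
    noise_sd: float = 5.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.soma_amplitude <= 0:
            raise ValueError("soma amplitude must be > 0")
        for _, _, _, amp in self.neurites:
            if amp <= 0:
                raise ValueError("neurite amplitude must be > 0")
        for _, _, amp in self.spines:
            if amp <= 0:
                raise ValueError("spine amplitude must be > 0")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    specimen_masks: np.ndarray  # (t, y, x) uint8, drift applied
    ratio_map: np.ndarray  # (y, x) float, frame-0 coordinates
    labels: np.ndarray  # (y, x) int, frame-0 compartment labels
    labels_frames: np.ndarray  # (t, y, x) int, drift applied
    drifts: list[tuple[float, float]]  # cumulative (dx, dy) per frame
    donor_scales: list[float]  # exp(-t / tau) per frame
    spec: PhantomSpec


def _paint_structure(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Amplitude map, ratio map and compartment labels in frame-0 coords."""
    h, w = spec.frame_shape
    amp = np.zeros((h, w), dtype=np.float64)
    ratio = np.zeros((h, w), dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int8)

    def paint(mask, amplitude, ratio_value, label):
        amp[mask] = amplitude
        ratio[mask] = ratio_value
        labels[mask] = label

    for (y0, x0), (y1, x1), width, amplitude in spec.neurites:
        rr, cc = draw_line(int(y0), int(x0), int(y1), int(x1))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        line_mask = np.zeros((h, w), dtype=bool)
        line_mask[rr[keep], cc[keep]] = True
        if width >= 2:
            line_mask = ndi.binary_dilation(line_mask, structure=np.ones((2, 2), dtype=bool))
        paint(line_mask, amplitude, spec.neurite_ratio, NEURITE)

    rr, cc = draw_disk(spec.soma_center, spec.soma_radius, shape=(h, w))
    soma_mask = np.zeros((h, w), dtype=bool)
    soma_mask[rr, cc] = True
    paint(soma_mask, spec.soma_amplitude, spec.soma_ratio, SOMA)

    for center, radius, amplitude in spec.spines:
        rr, cc = draw_disk(center, radius + 0.5, shape=(h, w))
        spine_mask = np.zeros((h, w), dtype=bool)
        spine_mask[rr, cc] = True
        paint(spine_mask, amplitude, spec.spine_ratio, SPINE)

    if not amp.any():
        raise ValueError("phantom has no structure inside the frame")
    return amp, ratio, labels


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Render donor and acceptor stacks plus ground truth.

    Per frame t (scale = exp(−t/tau), cumulative drift d_t = t·drift):

        donor_t    = offset + scale·shift(amplitude, d_t)            + noise
        acceptor_t = offset + scale·shift(amplitude·ratio_map, d_t)  + noise

    Drift uses bilinear interpolation (so subpixel registration is genuinely
    exercised); truth masks use nearest-neighbor shifts, which keeps the
    specimen pixel count constant. Values are clamped at 0 (camera counts).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_shape
    amp, ratio_map, labels = _paint_structure(spec)
    ideal_d = amp
    ideal_a = amp * ratio_map
    structure = (amp > 0).astype(np.float64)

    donor = np.empty((spec.n_frames, h, w))
    acceptor = np.empty((spec.n_frames, h, w))
    masks = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    labels_frames = np.empty((spec.n_frames, h, w), dtype=np.int8)
    drifts: list[tuple[float, float]] = []
    scales: list[float] = []
    dx_pf, dy_pf = spec.drift_per_frame

    for t in range(spec.n_frames):
        scale = float(np.exp(-t / spec.donor_decay_tau)) if spec.donor_decay_tau > 0 else 1.0
        dx, dy = t * dx_pf, t * dy_pf
        drifts.append((dx, dy))
        scales.append(scale)
        if dx == 0.0 and dy == 0.0:
            d_sig, a_sig = ideal_d, ideal_a
            masks[t] = structure.astype(np.uint8)
            labels_frames[t] = labels
        else:
            d_sig = ndi.shift(ideal_d, (dy, dx), order=1, mode="constant", cval=0.0)
            a_sig = ndi.shift(ideal_a, (dy, dx), order=1, mode="constant", cval=0.0)
            masks[t] = ndi.shift(structure, (dy, dx), order=0, mode="constant", cval=0.0).astype(
                np.uint8
            )
            labels_frames[t] = ndi.shift(
                labels, (dy, dx), order=0, mode="constant", cval=0
            ).astype(np.int8)
        d = spec.camera_offset + scale * d_sig
        a = spec.camera_offset + scale * a_sig
        if spec.poisson:
            d = rng.poisson(np.clip(d, 0, None)).astype(np.float64)
            a = rng.poisson(np.clip(a, 0, None)).astype(np.float64)
        if spec.noise_sd > 0:
            d = d + rng.normal(0.0, spec.noise_sd, size=(h, w))
            a = a + rng.normal(0.0, spec.noise_sd, size=(h, w))
        donor[t] = np.clip(d, 0.0, None)
        acceptor[t] = np.clip(a, 0.0, None)

    truth = PhantomTruth(
        specimen_masks=masks,
        ratio_map=ratio_map,
        labels=labels,
        labels_frames=labels_frames,
        drifts=drifts,
        donor_scales=scales,
        spec=spec,
    )
    return ImageStack(donor), ImageStack(acceptor), truth


# ---------------------------------------------------------------------------
# the documented standard phantom used by the acceptance suite


def default_neuron_spec(seed: int = 0) -> PhantomSpec:
    """256×256, 10 frames: soma 1000 counts (ratio 0.50), three neurites at
    60 counts (ratio 0.55), five radius-2 spines at 40 counts (ratio 0.65),
    decay tau 8 frames, offset 100, Gaussian noise sd 5, drift (0.3, −0.2)
    px/frame."""
    return PhantomSpec(
        frame_shape=(256, 256),
        n_frames=10,
        soma_center=(128, 128),
        soma_radius=18.0,
        soma_amplitude=1000.0,
        neurites=[
            ((128, 145), (128, 235), 2, 60.0),
            ((112, 116), (40, 60), 2, 60.0),
            ((145, 120), (225, 90), 2, 60.0),
        ],
        spines=[
            ((124, 180), 2, 40.0),
            ((132, 210), 2, 40.0),
            ((80, 90), 2, 40.0),
            ((190, 104), 2, 40.0),
            ((124, 228), 2, 40.0),
        ],
        soma_ratio=0.50,
        neurite_ratio=0.55,
        spine_ratio=0.65,
        donor_decay_tau=8.0,
        drift_per_frame=(0.3, -0.2),
        camera_offset=100.0,
        noise_sd=5.0,
        seed=seed,
    )


def default_neuron_phantom(seed: int = 0) -> tuple[ImageStack, ImageStack, PhantomTruth]:
    """Generate the documented standard phantom (see :func:`default_neuron_spec`)."""
    return generate_phantom(default_neuron_spec(seed))


def default_neuron_regions(spec: PhantomSpec | None = None) -> list[Region]:
    """Background region and measurement ROIs matching the default phantom.

    ROIs are defined in frame-0 (reference) coordinates: a rectangle inside
    the soma, one rectangle per spine (5×5, covering the 13-pixel disk), one
    on the first neurite, plus the threshold-reference and background areas.
    """
    if spec is None:
        spec = default_neuron_spec()
    regions = [
        Region("background", "rectangle", [(5, 5), (55, 55)], role="background"),
        Region("soma", "rectangle", [(120, 120), (136, 136)], role="measurement"),
        Region("neurite_1", "rectangle", [(170, 126), (200, 131)], role="measurement"),
    ]
    for i, (center, radius, _amp) in enumerate(spec.spines, start=1):
        cy, cx = center
        regions.append(
            Region(
                f"spine_{i}",
                "rectangle",
                [(cx - radius, cy - radius), (cx + radius + 1, cy + radius + 1)],
                role="measurement",
            )
        )
    return regions
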