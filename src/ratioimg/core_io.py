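"""Shared domain types and file I/O.

Image stacks are stored as float64 ``(t, y, x)`` arrays regardless of the
on-disk pixel depth; regions are named polygons/rectangles in 0-based pixel
coordinates with origin at the top-left.

Coordinate conventions
----------------------
* ``(x, y)`` with ``x`` the column index and ``y`` the row index.
* Rectangles are half-open: ``[x0, x1) × [y0, y1)``.
* Polygons are rasterized with a pixel-center-inside test under the
  even-odd rule; the center of pixel ``(row=y, col=x)`` is ``(x, y)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "Region",
    "MaskStack",
    "RatioStack",
    "MeasurementTable",
    "read_stack",
    "write_stack",
    "read_regions",
    "write_regions",
    "write_measurements",
    "read_measurements",
]

MEASUREMENT_COLUMNS = ["roi_name", "frame_index", "mean_ratio", "sd_ratio", "n_pixels"]


@dataclass
class ImageStack:
    """An ordered sequence of 2-D intensity frames for one channel.

    Parameters
    ----------
    frames : ndarray
        3-D ``(t, y, x)`` array. Converted to float64 on construction.
    dtype_in : numpy dtype, optional
        Original on-disk pixel depth, recorded for provenance.
    """

    frames: np.ndarray
    dtype_in: np.dtype | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim != 3:
            raise ValueError(f"frames must be (t, y, x), got shape {frames.shape}")
        if frames.shape[0] < 1 or frames.shape[1] < 1 or frames.shape[2] < 1:
            raise ValueError(f"empty stack: shape {frames.shape}")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.frames.copy(), dtype_in=self.dtype_in)


@dataclass
class Region:
    """A named rectangle or polygon in pixel coordinates.

    ``vertices`` are ``(x, y)`` pairs. A rectangle is given by two opposite
    corners and covers the half-open box ``[x0, x1) × [y0, y1)``.
    """

    name: str
    kind: str  # "rectangle" | "polygon"
    vertices: list[tuple[float, float]]
    role: str = "measurement"  # background | measurement | threshold-reference | crop

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "polygon"):
            raise ValueError(f"region {self.name!r}: unknown kind {self.kind!r}")
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if self.kind == "rectangle" and len(self.vertices) not in (2, 4):
            raise ValueError(
                f"region {self.name!r}: rectangle needs 2 opposite corners "
                f"(or 4 corners), got {len(self.vertices)} vertices"
            )
        if self.kind == "polygon" and len(self.vertices) < 3:
            raise ValueError(
                f"region {self.name!r}: polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) bounding box of the vertices."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)

    def rasterize(self, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of covered pixel centers, clipped to the frame.

        Out-of-bounds parts are clipped with a logged warning; an empty
        result raises ``ValueError``.
        """
        h, w = frame_shape
        x0, y0, x1, y1 = self.bounds()
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            logger.warning(
                "region %r extends outside the %dx%d frame; clipping", self.name, w, h
            )
        mask = np.zeros((h, w), dtype=bool)
        if self.kind == "rectangle":
            cx0 = max(int(math.ceil(x0)), 0)
            cy0 = max(int(math.ceil(y0)), 0)
            cx1 = min(int(math.ceil(x1)), w)
            cy1 = min(int(math.ceil(y1)), h)
            if cx1 > cx0 and cy1 > cy0:
                mask[cy0:cy1, cx0:cx1] = True
        else:
            mask = _rasterize_polygon(self.vertices, frame_shape)
        if not mask.any():
            raise ValueError(f"region {self.name!r} rasterizes to zero pixels in frame")
        return mask

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "vertices": [[x, y] for x, y in self.vertices],
            "role": self.role,
        }


def _rasterize_polygon(
    vertices: Sequence[tuple[float, float]], frame_shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd (ray crossing) pixel-center-inside test, vectorized.

    A pixel center exactly on an edge follows the standard half-open crossing
    rule (edges with ``yi <= py < yj`` count), which keeps adjacent polygons
    non-overlapping.
    """
    h, w = frame_shape
    xs = np.array([v[0] for v in vertices], dtype=float)
    ys = np.array([v[1] for v in vertices], dtype=float)
    bx0 = max(int(math.floor(xs.min())), 0)
    bx1 = min(int(math.ceil(xs.max())) + 1, w)
    by0 = max(int(math.floor(ys.min())), 0)
    by1 = min(int(math.ceil(ys.max())) + 1, h)
    mask = np.zeros((h, w), dtype=bool)
    if bx1 <= bx0 or by1 <= by0:
        return mask
    px, py = np.meshgrid(np.arange(bx0, bx1, dtype=float), np.arange(by0, by1, dtype=float))
    inside = np.zeros(px.shape, dtype=bool)
    n = len(xs)
    for i in range(n):
        j = (i - 1) % n
        xi, yi = xs[i], ys[i]
        xj, yj = xs[j], ys[j]
        crosses = (yi > py) != (yj > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (xj - xi) * (py - yi) / (yj - yi) + xi
        inside ^= crosses & (px < x_at)
    mask[by0:by1, bx0:bx1] = inside
    return mask


@dataclass
class MaskStack:
    """Per-frame binary specimen mask with values in {0, 1}."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim != 3:
            raise ValueError(f"mask frames must be (t, y, x), got {frames.shape}")
        uniq = np.unique(frames)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, got {uniq[:10]}")
        self.frames = frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class RatioStack:
    """Per-frame floating-point A/D ratio; 0 marks excluded pixels."""

    frames: np.ndarray
    display_min: float | None = None
    display_max: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim == 2:
            frames = frames[np.newaxis]
        if frames.ndim != 3:
            raise ValueError(f"ratio frames must be (t, y, x), got {frames.shape}")
        if not np.isfinite(frames).all():
            raise ValueError("ratio stack contains non-finite values")
        if (frames < 0).any():
            raise ValueError("ratio stack contains negative values")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class MeasurementTable:
    """Per-ROI, per-frame ratio statistics (zero pixels excluded)."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MEASUREMENT_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"measurement table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# stacks on disk


def read_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: TIFF has zero pages")
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: pages differ in size: {sorted(shapes)}")
        arr = tif.asarray()
        dtype_in = tif.pages[0].dtype
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of shape {arr.shape}")
    return ImageStack(arr.astype(np.float64), dtype_in=np.dtype(dtype_in))


def write_stack(stack: ImageStack | MaskStack, path: str | Path, depth: str = "32-bit-float") -> Path:
    """Write a stack as multi-page TIFF at the requested depth.

    ``depth`` is ``"8-bit"``, ``"16-bit"`` or ``"32-bit-float"``. Integer
    depths reject out-of-range values rather than wrapping.
    """
    path = Path(path)
    frames = np.asarray(stack.frames, dtype=np.float64)
    if depth == "32-bit-float":
        out = frames.astype(np.float32)
    elif depth in ("8-bit", "16-bit"):
        limit = 255 if depth == "8-bit" else 65535
        rounded = np.rint(frames)
        if rounded.min() < 0 or rounded.max() > limit:
            raise ValueError(
                f"values in [{frames.min():g}, {frames.max():g}] do not fit {depth} "
                f"(allowed 0..{limit})"
            )
        out = rounded.astype(np.uint8 if depth == "8-bit" else np.uint16)
    else:
        raise ValueError(f"unknown depth {depth!r}")
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# regions


def read_regions(path: str | Path) -> list[Region]:
    """Read region definitions from a JSON sidecar (or ImageJ .roi/.zip).

    The native format is ``{"regions": [{"name", "kind", "vertices",
    "role"}, ...]}``. ImageJ ``.roi``/``.zip`` files are read through the
    optional ``roifile`` dependency.
    """
    path = Path(path)
    if path.suffix.lower() in (".roi", ".zip"):
        return _read_imagej_rois(path)
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "regions" not in payload:
        raise ValueError(f"{path}: expected a JSON object with a 'regions' key")
    regions = []
    for entry in payload["regions"]:
        try:
            regions.append(
                Region(
                    name=entry["name"],
                    kind=entry["kind"],
                    vertices=[tuple(v) for v in entry["vertices"]],
                    role=entry.get("role", "measurement"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed region entry {entry!r}") from exc
    return regions


def _read_imagej_rois(path: Path) -> list[Region]:
    try:
        import roifile
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading ImageJ .roi/.zip files requires the optional 'roifile' package; "
            "use the JSON sidecar format instead"
        ) from exc
    rois = roifile.roiread(str(path))
    if not isinstance(rois, list):
        rois = [rois]
    regions = []
    for roi in rois:
        coords = roi.coordinates()
        kind = "rectangle" if roi.roitype == roifile.ROI_TYPE.RECT else "polygon"
        if kind == "rectangle":
            vertices = [(roi.left, roi.top), (roi.right, roi.bottom)]
        else:
            vertices = [(float(x), float(y)) for x, y in coords]
        regions.append(Region(name=roi.name or f"roi_{len(regions)}", kind=kind, vertices=vertices))
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"regions": [r.to_dict() for r in regions]}, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# measurements


def write_measurements(table: MeasurementTable, path: str | Path) -> Path:
    """Write the measurement table as CSV; missing stats become empty fields."""
    if len(table) == 0:
        raise ValueError("measurement table is empty")
    path = Path(path)
    df = table.data.loc[:, [c for c in table.data.columns]]
    df.to_csv(path, index=False, na_rep="", float_format="%.9g")
    return path


def read_measurements(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(path)
    return MeasurementTable(df)
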