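"""Per-ROI, per-frame ratio statistics over the time series.

Pixels with a null ratio are masked background and are excluded from every
statistic; an ROI whose mask support vanishes in a frame reports missing
values rather than a silent zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ratioimg.core_io import MEASUREMENT_COLUMNS, MeasurementTable, RatioStack, Region

__all__ = ["measure_rois", "pool_measurements"]


def measure_rois(ratio: RatioStack, rois: list[Region]) -> MeasurementTable:
    """Mean, sample SD (n−1) and pixel count of nonzero ratio per ROI per frame.

    mean_ratio is missing (NaN) when no nonzero pixel falls in the ROI;
    sd_ratio is missing when fewer than two do. Padding an ROI with
    zero-valued pixels changes nothing.
    """
    if not rois:
        raise ValueError("no ROIs given")
    frame_shape = ratio.frames.shape[1:]
    rows = []
    for roi in rois:
        mask = roi.rasterize(frame_shape)
        for t in range(ratio.n_frames):
            vals = ratio.frames[t][mask]
            nz = vals[vals > 0]
            n = int(nz.size)
            mean = float(nz.mean()) if n >= 1 else np.nan
            sd = float(nz.std(ddof=1)) if n >= 2 else np.nan
            rows.append((roi.name, t, mean, sd, n))
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return MeasurementTable(df)


def pool_measurements(
    tables: list[MeasurementTable], labels: list[str] | None = None
) -> MeasurementTable:
    """Concatenate tables from multiple sources into one labeled table.

    Adds a ``source`` column so per-frame across-ROI summaries (mean ± SEM)
    can be computed downstream. (roi_name, frame_index) must be unique
    within each source.
    """
    if not tables:
        raise ValueError("no measurement tables to pool")
    if labels is None:
        labels = [f"source_{i}" for i in range(len(tables))]
    if len(labels) != len(tables):
        raise ValueError(f"{len(tables)} tables but {len(labels)} labels")
    parts = []
    for table, label in zip(tables, labels):
        df = table.data.copy()
        if df.duplicated(subset=["roi_name", "frame_index"]).any():
            raise ValueError(f"duplicate (roi_name, frame_index) within source {label!r}")
        df["source"] = label
        parts.append(df)
    pooled = pd.concat(parts, ignore_index=True)
    return MeasurementTable(pooled)


def summarize_across_rois(table: MeasurementTable) -> pd.DataFrame:
    """Per-frame mean ± SEM of ROI mean ratios (one point per time point)."""
    df = table.data.dropna(subset=["mean_ratio"])
    grouped = df.groupby("frame_index")["mean_ratio"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
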