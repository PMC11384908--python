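"""ROS-reporter fluorescence quantification.

DHR-type dyes convert to a fluorescent product upon oxidation, so the ROS
signal of a vessel is the rise of background-subtracted ROI intensity over
the acquisition: ΔF(x) = F(x min) − F(0 min) on the minute grid.  ΔF is by
construction 0 at t = 0 and invariant to any constant added to both the ROI
and background channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FluorescenceSeries


@dataclass
class DeltaFSeries:
    """ΔF-from-baseline time course for one vessel."""

    t_min: np.ndarray
    delta_f_au: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.delta_f_au = np.asarray(self.delta_f_au, dtype=float)
        if self.t_min.size == 0 or self.t_min[0] != 0:
            raise ValueError("ΔF series must start at t = 0")
        if self.delta_f_au[0] != 0.0:
            raise ValueError("ΔF at t = 0 must be exactly 0")


def background_subtract(series: FluorescenceSeries) -> FluorescenceSeries:
    """Subtract the background channel from the ROI channel, point by point.

    Negative corrected intensities are kept in the data (clipping would bias
    ΔF); a warning-style metadata flag notes their presence.  The channels
    must share one time grid.
    """
    corrected = series.roi_au - series.background_au
    meta = dict(series.metadata, background_subtracted=True)
    if np.any(corrected < 0):
        import warnings

        warnings.warn(
            "background exceeds ROI intensity at some time points; values "
            "kept unclipped",
            stacklevel=2,
        )
        meta["negative_corrected_values"] = int(np.sum(corrected < 0))
    return FluorescenceSeries(
        series.t_min.copy(), corrected, np.zeros_like(corrected), meta
    )


def delta_f(series: FluorescenceSeries, condition: str | None = None) -> DeltaFSeries:
    """ΔF(x) = F(x) − F(0) on the acquisition grid of a corrected series."""
    if series.t_min.size == 0 or series.t_min[0] != 0:
        raise ValueError("series lacks the t = 0 sample; ΔF undefined")
    f0 = series.roi_au[0]
    return DeltaFSeries(series.t_min.copy(), series.roi_au - f0, condition)


def condition_summary(series_by_vessel: dict[str, DeltaFSeries]) -> pd.DataFrame:
    """Group ΔF time courses: per-time mean ± SD across vessels.

    All vessels must share the acquisition grid.  Returns a frame with
    columns ``t_min``, ``mean_delta_f_au``, ``sd_delta_f_au``, ``n``;
    group-level inference is the job of :mod:`lymphpump.stats`.
    """
    if not series_by_vessel:
        raise ValueError("empty group: need at least one vessel")
    items = list(series_by_vessel.values())
    grid = items[0].t_min
    for s in items[1:]:
        if s.t_min.size != grid.size or np.any(s.t_min != grid):
            raise ValueError("vessels do not share one acquisition grid")
    stack = np.vstack([s.delta_f_au for s in items])
    return pd.DataFrame(
        {
            "t_min": grid,
            "mean_delta_f_au": stack.mean(axis=0),
            "sd_delta_f_au": stack.std(axis=0, ddof=1) if len(items) > 1
            else np.zeros(grid.size),
            "n": len(items),
        }
    )


def roi_mean_series(
    frames: np.ndarray, roi: tuple[int, int, int, int],
    background_roi: tuple[int, int, int, int], t_min: np.ndarray,
) -> FluorescenceSeries:
    """Build a :class:`FluorescenceSeries` from an image stack.

    ``frames`` is (time, rows, cols); each ROI is ``(row0, row1, col0,
    col1)`` with half-open bounds.  Rectangular-ROI means are the only image
    operation supported — segmentation is out of scope.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (time, rows, cols) stack")
    r0, r1, c0, c1 = roi
    b0, b1, d0, d1 = background_roi
    roi_vals = frames[:, r0:r1, c0:c1].mean(axis=(1, 2))
    bg_vals = frames[:, b0:b1, d0:d1].mean(axis=(1, 2))
    return FluorescenceSeries(np.asarray(t_min, float), roi_vals, bg_vals)
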