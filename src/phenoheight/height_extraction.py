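"""Per-plot canopy height from crop surface models.

The binned percentile method: the plot window (middle two rows, planted
length) is sliced into 20 bins along the row; each bin contributes its 3rd
and 97th percentile elevations; the plot ground elevation is the minimum
3rd percentile across bins; each bin's height is its 97th percentile minus
the ground; and the plot mean height (PH_UAV) is the trimmed mean of the
middle 12 bins after dropping the single highest and single lowest bin
(average of the remaining 10).  A whole-plot 95th-percentile estimator
(PH_95, same ground) is provided for comparison.  Avoiding a separate
bare-ground terrain model, ground is estimated per plot per date directly
from the surface raster, which requires some ground-visible pixels inside
each boundary.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import (
    ConfigurationError,
    EmptyBinError,
    EmptyPlotError,
    GeoreferenceError,
    ResolutionError,
)
from .field_design import PlotBoundary
from .raster import SurfaceRaster

logger = logging.getLogger(__name__)


@dataclass
class PixelWindow:
    """Valid pixels of one plot, oriented so axis 1 runs along the row."""

    plot_id: str
    values: np.ndarray  # 2D elevations (m), bounding box of the boundary
    mask: np.ndarray  # 2D bool: pixel center inside polygon and finite
    pixel_size: float
    date: _dt.date | None = None

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class BinProfile:
    """Per-bin percentile elevations for one plot on one date."""

    plot_id: str
    date: _dt.date | None
    n_bins: int
    counts: np.ndarray
    p_low: np.ndarray  # low-percentile elevation per bin (m)
    p_high: np.ndarray  # high-percentile elevation per bin (m)
    pct_low: float = 3.0
    pct_high: float = 97.0

    @property
    def ground(self) -> float:
        return float(np.min(self.p_low))

    def bin_heights(self) -> np.ndarray:
        """Bin heights = p_high - ground, floored at zero (heights are
        physical lengths; barren bins may dip below the ground estimate)."""
        return np.clip(self.p_high - self.ground, 0.0, None)


@dataclass
class PlotHeightRecord:
    plot_id: str
    date: _dt.date | None
    days_after_sowing: int | None
    method: str  # "binned_trimmed" | "p95_whole_plot"
    ph_m: float
    ground_m: float
    n_valid_pixels: int


def _points_in_polygon(poly, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pixel-center inclusion, half-open: centers on the min-x/min-y edges
    are in, centers on the max-x/max-y edges are out, so adjacent plot
    windows never share pixels."""
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    on_edge = shapely.intersects_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape) & ~inside
    if on_edge.any():
        minx, miny, maxx, maxy = poly.bounds
        keep = on_edge & ~np.isclose(X, maxx) & ~np.isclose(Y, maxy)
        inside |= keep
    return inside


def segment_plot(raster: SurfaceRaster, boundary: PlotBoundary) -> PixelWindow:
    """Clip the plot boundary out of the raster.

    Raises :class:`EmptyPlotError` when no valid pixel center falls inside
    and :class:`GeoreferenceError` on CRS mismatch.  The window is oriented
    so that its columns run along the row axis declared by the boundary;
    only axis-aligned boundaries (along-row axis parallel to x or y) are
    supported by the binning that follows.
    """
    if (
        raster.crs_epsg is not None
        and boundary.crs_epsg is not None
        and raster.crs_epsg != boundary.crs_epsg
    ):
        raise GeoreferenceError(
            f"raster EPSG:{raster.crs_epsg} != boundary EPSG:{boundary.crs_epsg}"
        )
    minx, miny, maxx, maxy = boundary.polygon.bounds
    rminx, rminy, rmaxx, rmaxy = raster.bounds
    if minx >= rmaxx or maxx <= rminx or miny >= rmaxy or maxy <= rminy:
        raise EmptyPlotError(f"plot {boundary.plot_id}: boundary outside raster extent")
    gs = raster.pixel_size
    c0 = max(0, int(np.floor((minx - raster.x_origin) / gs)))
    c1 = min(raster.shape[1], int(np.ceil((maxx - raster.x_origin) / gs)))
    r0 = max(0, int(np.floor((raster.y_origin - maxy) / gs)))
    r1 = min(raster.shape[0], int(np.ceil((raster.y_origin - miny) / gs)))
    if c0 >= c1 or r0 >= r1:
        raise EmptyPlotError(f"plot {boundary.plot_id}: no pixels in boundary bbox")
    xs = raster.x_centers(np.arange(c0, c1))
    ys = raster.y_centers(np.arange(r0, r1))
    inside = _points_in_polygon(boundary.polygon, xs, ys)
    values = raster.data[r0:r1, c0:c1].astype(np.float64)
    mask = inside & np.isfinite(values)
    ux, uy = boundary.axis
    if abs(ux) < abs(uy):  # row axis runs along world y -> transpose so
        values = values.T[::-1]  # columns follow increasing y
        mask = mask.T[::-1]
    if not mask.any():
        raise EmptyPlotError(f"plot {boundary.plot_id}: no valid pixels inside boundary")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    values = values[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return PixelWindow(
        plot_id=boundary.plot_id,
        values=values,
        mask=mask,
        pixel_size=gs,
        date=raster.date,
    )


def bin_plot(window: PixelWindow, n_bins: int = 20) -> list[PixelWindow]:
    """Partition the window into ``n_bins`` contiguous column slices along
    the row axis; slice widths differ by at most one column (wider slices
    first)."""
    ncol = window.values.shape[1]
    if ncol < n_bins:
        raise ResolutionError(f"{ncol} pixel columns < {n_bins} bins")
    edges = np.array_split(np.arange(ncol), n_bins)
    return [
        PixelWindow(
            plot_id=window.plot_id,
            values=window.values[:, idx[0] : idx[-1] + 1],
            mask=window.mask[:, idx[0] : idx[-1] + 1],
            pixel_size=window.pixel_size,
            date=window.date,
        )
        for idx in edges
    ]


def bin_percentiles(
    subwindow: PixelWindow, p_low: float = 3.0, p_high: float = 97.0
) -> tuple[float, float]:
    """Low/high percentile elevations of a bin's valid pixels, by linear
    interpolation between order statistics (index = (n-1) * p / 100)."""
    vals = subwindow.valid_values()
    if vals.size == 0:
        raise EmptyBinError(f"plot {subwindow.plot_id}: bin has no valid pixels")
    lo, hi = np.percentile(vals, [p_low, p_high])
    return float(lo), float(hi)


def bin_profile(
    window: PixelWindow, n_bins: int = 20, p_low: float = 3.0, p_high: float = 97.0
) -> BinProfile:
    bins = bin_plot(window, n_bins)
    lows, highs, counts = [], [], []
    for b in bins:
        lo, hi = bin_percentiles(b, p_low, p_high)
        lows.append(lo)
        highs.append(hi)
        counts.append(b.n_valid)
    return BinProfile(
        plot_id=window.plot_id,
        date=window.date,
        n_bins=n_bins,
        counts=np.array(counts),
        p_low=np.array(lows),
        p_high=np.array(highs),
        pct_low=p_low,
        pct_high=p_high,
    )


def ground_height(profile: BinProfile) -> float:
    """Plot ground elevation: minimum low-percentile elevation across bins."""
    return profile.ground


def plot_mean_height(profile: BinProfile, n_middle: int = 12, n_trim: int = 1) -> float:
    """Trimmed mean plot height (PH_UAV, m).

    Takes the middle ``n_middle`` bins (bins 5-16 of 20 under defaults,
    symmetric exclusion of the alley-adjacent ends), removes the ``n_trim``
    highest and lowest bins (one each by default, first occurrence on
    ties), and averages the rest.
    """
    if (n_middle, n_trim) == (12, 1) and profile.n_bins != 20:
        raise ConfigurationError(
            f"default trim settings require 20 bins, got {profile.n_bins}"
        )
    if n_middle > profile.n_bins or (profile.n_bins - n_middle) % 2:
        raise ConfigurationError(
            f"cannot center {n_middle} bins within {profile.n_bins}"
        )
    if n_middle - 2 * n_trim < 1:
        raise ConfigurationError("trimming would remove every bin")
    start = (profile.n_bins - n_middle) // 2
    heights = profile.bin_heights()[start : start + n_middle]
    idx = np.arange(n_middle)
    keep = np.ones(n_middle, dtype=bool)
    for _ in range(n_trim):  # ties: first occurrence along the row
        cand = idx[keep]
        keep[cand[np.argmax(heights[cand])]] = False
    for _ in range(n_trim):
        cand = idx[keep]
        keep[cand[np.argmin(heights[cand])]] = False
    return float(np.mean(heights[keep]))


def plot_p95_height(
    window: PixelWindow, ground_elevation: float, pct: float = 95.0
) -> float:
    """Whole-plot percentile height (PH_95, m): the ``pct`` percentile of
    all valid plot pixels minus the plot ground elevation."""
    vals = window.valid_values()
    if vals.size == 0:
        raise EmptyPlotError(f"plot {window.plot_id}: empty window")
    return float(np.percentile(vals, pct) - ground_elevation)


@dataclass
class ExtractionConfig:
    n_bins: int = 20
    p_low: float = 3.0
    p_high: float = 97.0
    p95: float = 95.0
    methods: tuple[str, ...] = ("binned_trimmed",)  # and/or "p95_whole_plot"
    n_middle: int = 12
    n_trim: int = 1


def extract_plot(
    raster: SurfaceRaster, boundary: PlotBoundary, config: ExtractionConfig | None = None
) -> list[PlotHeightRecord]:
    config = config or ExtractionConfig()
    window = segment_plot(raster, boundary)
    profile = bin_profile(window, config.n_bins, config.p_low, config.p_high)
    ground = ground_height(profile)
    das = None
    pdate = boundary.properties.get("planting_date")
    if pdate is not None and raster.date is not None:
        das = (raster.date - _dt.date.fromisoformat(str(pdate))).days
    out = []
    for method in config.methods:
        if method == "binned_trimmed":
            ph = plot_mean_height(profile, config.n_middle, config.n_trim)
        elif method == "p95_whole_plot":
            ph = plot_p95_height(window, ground, config.p95)
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        out.append(
            PlotHeightRecord(
                plot_id=boundary.plot_id,
                date=raster.date,
                days_after_sowing=das,
                method=method,
                ph_m=ph,
                ground_m=ground,
                n_valid_pixels=window.n_valid,
            )
        )
    return out


def extract_field(
    rasters: Sequence[SurfaceRaster],
    boundaries: Sequence[PlotBoundary],
    config: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Batch extraction: one record per plot per date per method.

    Per-plot failures (empty windows, CRS mismatches) are logged and
    collected, never fatal to the batch.  Returns (records, failures).
    """
    config = config or ExtractionConfig()
    rows, failures = [], []
    for raster in rasters:
        for boundary in boundaries:
            try:
                for rec in extract_plot(raster, boundary, config):
                    rows.append(
                        {
                            "plot_id": rec.plot_id,
                            "date": rec.date.isoformat() if rec.date else None,
                            "days_after_sowing": rec.days_after_sowing,
                            "method": rec.method,
                            "ph_m": rec.ph_m,
                            "ground_m": rec.ground_m,
                            "n_pixels": rec.n_valid_pixels,
                        }
                    )
            except ConfigurationError:
                raise
            except Exception as exc:  # per-plot failure: record and move on
                reason = f"{type(exc).__name__}: {exc}"
                logger.warning(
                    "plot %s date %s skipped (%s)", boundary.plot_id, raster.date, reason
                )
                failures.append(
                    {
                        "plot_id": boundary.plot_id,
                        "date": raster.date.isoformat() if raster.date else None,
                        "reason": reason,
                    }
                )
    return pd.DataFrame(rows), failures
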