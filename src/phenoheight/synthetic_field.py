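"""Ground-truthed synthetic field scenes.

Generates everything a season of drone flights over a maize trial would
yield -- per-plant logistic growth trajectories, an optional wind-lodging
event whose severity scales with planting density, crop-surface-model
rasters rendered from per-plant canopy discs over a tilted terrain plane,
and ruler measurement tables -- with the true heights retained so every
downstream stage can be validated against known answers.

The canopy is rendered as radially tapered discs: a plateau at the plant's
height out to ``plateau_frac`` of the radius, then a linear taper to the
ground.  The disc radius grows with plant height but is capped at 45% of
the row spacing, which keeps a thin inter-row ground strip visible all
season; this mimics the row-gap/alley ground visibility the per-plot
ground-height estimate relies on.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ResolutionError, SamplingError
from .field_design import FieldDesign, PlotRecord
from .raster import SurfaceRaster


@dataclass
class GrowthParams:
    """Logistic growth parameters h(t) = A / (1 + exp(-r (t - t0)))."""

    asymptote_m: dict[str, float]  # terminal height A per genotype
    rate_per_day: dict[str, float]  # base logistic rate r per genotype
    inflection_das: dict[_dt.date, float]  # t0 per planting date (days after sowing)
    density_rate_mult: dict[float, float]  # multiplier on r per density
    plant_asymptote_sd_m: float = 0.05

    @classmethod
    def default_for(cls, design: FieldDesign, seed: int = 0) -> "GrowthParams":
        """Realistic maize-hybrid defaults: terminal heights 2.0-2.7 m,
        rates 0.14-0.18 /day, inflection ~42 days after sowing, higher
        density growing slightly faster."""
        rng = np.random.default_rng(seed)
        a = {g: float(rng.uniform(2.0, 2.7)) for g in design.genotypes}
        r = {g: float(rng.uniform(0.14, 0.18)) for g in design.genotypes}
        t0 = {d: 42.0 for d in design.planting_dates}
        dens = sorted(design.densities)
        mid = dens[len(dens) // 2]
        mult = {d: 1.0 + 0.05 * np.sign(d - mid) for d in dens}
        return cls(a, r, t0, mult, 0.05)


@dataclass
class LodgingEvent:
    """Mid-season wind lodging: an instantaneous fractional height loss at
    ``event_day`` (days after sowing of the first planting) that relaxes
    linearly back to the pre-event trajectory over ``recovery_days``.
    Severity increases with planting density; by default only the earliest
    planting date is affected."""

    event_day: float = 48.0
    severity_by_density: dict[float, float] = field(
        default_factory=lambda: {60000.0: 0.10, 90000.0: 0.20, 120000.0: 0.30}
    )
    recovery_days: float = 10.0
    affected_dates: Sequence[_dt.date] | None = None  # None -> earliest planting only

    def __post_init__(self) -> None:
        for s in self.severity_by_density.values():
            if not 0 <= s < 1:
                raise ValueError("lodging severity must be in [0, 1)")
        if self.recovery_days < 0:
            raise ValueError("recovery_days must be >= 0")

    def applies_to(self, planting_date: _dt.date, all_dates: Sequence[_dt.date]) -> bool:
        affected = self.affected_dates if self.affected_dates is not None else [min(all_dates)]
        return planting_date in affected

    def das_for(self, planting_date: _dt.date, first_planting: _dt.date) -> float:
        """Event time on a plot's own days-after-sowing clock."""
        return self.event_day - (planting_date - first_planting).days

    def multiplier(self, t_das: float, event_das: float, severity: float) -> float:
        if t_das < event_das or severity <= 0:
            return 1.0
        if self.recovery_days == 0:
            return 1.0 if t_das > event_das else 1.0 - severity
        frac = min(1.0, (t_das - event_das) / self.recovery_days)
        return 1.0 - severity * (1.0 - frac)


def logistic_height(a: float, r: float, t0: float, t: float) -> float:
    return a / (1.0 + np.exp(-r * (t - t0)))


def simulate_growth_curve(
    params: GrowthParams,
    genotype: str,
    density: float,
    planting_date: _dt.date,
    t_das: float,
    a_plant: float | None = None,
    lodging: LodgingEvent | None = None,
    first_planting: _dt.date | None = None,
    lodging_applies: bool = True,
) -> float:
    """True plant height (m) at ``t_das`` days after sowing."""
    if t_das < 0:
        return 0.0
    a = params.asymptote_m[genotype] if a_plant is None else a_plant
    r = params.rate_per_day[genotype] * params.density_rate_mult.get(density, 1.0)
    t0 = params.inflection_das[planting_date]
    h = logistic_height(a, r, t0, t_das)
    if lodging is not None and lodging_applies:
        sev = lodging.severity_by_density.get(density, 0.0)
        event_das = lodging.das_for(planting_date, first_planting or planting_date)
        h *= lodging.multiplier(t_das, event_das, sev)
    return float(h)


@dataclass
class SceneTruth:
    """Everything the simulator knows about the field, for validation."""

    design: FieldDesign
    plants: pd.DataFrame  # plot_id, plant, row, x, y, asymptote_m
    heights: pd.DataFrame  # plot_id, plant, date, das, height_m (long)
    plot_means: pd.DataFrame  # plot_id, date, das, true_mean_m
    terrain: tuple[float, float, float]  # base elevation, tilt_x, tilt_y (m/m)
    records: Sequence[PlotRecord] = ()


def plants_per_row(design: FieldDesign, density: float) -> int:
    spacing = 10000.0 / (density * design.row_spacing_m)
    return int(round(design.planted_length_m / spacing))


def build_scene_truth(
    design: FieldDesign,
    records: Sequence[PlotRecord],
    params: GrowthParams,
    dates: Sequence[_dt.date],
    lodging: LodgingEvent | None = None,
    seed: int = 0,
    terrain: tuple[float, float, float] = (100.0, 0.005, 0.0),
) -> SceneTruth:
    """Instantiate plants on the grid and evaluate their growth curves."""
    rng = np.random.default_rng(seed)
    ox, oy = design.field_origin
    first_planting = min(design.planting_dates)
    prow: list[dict] = []
    for rec in records:
        n = plants_per_row(design, rec.density)
        step = design.planted_length_m / n
        x0 = ox + rec.grid_col * design.row_length_pitch_m
        band = oy + rec.grid_row * design.plot_width_m
        a_g = params.asymptote_m[rec.genotype]
        for row in range(design.rows_per_plot):
            y = band + (row + 0.5) * design.row_spacing_m
            a_plants = a_g + params.plant_asymptote_sd_m * rng.standard_normal(n)
            a_plants = np.clip(a_plants, 1e-3, None)  # truncate at > 0
            for j in range(n):
                prow.append(
                    {
                        "plot_id": rec.plot_id,
                        "plant": f"{row}_{j}",
                        "row": row,
                        "x": x0 + (j + 0.5) * step,
                        "y": y,
                        "asymptote_m": float(a_plants[j]),
                    }
                )
    plants = pd.DataFrame(prow)

    by_plot = dict(tuple(plants.groupby("plot_id", sort=False)))
    frames = []
    for rec in records:
        sub = by_plot[rec.plot_id]
        applies = lodging.applies_to(rec.planting_date, design.planting_dates) if lodging else False
        r = params.rate_per_day[rec.genotype] * params.density_rate_mult.get(rec.density, 1.0)
        t0 = params.inflection_das[rec.planting_date]
        for date in dates:
            das = (date - rec.planting_date).days
            if das < 0:
                h = np.zeros(len(sub))
            else:
                h = sub.asymptote_m.to_numpy() / (1.0 + np.exp(-r * (das - t0)))
                if lodging is not None and applies:
                    sev = lodging.severity_by_density.get(rec.density, 0.0)
                    event_das = lodging.das_for(rec.planting_date, first_planting)
                    h = h * lodging.multiplier(das, event_das, sev)
            frames.append(
                pd.DataFrame(
                    {
                        "plot_id": rec.plot_id,
                        "plant": sub.plant.to_numpy(),
                        "row": sub.row.to_numpy(),
                        "date": date,
                        "das": das,
                        "height_m": h,
                    }
                )
            )
    heights = pd.concat(frames, ignore_index=True)
    pm = (
        heights.groupby(["plot_id", "date"], sort=False)
        .agg(das=("das", "first"), true_mean_m=("height_m", "mean"))
        .reset_index()
    )
    return SceneTruth(design, plants, heights, pm, terrain, records)


def canopy_radius(h: float, row_spacing_m: float) -> float:
    """Disc radius (m) for a plant of height h; capped below half the row
    spacing so the inter-row ground strip stays visible."""
    return min(0.06 + 0.4 * h, 0.45 * row_spacing_m)


def render_csm(
    design: FieldDesign,
    truth: SceneTruth,
    date: _dt.date,
    gsd_m: float = 0.0082,
    noise_sd_m: float = 0.01,
    seed: int = 0,
    margin_m: float = 0.5,
    nodata_border_px: int = 2,
    plateau_frac: float = 0.6,
    n_bins: int = 20,
) -> SurfaceRaster:
    """Render one flight date as a crop surface model raster.

    Surface = terrain plane + max over per-plant canopy discs + iid
    Gaussian noise; a NaN border ring marks the reconstruction edge.
    """
    bin_len = design.planted_length_m / n_bins
    if (bin_len / gsd_m) * (2 * design.row_spacing_m / gsd_m) < 25:
        raise ResolutionError(
            f"gsd {gsd_m} m too coarse: fewer than 25 pixels per extraction bin"
        )
    ox, oy = design.field_origin
    n_grid_rows = int(np.ceil(len(truth.records) / design.plots_per_range)) if len(truth.records) else 1
    width = design.plots_per_range * design.row_length_pitch_m
    height = n_grid_rows * design.plot_width_m
    xmin, ymin = ox - margin_m, oy - margin_m
    xmax, ymax = ox + width + margin_m, oy + height + margin_m
    ncol = int(np.ceil((xmax - xmin) / gsd_m))
    nrow = int(np.ceil((ymax - ymin) / gsd_m))
    y_origin = ymin + nrow * gsd_m

    z0, tx, ty = truth.terrain
    xc = xmin + (np.arange(ncol) + 0.5) * gsd_m
    yc = y_origin - (np.arange(nrow) + 0.5) * gsd_m
    surface = z0 + tx * (xc[None, :] - ox) + ty * (yc[:, None] - oy)
    surface = np.broadcast_to(surface, (nrow, ncol)).astype(np.float64).copy()

    canopy = np.zeros((nrow, ncol))
    hts = truth.heights[truth.heights.date == date]
    hmap = dict(zip(zip(hts.plot_id, hts.plant), hts.height_m))
    for p in truth.plants.itertuples():
        h = hmap.get((p.plot_id, p.plant), 0.0)
        if h <= 0:
            continue
        R = canopy_radius(h, design.row_spacing_m)
        c0 = max(0, int((p.x - R - xmin) / gsd_m))
        c1 = min(ncol, int((p.x + R - xmin) / gsd_m) + 1)
        r1 = min(nrow, int((y_origin - (p.y - R)) / gsd_m) + 1)
        r0 = max(0, int((y_origin - (p.y + R)) / gsd_m))
        if c0 >= c1 or r0 >= r1:
            continue
        dx = xc[c0:c1] - p.x
        dy = yc[r0:r1] - p.y
        d = np.hypot(dx[None, :], dy[:, None])
        prof = np.where(
            d <= plateau_frac * R,
            h,
            np.clip(h * (R - d) / ((1 - plateau_frac) * R), 0.0, h),
        )
        np.maximum(canopy[r0:r1, c0:c1], prof, out=canopy[r0:r1, c0:c1])
    surface += canopy
    if noise_sd_m > 0:
        rng = np.random.default_rng(seed)
        surface += rng.normal(0.0, noise_sd_m, size=surface.shape)
    if nodata_border_px > 0:
        b = nodata_border_px
        surface[:b, :] = np.nan
        surface[-b:, :] = np.nan
        surface[:, :b] = np.nan
        surface[:, -b:] = np.nan
    return SurfaceRaster(
        data=surface.astype(np.float32),
        x_origin=xmin,
        y_origin=y_origin,
        pixel_size=gsd_m,
        date=date,
        crs_epsg=design.crs_epsg,
    )


def simulate_ruler_measurements(
    truth: SceneTruth,
    date: _dt.date,
    plants_per_row: int | str = 2,
    error_sd_m: float = 0.01,
    seed: int = 0,
    plot_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ruler measurements from the middle two rows of each plot.

    ``plants_per_row=k`` draws k plants uniformly without replacement from
    each middle row; ``"all"`` measures every plant of one middle row.
    """
    rng = np.random.default_rng(seed)
    design = truth.design
    mid = (design.rows_per_plot // 2 - 1, design.rows_per_plot // 2)
    hts = truth.heights[truth.heights.date == date]
    if plot_ids is not None:
        hts = hts[hts.plot_id.isin(plot_ids)]
    out = []
    for plot_id, grp in hts.groupby("plot_id", sort=False):
        if plants_per_row == "all":
            row_grp = grp[grp.row == mid[0]]
            for t in row_grp.itertuples():
                out.append((plot_id, t.row, t.plant, t.height_m))
        else:
            k = int(plants_per_row)
            for row in mid:
                row_grp = grp[grp.row == row]
                if len(row_grp) < k:
                    raise SamplingError(
                        f"plot {plot_id} row {row}: {len(row_grp)} plants < requested {k}"
                    )
                pick = rng.choice(len(row_grp), size=k, replace=False)
                for i in pick:
                    t = row_grp.iloc[i]
                    out.append((plot_id, int(t.row), t.plant, float(t.height_m)))
    df = pd.DataFrame(out, columns=["plot_id", "row", "plant", "true_height_m"])
    df["measured_m"] = df.true_height_m + (
        rng.normal(0.0, error_sd_m, size=len(df)) if error_sd_m > 0 else 0.0
    )
    df.insert(1, "date", date)
    return df
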