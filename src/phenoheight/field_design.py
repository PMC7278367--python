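"""Factorial field-trial design and plot-boundary geometry.

Encodes a randomized complete block maize trial (genotypes x planting
dates x densities, replicated within planting date) and lays the plots out
on a regular grid, producing the world-coordinate rectangle covering the
middle two rows of each plot -- the region from which canopy height is
extracted.  All lengths are metric internally; the defaults encode the
common 15 ft row pitch (12 ft planted + 3 ft alley) with 30 in row spacing.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Polygon, box, mapping, shape

from .errors import GeometryError, InvalidDesignError

FT_M = 0.3048
IN_M = 0.0254


@dataclass
class FieldDesign:
    """Trial structure plus plot geometry parameters (meters).

    ``plots_per_range`` controls how many plots sit end-to-end along the
    row direction; the grid fills block by block, row-major.
    """

    genotypes: Sequence[str]
    planting_dates: Sequence[_dt.date]
    densities: Sequence[float]  # plants per hectare
    replicates_per_date: int = 2
    rows_per_plot: int = 4
    row_length_pitch_m: float = 15 * FT_M  # 4.572
    planted_length_m: float = 12 * FT_M  # 3.6576
    alley_m: float = 3 * FT_M  # 0.9144
    row_spacing_m: float = 30 * IN_M  # 0.762
    field_origin: tuple[float, float] = (0.0, 0.0)
    orientation_deg: float = 0.0  # rotation of the along-row axis from +x
    plots_per_range: int = 12
    crs_epsg: int | None = None

    def __post_init__(self) -> None:
        if not self.genotypes or not self.planting_dates or not self.densities:
            raise InvalidDesignError("every factor needs at least one level")
        if self.replicates_per_date < 1:
            raise InvalidDesignError("replicates_per_date must be >= 1")
        for name in ("row_length_pitch_m", "planted_length_m", "alley_m", "row_spacing_m"):
            if getattr(self, name) <= 0:
                raise InvalidDesignError(f"{name} must be > 0")
        if not math.isclose(
            self.planted_length_m + self.alley_m, self.row_length_pitch_m, rel_tol=1e-9
        ):
            raise InvalidDesignError("planted_length_m + alley_m must equal row_length_pitch_m")
        if any(d <= 0 for d in self.densities):
            raise InvalidDesignError("densities must be strictly positive")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise InvalidDesignError("duplicate genotype labels")

    @property
    def n_plots(self) -> int:
        return (
            len(self.genotypes)
            * len(self.planting_dates)
            * len(self.densities)
            * self.replicates_per_date
        )

    @property
    def plot_width_m(self) -> float:
        """Across-row footprint of a whole plot (all rows)."""
        return self.rows_per_plot * self.row_spacing_m

    def along_axis(self) -> tuple[float, float]:
        a = math.radians(self.orientation_deg)
        return (math.cos(a), math.sin(a))


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    genotype: str
    planting_date: _dt.date
    density: float
    replicate: int
    grid_row: int
    grid_col: int


@dataclass
class PlotBoundary:
    """World-coordinate rectangle over the middle two rows of one plot."""

    plot_id: str
    polygon: Polygon
    axis: tuple[float, float]  # along-row unit vector
    properties: dict = field(default_factory=dict)
    crs_epsg: int | None = None


def enumerate_plots(design: FieldDesign, seed: int) -> list[PlotRecord]:
    """Enumerate every plot of the trial with a randomized layout.

    Genotype x density combinations are completely randomized within each
    (planting date, replicate) block; blocks occupy contiguous bands of the
    plot grid.  The multiset of treatments per block is seed-independent;
    only their grid placement depends on ``seed``.
    """
    rng = np.random.default_rng(seed)
    combos = [(g, d) for g in design.genotypes for d in design.densities]
    records: list[PlotRecord] = []
    idx = 0
    for date in design.planting_dates:
        for rep in range(1, design.replicates_per_date + 1):
            order = rng.permutation(len(combos))
            for j in order:
                g, d = combos[j]
                records.append(
                    PlotRecord(
                        plot_id=f"P{idx + 1:03d}",
                        genotype=g,
                        planting_date=date,
                        density=d,
                        replicate=rep,
                        grid_row=idx // design.plots_per_range,
                        grid_col=idx % design.plots_per_range,
                    )
                )
                idx += 1
    return records


def build_plot_grid(design: FieldDesign, records: Sequence[PlotRecord]) -> list[PlotBoundary]:
    """Boundary rectangles (middle two rows, planted length) for each record.

    Grid column ``k`` maps to along-row extent
    ``[k * pitch, k * pitch + planted_length]`` from the field origin; the
    across-row extent is the 2-row strip centered in the plot's row band.
    """
    positions = [(r.grid_row, r.grid_col) for r in records]
    if len(set(positions)) != len(positions):
        raise GeometryError("duplicate grid positions among plot records")
    ox, oy = design.field_origin
    rs = design.row_spacing_m
    boundaries = []
    for rec in records:
        x0 = rec.grid_col * design.row_length_pitch_m
        x1 = x0 + design.planted_length_m
        band = rec.grid_row * design.plot_width_m
        yc = band + design.plot_width_m / 2
        poly = box(x0, yc - rs, x1, yc + rs)
        if design.orientation_deg:
            poly = affinity.rotate(poly, design.orientation_deg, origin=(0, 0))
        poly = affinity.translate(poly, ox, oy)
        boundaries.append(
            PlotBoundary(
                plot_id=rec.plot_id,
                polygon=poly,
                axis=design.along_axis(),
                properties={
                    "genotype": rec.genotype,
                    "planting_date": rec.planting_date.isoformat(),
                    "density": rec.density,
                    "replicate": rec.replicate,
                },
                crs_epsg=design.crs_epsg,
            )
        )
    return boundaries


# ---------------------------------------------------------------------------
# I/O

def records_to_frame(records: Sequence[PlotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "genotype": [r.genotype for r in records],
            "planting_date": [r.planting_date.isoformat() for r in records],
            "density": [r.density for r in records],
            "replicate": [r.replicate for r in records],
            "grid_row": [r.grid_row for r in records],
            "grid_col": [r.grid_col for r in records],
        }
    )


def write_records_csv(records: Sequence[PlotRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PlotRecord]:
    df = pd.read_csv(path)
    return [
        PlotRecord(
            plot_id=str(r.plot_id),
            genotype=str(r.genotype),
            planting_date=_dt.date.fromisoformat(r.planting_date),
            density=float(r.density),
            replicate=int(r.replicate),
            grid_row=int(r.grid_row),
            grid_col=int(r.grid_col),
        )
        for r in df.itertuples()
    ]


def write_boundaries_geojson(boundaries: Sequence[PlotBoundary], path) -> None:
    features = []
    for b in boundaries:
        props = {"plot_id": b.plot_id, "axis_x": b.axis[0], "axis_y": b.axis[1]}
        props.update(b.properties)
        features.append(
            {"type": "Feature", "geometry": mapping(b.polygon), "properties": props}
        )
    fc: dict = {"type": "FeatureCollection", "features": features}
    crs = {c for c in (b.crs_epsg for b in boundaries) if c is not None}
    if len(crs) == 1:
        epsg = crs.pop()
        fc["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:EPSG::{epsg}"}}
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


def read_boundaries_geojson(path) -> list[PlotBoundary]:
    with open(path) as fh:
        fc = json.load(fh)
    epsg = None
    name = fc.get("crs", {}).get("properties", {}).get("name", "")
    if "EPSG" in name:
        epsg = int(name.rsplit(":", 1)[-1])
    out = []
    for feat in fc["features"]:
        props = dict(feat.get("properties") or {})
        axis = (props.pop("axis_x", 1.0), props.pop("axis_y", 0.0))
        out.append(
            PlotBoundary(
                plot_id=str(props.pop("plot_id")),
                polygon=shape(feat["geometry"]),
                axis=(float(axis[0]), float(axis[1])),
                properties=props,
                crs_epsg=epsg,
            )
        )
    return out
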