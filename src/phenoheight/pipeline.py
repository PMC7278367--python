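"""End-to-end orchestration: simulate -> extract -> QC -> growth curves ->
terminal prediction -> metrics/ANOVA, with a YAML config, derived stage
seeds and a run manifest.

Stage seeds are derived as hash(master_seed, stage_name), so adding a
stage never perturbs the randomness of earlier stages.  All tabular
outputs are deterministic given the config; the manifest records a sha256
digest of every output file.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .field_design import (
    FieldDesign,
    build_plot_grid,
    enumerate_plots,
    records_to_frame,
    write_boundaries_geojson,
    write_records_csv,
)
from .growth_model import fit_plots, sample_slopes
from .height_extraction import ExtractionConfig, extract_field
from .metrics_stats import anova_partition, compute_metrics, resample_plot_means
from .synthetic_field import (
    GrowthParams,
    LodgingEvent,
    build_scene_truth,
    render_csm,
    simulate_ruler_measurements,
)
from .terminal_prediction import predict_terminal
from .timeseries_qc import DEFAULT_FACTOR, filter_heights

logger = logging.getLogger(__name__)

_DEFAULT_GENOTYPES = [f"HYB{i + 1:02d}" for i in range(12)]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str = "phenoheight_run"
    master_seed: int = 0
    # trial design
    genotypes: list[str] = field(default_factory=lambda: list(_DEFAULT_GENOTYPES))
    planting_dates: list[str] = field(default_factory=lambda: ["2018-05-14", "2018-05-21"])
    densities: list[float] = field(default_factory=lambda: [60000.0, 90000.0, 120000.0])
    replicates_per_date: int = 2
    plots_per_range: int = 12
    crs_epsg: int = 32615
    # flights: days after the first planting date
    flight_offsets_days: list[int] = field(
        default_factory=lambda: [20, 27, 34, 41, 48, 55, 62, 69]
    )
    # scene
    gsd_m: float = 0.02
    noise_sd_m: float = 0.01
    terrain: list[float] = field(default_factory=lambda: [100.0, 0.005, 0.0])
    plant_asymptote_sd_m: float = 0.05
    lodging_enabled: bool = True
    lodging_event_day: float = 48.0
    lodging_severity: dict = field(
        default_factory=lambda: {60000.0: 0.10, 90000.0: 0.20, 120000.0: 0.30}
    )
    lodging_recovery_days: float = 10.0
    # extraction
    n_bins: int = 20
    p_low: float = 3.0
    p_high: float = 97.0
    methods: list[str] = field(default_factory=lambda: ["binned_trimmed"])
    # qc
    qc_factor: float = DEFAULT_FACTOR
    # growth model
    spline_pieces: int = 20
    spline_order: int = 4
    n_slope_samples: int = 100
    # prediction
    screening_threshold: float = 0.40
    train_fraction: float = 0.25
    screen_on: str = "train"
    # ruler simulation
    ruler_plants_per_row: int = 2
    ruler_error_sd_m: float = 0.02
    ruler_reps: int = 100
    ruler_all_rows_plots: int = 18

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "lodging_severity" in d:
            d["lodging_severity"] = {float(k): float(v) for k, v in d["lodging_severity"].items()}
        return cls(**d)

    def field_design(self) -> FieldDesign:
        return FieldDesign(
            genotypes=self.genotypes,
            planting_dates=[_dt.date.fromisoformat(s) for s in self.planting_dates],
            densities=self.densities,
            replicates_per_date=self.replicates_per_date,
            plots_per_range=self.plots_per_range,
            crs_epsg=self.crs_epsg,
        )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        s: stage_seed(config.master_seed, s)
        for s in ("layout", "growth", "scene", "raster", "ruler", "split", "resample")
    }
    counts: dict = {}
    files: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        files.append(p)
        return p

    config.to_yaml(out / "config.yaml")
    files.append(out / "config.yaml")

    # stage 1: design and geometry
    design = config.field_design()
    records = enumerate_plots(design, seed=seeds["layout"])
    boundaries = build_plot_grid(design, records)
    save_csv(records_to_frame(records), "plot_records.csv")
    write_boundaries_geojson(boundaries, out / "plot_boundaries.geojson")
    files.append(out / "plot_boundaries.geojson")
    counts["plots"] = len(records)

    # stage 2: synthetic scene
    params = GrowthParams.default_for(design, seed=seeds["growth"])
    params.plant_asymptote_sd_m = config.plant_asymptote_sd_m
    lodging = (
        LodgingEvent(
            event_day=config.lodging_event_day,
            severity_by_density={float(k): float(v) for k, v in config.lodging_severity.items()},
            recovery_days=config.lodging_recovery_days,
        )
        if config.lodging_enabled
        else None
    )
    first = min(design.planting_dates)
    flight_dates = [first + _dt.timedelta(days=int(d)) for d in config.flight_offsets_days]
    truth = build_scene_truth(
        design,
        records,
        params,
        flight_dates,
        lodging=lodging,
        seed=seeds["scene"],
        terrain=tuple(config.terrain),
    )
    save_csv(truth.plot_means.assign(date=truth.plot_means.date.astype(str)), "truth_plot_means.csv")
    counts["plants"] = len(truth.plants)

    rasters = []
    for i, date in enumerate(flight_dates):
        r = render_csm(
            design,
            truth,
            date,
            gsd_m=config.gsd_m,
            noise_sd_m=config.noise_sd_m,
            seed=stage_seed(seeds["raster"], date.isoformat()),
            n_bins=config.n_bins,
        )
        p = out / f"csm_{date.isoformat()}.tif"
        r.write_geotiff(p)
        files.append(p)
        rasters.append(r)
    counts["rasters"] = len(rasters)

    # stage 3: extraction
    ex_cfg = ExtractionConfig(
        n_bins=config.n_bins,
        p_low=config.p_low,
        p_high=config.p_high,
        methods=tuple(config.methods),
    )
    heights, failures = extract_field(rasters, boundaries, ex_cfg)
    save_csv(heights, "plot_heights.csv")
    if failures:
        save_csv(pd.DataFrame(failures), "extraction_failures.csv")
    counts["extraction_records"] = len(heights)
    counts["extraction_failures"] = len(failures)

    # stage 4: QC
    binned = heights[heights.method == "binned_trimmed"].reset_index(drop=True)
    filtered, qc_report, removed = filter_heights(binned, factor=config.qc_factor)
    save_csv(filtered, "plot_heights_qc.csv")
    save_csv(qc_report, "qc_report.csv")
    save_csv(removed, "qc_removed.csv")
    counts["qc_flagged"] = int(qc_report.n_flagged.sum())

    # stage 5: growth curves and slopes.  Plots whose QC'd series no longer
    # spans the common flight window are excluded: their spline domain would
    # shrink the shared slope grid into the early season for every plot.
    full_span = binned.groupby("plot_id").days_after_sowing.agg(["min", "max"])
    spans = (
        filtered.groupby("plot_id")
        .days_after_sowing.agg(["min", "max", "count"])
        .reindex(full_span.index)
    )
    ok = spans[
        (spans["min"] == full_span["min"])
        & (spans["max"] == full_span["max"])
        & (spans["count"] >= 4)
    ].index
    usable = filtered[filtered.plot_id.isin(ok)]
    counts["plots_spanning_window"] = len(ok)
    splines = fit_plots(
        usable,
        n_pieces=config.spline_pieces,
        order=config.spline_order,
    )
    slopes = sample_slopes(splines, n=config.n_slope_samples)
    save_csv(slopes, "slopes.csv")
    counts["plots_fitted"] = len(splines)

    # stage 6: terminal prediction (terminal = extracted height on the
    # last flight; evaluated against both UAV- and ruler-derived terminals)
    last_date = flight_dates[-1].isoformat()
    terminal_uav = (
        binned[binned.date == last_date].set_index("plot_id").ph_m
    )
    common = sorted(set(slopes.plot_id) & set(terminal_uav.index))
    model, split, report, preds = predict_terminal(
        slopes[slopes.plot_id.isin(common)],
        terminal_uav.loc[common],
        threshold=config.screening_threshold,
        train_fraction=config.train_fraction,
        seed=seeds["split"],
        screen_on=config.screen_on,
    )
    model.to_json(out / "terminal_model.json")
    files.append(out / "terminal_model.json")
    save_csv(preds, "terminal_predictions.csv")
    counts["selected_timepoints"] = len(model.selected_indices)

    # stage 7: ruler comparison metrics per date + terminal ANOVA
    ruler_frames = []
    for i, date in enumerate(flight_dates):
        ruler_frames.append(
            simulate_ruler_measurements(
                truth,
                date,
                plants_per_row=config.ruler_plants_per_row,
                error_sd_m=config.ruler_error_sd_m,
                seed=stage_seed(seeds["ruler"], date.isoformat()),
            )
        )
    ruler = pd.concat(ruler_frames, ignore_index=True)
    ruler["date"] = ruler.date.astype(str)
    ruler_means = (
        ruler.groupby(["plot_id", "date"]).measured_m.mean().rename("ph_r2_m").reset_index()
    )
    save_csv(ruler_means, "ruler_plot_means.csv")
    merged = binned.merge(ruler_means, on=["plot_id", "date"])
    rows = []
    for date, grp in merged.groupby("date"):
        m = compute_metrics(grp.ph_m, grp.ph_r2_m, reference="y")
        rows.append(
            {
                "date": date,
                "n": m.n,
                "adj_r2": m.adj_r2,
                "rmse_cm": m.rmse * 100,
                "nrmse": m.nrmse,
            }
        )
    overall = compute_metrics(merged.ph_m, merged.ph_r2_m, reference="y")
    rows.append(
        {
            "date": "all",
            "n": overall.n,
            "adj_r2": overall.adj_r2,
            "rmse_cm": overall.rmse * 100,
            "nrmse": overall.nrmse,
        }
    )
    save_csv(pd.DataFrame(rows), "uav_vs_ruler_metrics.csv")

    rec_df = records_to_frame(records)
    terminal_tbl = rec_df.merge(
        ruler_means[ruler_means.date == last_date], on="plot_id"
    ).rename(columns={"ph_r2_m": "value"})
    aov = anova_partition(terminal_tbl, value_col="value")
    save_csv(aov, "anova_terminal.csv")

    # stage 8: ruler resampling error (all plants of one middle row for a
    # subset of early-planting plots, two-plant subset means, 100 reps)
    early = rec_df[rec_df.planting_date == min(config.planting_dates)]
    sub_ids = sorted(early.plot_id)[: config.ruler_all_rows_plots]
    res_rows = []
    for date in (flight_dates[2], flight_dates[5], flight_dates[-1]):
        allrow = simulate_ruler_measurements(
            truth,
            date,
            plants_per_row="all",
            error_sd_m=config.ruler_error_sd_m,
            seed=stage_seed(seeds["resample"], date.isoformat()),
            plot_ids=sub_ids,
        )
        rep = resample_plot_means(
            allrow,
            k=2,
            reps=config.ruler_reps,
            seed=stage_seed(seeds["resample"], "pairs-" + date.isoformat()),
        )
        res_rows.append(
            {
                "date": date.isoformat(),
                "n_plots": rep.n_plots,
                "adj_r2_mean": rep.adj_r2_mean,
                "rmse_mean_cm": rep.rmse_mean * 100,
                "nrmse_mean": rep.nrmse_mean,
            }
        )
    save_csv(pd.DataFrame(res_rows), "ruler_resampling.csv")

    # manifest
    manifest = {
        "phenoheight_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "counts": counts,
        "test_adj_r2_uav_terminal": report.adj_r2,
        "test_rmse_cm_uav_terminal": report.rmse * 100,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(files, key=str)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
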