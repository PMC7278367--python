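import datetime as dt

import numpy as np
import pytest

from phenoheight import (
    FieldDesign,
    GrowthParams,
    build_plot_grid,
    build_scene_truth,
    enumerate_plots,
)

PLANTING_1 = dt.date(2018, 5, 14)
PLANTING_2 = dt.date(2018, 5, 21)


def trial_design(**kw) -> FieldDesign:
    """The 12-genotype x 2-date x 3-density x 2-replicate trial."""
    defaults = dict(
        genotypes=[f"HYB{i + 1:02d}" for i in range(12)],
        planting_dates=[PLANTING_1, PLANTING_2],
        densities=[60000.0, 90000.0, 120000.0],
        replicates_per_date=2,
        plots_per_range=12,
    )
    defaults.update(kw)
    return FieldDesign(**defaults)


@pytest.fixture(scope="session")
def full_design():
    return trial_design()


@pytest.fixture(scope="session")
def full_records(full_design):
    return enumerate_plots(full_design, seed=11)


@pytest.fixture(scope="session")
def full_boundaries(full_design, full_records):
    return build_plot_grid(full_design, full_records)


@pytest.fixture(scope="session")
def flight_dates():
    """Eight roughly weekly flights spanning the season."""
    return [PLANTING_1 + dt.timedelta(days=d) for d in (20, 27, 34, 41, 48, 55, 62, 69)]


@pytest.fixture(scope="session")
def uniform_truth(full_design, full_records, flight_dates):
    """Flat terrain, zero plant-to-plant spread, no lodging: every plant of
    a plot sits exactly on the genotype's logistic curve, so the canopy
    plateau height is known exactly per plot per date."""
    params = GrowthParams.default_for(full_design, seed=5)
    params.plant_asymptote_sd_m = 0.0
    return build_scene_truth(
        full_design,
        full_records,
        params,
        flight_dates,
        lodging=None,
        seed=5,
        terrain=(100.0, 0.0, 0.0),
    )


def small_design(**kw) -> FieldDesign:
    defaults = dict(
        genotypes=["A", "B", "C"],
        planting_dates=[PLANTING_1, PLANTING_2],
        densities=[60000.0, 120000.0],
        replicates_per_date=2,
        plots_per_range=6,
    )
    defaults.update(kw)
    return FieldDesign(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
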