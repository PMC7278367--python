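"""Correlation/error metrics, ruler resampling analysis, and the
fixed-effects ANOVA variance partition.

Metrics follow the conventions used for plot-height comparisons: Pearson r
with the adjusted R² of the simple regression of y on x
(1 - (1 - r²)(n - 1)/(n - 2)), RMSE in the input units, and NRMSE = RMSE
divided by the mean of the designated reference series.  The ANOVA is an
ordinary-least-squares fixed-effects fit with sequential (type-I) sums of
squares in the order genotype, planting date, density, replicate,
genotype x date, genotype x density, date x density.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import AliasingError, InsufficientDataError, SamplingError, ZeroVarianceError


@dataclass
class MetricsReport:
    n: int
    pearson_r: float
    adj_r2: float
    rmse: float
    nrmse: float


def compute_metrics(x, y, reference: str = "y") -> MetricsReport:
    """Pairwise comparison metrics between two aligned series.

    ``reference`` ("x" or "y") names the series whose mean normalizes the
    NRMSE; it must have a positive mean for NRMSE to be defined (NaN
    otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("metrics need two equal-length series of >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InsufficientDataError("metrics require finite values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    r = float(stats.pearsonr(x, y).statistic)
    n = x.size
    adj = 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    ref_mean = float(np.mean(x if reference == "x" else y))
    nrmse = rmse / ref_mean if ref_mean > 0 else float("nan")
    return MetricsReport(n=n, pearson_r=r, adj_r2=adj, rmse=rmse, nrmse=nrmse)


@dataclass
class ResamplingReport:
    """Replicate-pair agreement of k-plant plot means re-sampled from full
    single-row measurements."""

    k: int
    reps: int
    seed: int
    n_plots: int
    skipped_plots: list[str]
    adj_r2_mean: float
    rmse_mean: float
    nrmse_mean: float
    adj_r2: np.ndarray  # per replicate (NaN where undefined)
    rmse: np.ndarray
    nrmse: np.ndarray


def resample_plot_means(
    measurements: pd.DataFrame,
    k: int = 2,
    reps: int = 100,
    seed: int = 0,
    plot_col: str = "plot_id",
    value_col: str = "measured_m",
) -> ResamplingReport:
    """Quantify the error of k-plants-per-row plot means.

    ``measurements`` holds every plant of one row per plot.  Each
    replicate draws two disjoint k-plant subsets per plot and compares the
    two resulting plot-mean vectors across plots; metrics are averaged
    over replicates.  Plots with fewer than 2k plants are skipped.
    """
    rng = np.random.default_rng(seed)
    groups, skipped = [], []
    for pid, grp in measurements.groupby(plot_col, sort=False):
        vals = grp[value_col].to_numpy(dtype=float)
        if len(vals) < 2 * k:
            skipped.append(str(pid))
            continue
        groups.append(vals)
    if len(groups) < 3:
        raise SamplingError("need >= 3 plots with at least 2k plants each")
    r2s, rmses, nrmses = [], [], []
    for _ in range(reps):
        m1, m2 = [], []
        for vals in groups:
            pick = rng.choice(len(vals), size=2 * k, replace=False)
            m1.append(vals[pick[:k]].mean())
            m2.append(vals[pick[k:]].mean())
        m1, m2 = np.asarray(m1), np.asarray(m2)
        rmse = float(np.sqrt(np.mean((m1 - m2) ** 2)))
        rmses.append(rmse)
        ref = float(np.mean(m2))
        nrmses.append(rmse / ref if ref > 0 else np.nan)
        if np.var(m1) == 0 or np.var(m2) == 0:
            r2s.append(np.nan)  # agreement undefined for a homogeneous stand
        else:
            r = float(stats.pearsonr(m1, m2).statistic)
            r2s.append(1.0 - (1.0 - r * r) * (len(m1) - 1) / (len(m1) - 2))
    r2s, rmses, nrmses = map(np.asarray, (r2s, rmses, nrmses))
    return ResamplingReport(
        k=k,
        reps=reps,
        seed=seed,
        n_plots=len(groups),
        skipped_plots=skipped,
        adj_r2_mean=float(np.nanmean(r2s)) if not np.isnan(r2s).all() else float("nan"),
        rmse_mean=float(np.mean(rmses)),
        nrmse_mean=float(np.nanmean(nrmses)),
        adj_r2=r2s,
        rmse=rmses,
        nrmse=nrmses,
    )


_TERM_LABELS = {
    "C(genotype)": "Genotype",
    "C(planting_date)": "Planting Date",
    "C(density)": "Density",
    "C(replicate)": "Replicate",
    "C(planting_date):C(replicate)": "Replicate",
    "C(genotype):C(planting_date)": "Genotype:Planting Date",
    "C(genotype):C(density)": "Genotype:Density",
    "C(planting_date):C(density)": "Planting Date:Density",
    "Residual": "Residuals",
}


def anova_partition(
    table: pd.DataFrame,
    value_col: str = "value",
    include_date_density: bool = True,
    replicate_nested: bool = False,
) -> pd.DataFrame:
    """Fixed-effects variance partition of plot heights.

    Expects columns genotype, planting_date, density, replicate plus the
    response.  Replicate is coded as a factor crossed with date (1 DF on
    a 2-replicate trial) by default; ``replicate_nested=True`` codes it
    nested within planting date (date x replicate, 2 DF) instead.
    Sequential (type-I) sums of squares; F against the residual mean
    square.  Missing factor-combination cells raise
    :class:`AliasingError` naming the cells.
    """
    df = table.copy()
    for col in ("genotype", "planting_date", "density", "replicate"):
        if col not in df.columns:
            raise InsufficientDataError(f"missing factor column {col!r}")
        if df[col].nunique() < 2:
            raise InsufficientDataError(f"factor {col!r} needs >= 2 levels")
        df[col] = df[col].astype(str)
    levels = [sorted(df[c].unique()) for c in ("genotype", "planting_date", "density", "replicate")]
    present = set(zip(df.genotype, df.planting_date, df.density, df.replicate))
    missing = [cell for cell in product(*levels) if cell not in present]
    if missing:
        raise AliasingError(f"empty design cells: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    df = df.rename(columns={value_col: "_y"})
    rep_term = "C(planting_date):C(replicate)" if replicate_nested else "C(replicate)"
    terms = [
        "C(genotype)",
        "C(planting_date)",
        "C(density)",
        rep_term,
        "C(genotype):C(planting_date)",
        "C(genotype):C(density)",
    ]
    if include_date_density:
        terms.append("C(planting_date):C(density)")
    model = smf.ols("_y ~ " + " + ".join(terms), data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = sm.stats.anova_lm(model, typ=1)
    out = aov.reset_index().rename(
        columns={"index": "term", "PR(>F)": "p", "sum_sq": "sum_sq", "df": "df"}
    )
    out["term"] = [_TERM_LABELS.get(t, t) for t in out["term"]]
    out["df"] = out["df"].astype(int)
    return out[["term", "df", "sum_sq", "F", "p"]]
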