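"""Per-date outlier screening of plot heights.

A plot height is flagged when it falls strictly outside mean ± sqrt(2)·sd
of that date's values (sample sd, n-1 denominator), computed in a single
pass -- the filter is deliberately not iterated after removal, so applying
it twice can remove more points.  Values are pooled across all treatments
within a flight date.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

DEFAULT_FACTOR = math.sqrt(2.0)


@dataclass
class QCReport:
    date: object
    n_input: int
    n_flagged: int
    mean: float
    sd: float
    lower: float
    upper: float
    flags: np.ndarray  # bool per input value


def flag_outliers(values, factor: float = DEFAULT_FACTOR, date=None) -> QCReport:
    """Flag values strictly outside mean ± factor·sd for one date."""
    vals = np.asarray(values, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise InsufficientDataError("outlier screening needs >= 2 finite values")
    mean = float(np.mean(vals[finite]))
    sd = float(np.std(vals[finite], ddof=1))
    lower, upper = mean - factor * sd, mean + factor * sd
    flags = finite & ((vals < lower) | (vals > upper))
    return QCReport(
        date=date,
        n_input=int(finite.sum()),
        n_flagged=int(flags.sum()),
        mean=mean,
        sd=sd,
        lower=lower,
        upper=upper,
        flags=flags,
    )


def apply_qc(records: pd.DataFrame, reports: dict, date_col: str = "date") -> pd.DataFrame:
    """Drop flagged records; ``reports`` maps date -> QCReport aligned to
    the records of that date in order of appearance."""
    dates = records[date_col].unique()
    missing = [d for d in dates if d not in reports]
    if missing:
        raise InsufficientDataError(f"no QC report for dates: {missing}")
    drop = np.zeros(len(records), dtype=bool)
    for d, rep in reports.items():
        idx = np.flatnonzero((records[date_col] == d).to_numpy())
        drop[idx] = rep.flags
    return records.loc[~drop].reset_index(drop=True)


def filter_heights(
    records: pd.DataFrame,
    value_col: str = "ph_m",
    date_col: str = "date",
    factor: float = DEFAULT_FACTOR,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Screen a long-format height table date by date.

    Returns (filtered records, per-date report table, removal log).
    """
    reports = {}
    for d, grp in records.groupby(date_col, sort=False):
        reports[d] = flag_outliers(grp[value_col].to_numpy(), factor=factor, date=d)
    filtered = apply_qc(records, reports, date_col=date_col)
    rep_df = pd.DataFrame(
        {
            "date": list(reports),
            "n_input": [r.n_input for r in reports.values()],
            "n_flagged": [r.n_flagged for r in reports.values()],
            "mean": [r.mean for r in reports.values()],
            "sd": [r.sd for r in reports.values()],
            "lower": [r.lower for r in reports.values()],
            "upper": [r.upper for r in reports.values()],
        }
    )
    removed_rows = []
    for d, rep in reports.items():
        grp = records[records[date_col] == d]
        removed_rows.append(grp.loc[rep.flags])
    removed = pd.concat(removed_rows) if removed_rows else records.iloc[:0]
    return filtered, rep_df, removed.reset_index(drop=True)
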