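"""Terminal-height prediction from growth-rate features.

Each of the 100 slope timepoints is screened by the fraction of terminal-
height variance it explains alone (simple-regression R²); timepoints
strictly above the threshold (default 0.40) become predictors of an
ordinary least-squares model, trained on a random quarter of the plots and
evaluated on the remaining three quarters.  Screening uses the training
split only by default so the held-out evaluation is leakage-free; a flag
allows screening on all plots instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .metrics_stats import MetricsReport, compute_metrics


@dataclass
class SplitSpec:
    train_fraction: float
    seed: int
    train_ids: list[str]
    test_ids: list[str]


@dataclass
class TerminalModel:
    selected_indices: list[int]
    intercept: float
    coefficients: np.ndarray  # one per selected timepoint
    threshold: float
    train_ids: list[str] = field(default_factory=list)
    train_adj_r2: float = float("nan")

    def predict(self, slope_matrix: np.ndarray) -> np.ndarray:
        """slope_matrix: plots x 100 timepoints (full grid)."""
        X = np.asarray(slope_matrix)[:, self.selected_indices]
        return self.intercept + X @ self.coefficients

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_indices": [int(i) for i in self.selected_indices],
                    "intercept": self.intercept,
                    "coefficients": list(map(float, self.coefficients)),
                    "threshold": self.threshold,
                    "train_ids": self.train_ids,
                    "train_adj_r2": self.train_adj_r2,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "TerminalModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            selected_indices=d["selected_indices"],
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"]),
            threshold=d["threshold"],
            train_ids=d.get("train_ids", []),
            train_adj_r2=d.get("train_adj_r2", float("nan")),
        )


def slopes_to_matrix(slopes: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pivot a long slope table to a plots x timepoints matrix."""
    wide = slopes.pivot(index="plot_id", columns="timepoint_index", values="slope_m_per_day")
    wide = wide.sort_index(axis=1)
    return wide.to_numpy(), [str(i) for i in wide.index]


def screen_timepoints(
    slope_matrix: np.ndarray, terminal: np.ndarray, threshold: float = 0.40
) -> list[int]:
    """Indices whose univariate R² against terminal height is strictly
    greater than ``threshold``; zero-variance columns are skipped."""
    X = np.asarray(slope_matrix, dtype=float)
    y = np.asarray(terminal, dtype=float)
    if X.shape[0] < 3:
        raise InsufficientDataError("screening needs >= 3 plots")
    if np.var(y) == 0:
        raise InsufficientDataError("terminal heights have zero variance")
    selected = []
    yc = y - y.mean()
    vy = float(np.var(y))
    for j in range(X.shape[1]):
        xj = X[:, j]
        vx = float(np.var(xj))
        if vx == 0:
            warnings.warn(f"timepoint {j}: zero slope variance, skipped")
            continue
        cov = float(np.dot(xj - xj.mean(), yc)) / len(y)
        r_squared = cov * cov / (vx * vy)
        if r_squared > threshold:
            selected.append(j)
    return selected


def split_plots(plot_ids: Sequence[str], train_fraction: float = 0.25, seed: int = 0) -> SplitSpec:
    """Uniform random train/test split of plots without replacement."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    ids = list(plot_ids)
    if len(ids) < 8:
        raise InsufficientDataError("split needs >= 8 plots")
    n_train = int(np.floor(train_fraction * len(ids) + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return SplitSpec(train_fraction=train_fraction, seed=seed, train_ids=train, test_ids=test)


def fit_terminal_model(
    slope_matrix: np.ndarray,
    terminal: np.ndarray,
    selected_indices: Sequence[int],
    threshold: float = 0.40,
    train_ids: Sequence[str] = (),
) -> TerminalModel:
    """OLS of terminal height on the selected slope timepoints."""
    X = np.asarray(slope_matrix, dtype=float)[:, list(selected_indices)]
    y = np.asarray(terminal, dtype=float)
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    if n <= k + 1:
        warnings.warn("fewer observations than parameters: minimum-norm fit")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        warnings.warn("collinear slope features: minimum-norm resolution")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        if n - k - 1 > 0
        else float("nan")
    )
    return TerminalModel(
        selected_indices=list(selected_indices),
        intercept=float(beta[0]),
        coefficients=beta[1:],
        threshold=threshold,
        train_ids=list(train_ids),
        train_adj_r2=adj,
    )


def evaluate_model(
    model: TerminalModel, slope_matrix: np.ndarray, terminal: np.ndarray
) -> tuple[np.ndarray, MetricsReport]:
    """Predict held-out terminal heights; metrics of predicted vs observed
    (adjusted R² from the simple regression, RMSE, NRMSE normalized by the
    observed mean)."""
    pred = model.predict(slope_matrix)
    report = compute_metrics(pred, np.asarray(terminal, dtype=float), reference="y")
    return pred, report


def predict_terminal(
    slopes: pd.DataFrame,
    terminal: pd.Series,
    threshold: float = 0.40,
    train_fraction: float = 0.25,
    seed: int = 0,
    screen_on: str = "train",
) -> tuple[TerminalModel, SplitSpec, MetricsReport, pd.DataFrame]:
    """End-to-end screen/fit/evaluate from a long slope table.

    ``terminal`` is indexed by plot_id.  ``screen_on`` is "train"
    (leakage-free default) or "all".
    """
    M, ids = slopes_to_matrix(slopes)
    terminal = terminal.loc[ids]
    split = split_plots(ids, train_fraction, seed)
    pos = {p: i for i, p in enumerate(ids)}
    itrain = [pos[p] for p in split.train_ids]
    itest = [pos[p] for p in split.test_ids]
    if screen_on == "train":
        sel = screen_timepoints(M[itrain], terminal.iloc[itrain].to_numpy(), threshold)
    elif screen_on == "all":
        sel = screen_timepoints(M, terminal.to_numpy(), threshold)
    else:
        raise ConfigurationError("screen_on must be 'train' or 'all'")
    if not sel:
        raise InsufficientDataError("no timepoint passed the screening threshold")
    model = fit_terminal_model(
        M[itrain], terminal.iloc[itrain].to_numpy(), sel, threshold, split.train_ids
    )
    pred, report = evaluate_model(model, M[itest], terminal.iloc[itest].to_numpy())
    preds = pd.DataFrame(
        {
            "plot_id": split.test_ids,
            "observed_m": terminal.iloc[itest].to_numpy(),
            "predicted_m": pred,
        }
    )
    return model, split, report, preds
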