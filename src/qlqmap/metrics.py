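"""Model-comparison machinery: summary fit statistics and diagnostics.

Mirrors the comparison table and the two visual checks used to judge
mapping models: an empirical-CDF overlay of observed versus predicted
utilities, and mean observed versus mean predicted across global health
severity bins (where the characteristic linear-model bias — too high in
poor health, too low in good health — shows up).  Plot functions return
the tabulated numbers and optionally write an image, so tests assert on
numbers rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FitMetrics", "compute_metrics", "cdf_overlay", "mean_by_severity"]


@dataclass
class FitMetrics:
    """Prediction error summaries on the utility scale."""

    mean_error: float
    mae: float
    rmse: float
    mean_predicted: float
    mean_observed: float
    absolute_difference_of_means: float


def compute_metrics(observed, predicted) -> FitMetrics:
    """ME, MAE, RMSE and mean comparisons (errors are pred - obs)."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if len(obs) == 0:
        raise ValueError("empty vectors")
    if len(obs) != len(pred):
        raise ValueError("observed and predicted lengths differ")
    err = pred - obs
    return FitMetrics(
        mean_error=float(err.mean()),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        mean_predicted=float(pred.mean()),
        mean_observed=float(obs.mean()),
        absolute_difference_of_means=float(abs(pred.mean() - obs.mean())),
    )


def _ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(values), grid, side="right") / len(values)


def cdf_overlay(
    observed,
    predictions: dict[str, np.ndarray],
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Empirical CDFs of observed and predicted utilities on a shared grid.

    Returns the tabulated curves and, per method, the maximum vertical
    gap to the observed CDF (a Kolmogorov-style summary).  Writes a PNG
    when ``out_path`` is given.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    grid = np.unique(np.concatenate(
        [obs] + [np.asarray(p, dtype=float).ravel() for p in predictions.values()]))
    table = pd.DataFrame({"utility": grid, "observed": _ecdf(obs, grid)})
    gaps: dict[str, float] = {}
    for name, pred in predictions.items():
        curve = _ecdf(np.asarray(pred, dtype=float).ravel(), grid)
        table[name] = curve
        gaps[name] = float(np.abs(curve - table["observed"].to_numpy()).max())
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        ax.step(table["utility"], table["observed"], where="post",
                label="observed", lw=2, color="black")
        for name in predictions:
            ax.step(table["utility"], table[name], where="post", label=name)
        ax.set_xlabel("EQ-5D-3L utility")
        ax.set_ylabel("cumulative probability")
        ax.legend()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return table, gaps


def mean_by_severity(
    observed,
    predicted,
    global_health,
    n_bins: int = 10,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Mean observed and predicted utility by global-health bin.

    Bins the 0-100 global health score into ``n_bins`` equal-width bins;
    empty bins appear with NaN means rather than raising.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    gh = np.asarray(global_health, dtype=float).ravel()
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(gh, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append({
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "n": int(sel.sum()),
            "mean_observed": float(obs[sel].mean()) if sel.any() else np.nan,
            "mean_predicted": float(pred[sel].mean()) if sel.any() else np.nan,
        })
    table = pd.DataFrame(rows)
    table["difference"] = table["mean_predicted"] - table["mean_observed"]
    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        centres = (table["bin_low"] + table["bin_high"]) / 2
        ax.plot(centres, table["mean_observed"], "o-", label="observed")
        ax.plot(centres, table["mean_predicted"], "s--", label="predicted")
        ax.set_xlabel("global health status")
        ax.set_ylabel("mean EQ-5D-3L utility")
        ax.legend()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return table
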