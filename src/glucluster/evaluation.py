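"""Forecast accuracy metrics and the algorithm-comparison benchmark.

Metrics follow the standard definitions over all forecast points
(t_i = truth, t-hat_i = forecast, N = number of pooled points):

    RMSE = sqrt( sum (t_i - t-hat_i)^2 / N )
    MAE  =       sum |t_i - t-hat_i|  / N
    MAPE =       sum |t_i - t-hat_i| / t_i / N      (reported as a fraction)

By default all steps of all evaluated nights are pooled into one number per
(group, horizon, algorithm); per-step resolution is kept separately as MAE
curves indexed by forecast step. A per-series averaging mode is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import forecasters as fc
from .clustering import ClusterModel, fit_cluster_model
from .exceptions import DataError
from .forecasters import HorizonSpec
from .preprocessing import SegmentSet

#: Benchmark rows mirror the published comparison: the two medoid-based
#: forecasters, Holt, global gradient boosting, and the two cluster-routed
#: ensembles.
DEFAULT_ALGORITHMS = (
    "mtsc",
    "wmtsc",
    "holt",
    "gbt_global",
    "rf_cluster",
    "gbt_cluster",
)

ALL_ALGORITHMS = DEFAULT_ALGORITHMS + ("rf_global",)


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    mape: float
    n_points: int


def compute_metrics(
    truth: np.ndarray, pred: np.ndarray, per_series: bool = False
) -> MetricsReport:
    """RMSE / MAE / MAPE pooled over every element of truth vs pred.

    With ``per_series`` the three metrics are computed per row and averaged
    across rows instead (only meaningful for 2-D input).
    """
    truth = np.asarray(truth, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if truth.shape != pred.shape:
        raise DataError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    if np.any(truth <= 0):
        raise DataError("MAPE undefined: truth contains non-positive values")
    err = truth - pred
    if per_series and truth.ndim == 2:
        rmse = float(np.mean(np.sqrt(np.mean(err**2, axis=1))))
        mae = float(np.mean(np.mean(np.abs(err), axis=1)))
        mape = float(np.mean(np.mean(np.abs(err) / truth, axis=1)))
    else:
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))
        mape = float(np.mean(np.abs(err) / truth))
    return MetricsReport(rmse=rmse, mae=mae, mape=mape, n_points=truth.size)


def per_step_mae(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Column-wise MAE across evaluated nights: one value per forecast step."""
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if truth.shape != pred.shape:
        raise DataError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    return np.mean(np.abs(truth - pred), axis=0)


def rolling_origin_mae(
    test: np.ndarray, forecast_fn, lengths: range
) -> pd.DataFrame:
    """Alternative MAE-vs-length view: forecast the last L points for each L.

    ``forecast_fn(prefixes, h)`` must return an (n, h) forecast matrix. This
    mode treats the curve's x-axis as the length of the predicted tail rather
    than the step index within a fixed horizon.
    """
    test = np.asarray(test, dtype=float)
    rows = []
    for L in lengths:
        pred = forecast_fn(test[:, :-L], L)
        rows.append({"length": L, "mae": float(np.mean(np.abs(test[:, -L:] - pred)))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkTable:
    """One row per (group, horizon, algorithm) plus per-step MAE curves."""

    table: pd.DataFrame
    per_step: pd.DataFrame
    cluster_info: dict = field(default_factory=dict)

    def to_csv(self, table_path, per_step_path=None) -> None:
        self.table.to_csv(table_path, index=False, float_format="%.6f")
        if per_step_path is not None:
            self.per_step.to_csv(per_step_path, index=False, float_format="%.6f")


def _forecast(
    algo: str,
    prefixes: np.ndarray,
    cluster_model: ClusterModel,
    models: dict,
    horizon: HorizonSpec,
) -> np.ndarray:
    if algo == "mtsc":
        return np.vstack([fc.mtsc_forecast(p, cluster_model, horizon) for p in prefixes])
    if algo == "wmtsc":
        return np.vstack([fc.wmtsc_forecast(p, cluster_model, horizon) for p in prefixes])
    if algo == "holt":
        return fc.holt_forecast_batch(prefixes, horizon)
    if algo in ("rf_global", "gbt_global"):
        return models[algo].predict(prefixes)
    if algo in ("rf_cluster", "gbt_cluster"):
        return fc.predict_cluster_routed(models[algo], prefixes)
    raise DataError(f"unknown algorithm {algo!r}")


_LEARNER_OF = {"rf": "random_forest", "gbt": "gradient_boosting"}


def run_benchmark(
    groups: dict[str, SegmentSet],
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    horizons_min: tuple[int, ...] = (15, 30),
    seed: int = 0,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
    hyperparams: dict | None = None,
    min_cluster_size: int = fc.MIN_CLUSTER_SIZE,
    stability_reps: int = 0,
    per_series: bool = False,
    holt_grid=None,
) -> BenchmarkTable:
    """Fit and score every algorithm on every glucose-pattern group/horizon.

    Each group (typically 'no_NH' and 'NH') is clustered independently on its
    full-length training series; every algorithm then forecasts each test
    night's last h readings from its first 72-h readings. ``hyperparams``
    maps learner kind to keyword overrides. Fully deterministic for a fixed
    (groups, seed, config).
    """
    hyperparams = hyperparams or {}
    holt_kwargs = {} if holt_grid is None else {"alphas": holt_grid, "betas": holt_grid}
    rows, curve_rows, cluster_info = [], [], {}
    for group in sorted(groups):
        segset = groups[group]
        train = segset.matrix("train")
        test = segset.matrix("test")
        if train.shape[0] < 2 or test.shape[0] == 0:
            raise DataError(f"group {group!r} lacks train or test segments")
        cluster_model = fit_cluster_model(
            train, k=k, k_range=k_range, stability_reps=stability_reps, seed=seed
        )
        cluster_info[group] = {
            "k": cluster_model.k,
            "silhouette": cluster_model.silhouette,
            "stability": cluster_model.stability,
            "n_train": train.shape[0],
            "n_test": test.shape[0],
        }
        for minutes in horizons_min:
            horizon = HorizonSpec(minutes)
            h = horizon.steps
            prefixes, truth = test[:, :-h], test[:, -h:]
            models: dict[str, object] = {}
            for algo in algorithms:
                kind = _LEARNER_OF.get(algo.split("_")[0])
                if algo.endswith("_global") and algo not in models:
                    models[algo] = fc.fit_global(
                        train, kind, horizon, hyperparams.get(kind), seed
                    )
                elif algo.endswith("_cluster"):
                    models[algo] = fc.fit_cluster_routed(
                        train, cluster_model, kind, horizon,
                        hyperparams.get(kind), seed, min_cluster_size,
                    )
            for algo in algorithms:
                if algo == "holt":
                    pred = fc.holt_forecast_batch(prefixes, horizon, **holt_kwargs)
                else:
                    pred = _forecast(algo, prefixes, cluster_model, models, horizon)
                report = compute_metrics(truth, pred, per_series=per_series)
                rows.append(
                    {
                        "group": group,
                        "ph_minutes": minutes,
                        "algorithm": algo,
                        "rmse": report.rmse,
                        "mae": report.mae,
                        "mape": report.mape,
                        "n_series": test.shape[0],
                        "seed": seed,
                    }
                )
                for step, value in enumerate(per_step_mae(truth, pred), start=1):
                    curve_rows.append(
                        {
                            "group": group,
                            "ph_minutes": minutes,
                            "algorithm": algo,
                            "step": step,
                            "mae": float(value),
                        }
                    )
    return BenchmarkTable(
        table=pd.DataFrame(rows),
        per_step=pd.DataFrame(curve_rows),
        cluster_info=cluster_info,
    )


def render_report(table: pd.DataFrame) -> str:
    """Plain-text benchmark table, one block per (group, horizon), with the
    per-column minimum marked by an asterisk."""
    lines = []
    for (group, ph), block in table.groupby(["group", "ph_minutes"]):
        lines.append(f"=== group={group}  PH={ph} min ===")
        mins = {m: block[m].min() for m in ("rmse", "mae", "mape")}
        lines.append(f"{'algorithm':<14}{'RMSE':>10}{'MAE':>10}{'MAPE':>10}")
        for _, row in block.iterrows():
            cells = []
            for m in ("rmse", "mae", "mape"):
                mark = "*" if np.isclose(row[m], mins[m]) else " "
                cells.append(f"{row[m]:>9.3f}{mark}")
            lines.append(f"{row['algorithm']:<14}" + "".join(cells))
        lines.append("")
    return "\n".join(lines)
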