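"""Short-horizon nocturnal glucose forecasters.

Five families, all forecasting the last h readings of a 72-point night from
its first 72-h readings (h = 3 or 6 steps for the 15/30-min horizons):

* **MTSC** — medoids of time-series clusters: copy the next h components of
  the nearest cluster medoid.
* **WMTSC** — weighted MTSC: a softmax-of-inverse-distance weighted sum of
  every medoid's continuation, so the forecast is a convex combination of
  all typical night patterns rather than a single one.
* **Cluster-routed ensembles** — one supervised multi-output regressor
  (random forest or gradient-boosted trees) per cluster, trained on that
  cluster's members only; at prediction time the night is routed to the
  nearest medoid's model.
* **Global ensembles** — the same regressors trained on the whole training
  panel, without pre-clustering.
* **Holt** — double exponential smoothing (level + trend, no seasonal term)
  fitted per night by grid search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.multioutput import MultiOutputRegressor

from .clustering import ClusterModel, assign_nearest_cluster
from .exceptions import ConfigurationError, DataError

LEARNER_KINDS = ("random_forest", "gradient_boosting")

#: Default ensemble hyperparameters (tunable on the validation split).
DEFAULT_HYPERPARAMS = {
    "random_forest": {"n_estimators": 300, "max_depth": None},
    "gradient_boosting": {"n_estimators": 300, "max_depth": 3, "learning_rate": 0.1},
}

#: Clusters smaller than this fall back to the global learner.
MIN_CLUSTER_SIZE = 10


@dataclass(frozen=True)
class HorizonSpec:
    """Prediction horizon: h = minutes / 5 forecast steps."""

    minutes: int

    def __post_init__(self) -> None:
        if self.minutes <= 0 or self.minutes % 5 != 0:
            raise ConfigurationError("horizon must be a positive multiple of 5 min")

    @property
    def steps(self) -> int:
        return self.minutes // 5


@dataclass(frozen=True)
class ClusterAssignment:
    """Distances to all medoids and the derived softmax weights."""

    distances: np.ndarray  # d'
    inverse_distances: np.ndarray  # d = 1/d'
    weights: np.ndarray  # omega = softmax(d)
    nearest: int  # argmin of d', 1-based


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def cluster_weights(
    prefix: np.ndarray, model: ClusterModel, zero_eps: float = 1e-12
) -> ClusterAssignment:
    """Softmax-of-inverse-distance weights of a prefix over all medoids.

    d' holds Euclidean distances from the prefix to each medoid prefix,
    d = 1/d' elementwise, and the weights are softmax(d). An exact match
    (d' <= zero_eps) short-circuits: weight 1 on the matching medoid, shared
    uniformly if several match exactly.
    """
    nearest, d_prime = assign_nearest_cluster(prefix, model)
    zero = d_prime <= zero_eps
    if zero.any():
        weights = zero.astype(float) / zero.sum()
        with np.errstate(divide="ignore"):
            inv = np.where(zero, np.inf, 1.0 / d_prime)
    else:
        inv = 1.0 / d_prime
        weights = _softmax(inv)
    return ClusterAssignment(d_prime, inv, weights, nearest)


# ---------------------------------------------------------------------------
# Medoid-based forecasters
# ---------------------------------------------------------------------------

def _check_prefix(prefix: np.ndarray, model: ClusterModel, horizon: HorizonSpec) -> np.ndarray:
    prefix = np.asarray(prefix, dtype=float)
    h = horizon.steps
    if h >= model.series_length:
        raise ConfigurationError("horizon must be shorter than the series")
    if len(prefix) != model.series_length - h:
        raise DataError(
            f"prefix length {len(prefix)} != series length {model.series_length} - h {h}"
        )
    return prefix


def mtsc_forecast(
    prefix: np.ndarray, model: ClusterModel, horizon: HorizonSpec
) -> np.ndarray:
    """Copy the next h components of the nearest cluster medoid."""
    prefix = _check_prefix(prefix, model, horizon)
    nearest, _ = assign_nearest_cluster(prefix, model)
    return model.medoid_series[nearest - 1, -horizon.steps :].copy()


def wmtsc_forecast(
    prefix: np.ndarray, model: ClusterModel, horizon: HorizonSpec
) -> np.ndarray:
    """Softmax-weighted sum of all medoid continuations.

    forecast = omega . M where row i of M is medoid i's last h components and
    omega = softmax(1/d'). The output is therefore always inside the
    componentwise [min, max] envelope of the medoid continuations.
    """
    prefix = _check_prefix(prefix, model, horizon)
    assignment = cluster_weights(prefix, model)
    continuations = model.medoid_series[:, -horizon.steps :]
    return assignment.weights @ continuations


# ---------------------------------------------------------------------------
# Supervised ensembles (global and cluster-routed)
# ---------------------------------------------------------------------------

def _make_learner(kind: str, seed: int, hyperparams: dict | None):
    params = dict(DEFAULT_HYPERPARAMS.get(kind, {}))
    if hyperparams:
        params.update(hyperparams)
    if kind == "random_forest":
        # Random forests are natively multi-output.
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if kind == "gradient_boosting":
        # Boosting is single-output; one boosted model per forecast step.
        return MultiOutputRegressor(
            GradientBoostingRegressor(random_state=seed, loss="squared_error", **params),
            n_jobs=1,
        )
    raise ConfigurationError(f"unknown learner kind {kind!r}")


def _features_targets(series: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray]:
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise DataError("training series must be a 2-D matrix")
    if h >= series.shape[1]:
        raise ConfigurationError("horizon must be shorter than the series")
    return series[:, :-h], series[:, -h:]


@dataclass
class GlobalForecastModel:
    """One multi-output regressor over the whole training panel."""

    estimator: object
    learner_kind: str
    horizon: HorizonSpec
    series_length: int
    seed: int

    def predict(self, prefixes: np.ndarray) -> np.ndarray:
        prefixes = np.atleast_2d(np.asarray(prefixes, dtype=float))
        if prefixes.shape[1] != self.series_length - self.horizon.steps:
            raise DataError("prefix length mismatch")
        pred = np.asarray(self.estimator.predict(prefixes))
        return pred.reshape(prefixes.shape[0], self.horizon.steps)


def fit_global(
    train: np.ndarray,
    learner_kind: str,
    horizon: HorizonSpec,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> GlobalForecastModel:
    """Fit one regressor mapping the first 72-h values to the last h values
    of every training night (direct multi-output strategy)."""
    train = np.asarray(train, dtype=float)
    if train.shape[0] == 0:
        raise DataError("empty training set")
    X, y = _features_targets(train, horizon.steps)
    est = _make_learner(learner_kind, seed, hyperparams)
    est.fit(X, y)
    return GlobalForecastModel(est, learner_kind, horizon, train.shape[1], seed)


@dataclass
class ClusterRoutedModel:
    """One supervised learner per cluster, with nearest-medoid routing.

    Clusters with fewer than ``min_cluster_size`` members have no dedicated
    learner and route to the ``fallback`` global model.
    """

    cluster_model: ClusterModel
    learners: dict[int, object]
    learner_kind: str
    horizon: HorizonSpec
    fallback: GlobalForecastModel | None
    min_cluster_size: int = MIN_CLUSTER_SIZE
    seed: int = 0

    @property
    def series_length(self) -> int:
        return self.cluster_model.series_length


def fit_cluster_routed(
    train: np.ndarray,
    cluster_model: ClusterModel,
    learner_kind: str,
    horizon: HorizonSpec,
    hyperparams: dict | None = None,
    seed: int = 0,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> ClusterRoutedModel:
    """Fit one multi-output regressor per cluster of the training panel.

    ``train`` must be the matrix the cluster model was fitted on (row order
    matching ``cluster_model.labels``). Undersized clusters fall back to a
    global model of the same learner kind.
    """
    train = np.asarray(train, dtype=float)
    if train.shape[0] != len(cluster_model.labels):
        raise DataError("training matrix does not match cluster labels")
    h = horizon.steps
    learners: dict[int, object] = {}
    need_fallback = False
    for lab in range(1, cluster_model.k + 1):
        idx = np.flatnonzero(cluster_model.labels == lab)
        if len(idx) == 0:
            raise DataError(f"cluster {lab} is empty")
        if len(idx) < min_cluster_size:
            need_fallback = True
            continue
        X, y = _features_targets(train[idx], h)
        est = _make_learner(learner_kind, seed, hyperparams)
        est.fit(X, y)
        learners[lab] = est
    fallback = (
        fit_global(train, learner_kind, horizon, hyperparams, seed)
        if need_fallback
        else None
    )
    return ClusterRoutedModel(
        cluster_model, learners, learner_kind, horizon, fallback,
        min_cluster_size, seed,
    )


def predict_cluster_routed(
    model: ClusterRoutedModel, prefixes: np.ndarray
) -> np.ndarray:
    """Route each prefix to its nearest medoid's learner and predict.

    Accepts a single prefix (1-D) or a stack of prefixes (2-D); returns
    forecasts of matching shape.
    """
    arr = np.asarray(prefixes, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    h = model.horizon.steps
    if arr.shape[1] != model.series_length - h:
        raise DataError("prefix length mismatch")
    routes = np.array(
        [assign_nearest_cluster(p, model.cluster_model)[0] for p in arr]
    )
    out = np.empty((arr.shape[0], h))
    for lab in np.unique(routes):
        idx = np.flatnonzero(routes == lab)
        learner = model.learners.get(int(lab))
        if learner is None:
            out[idx] = model.fallback.predict(arr[idx])
        else:
            out[idx] = np.asarray(learner.predict(arr[idx])).reshape(len(idx), h)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Holt double exponential smoothing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HoltParams:
    """Smoothing weights and optional explicit initial state.

    When ``level_init``/``trend_init`` are None the classical initialization
    l1 = y1, b1 = y2 - y1 is used.
    """

    alpha: float
    beta: float
    level_init: float | None = None
    trend_init: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.beta <= 1):
            raise ConfigurationError("alpha and beta must lie in (0, 1]")


def _holt_state(y: np.ndarray, alpha: float, beta: float,
                level_init: float | None, trend_init: float | None) -> tuple[float, float]:
    level = y[0] if level_init is None else level_init
    trend = (y[1] - y[0]) if trend_init is None else trend_init
    for t in range(1, len(y)):
        prev = level
        level = alpha * y[t] + (1 - alpha) * (level + trend)
        trend = beta * (level - prev) + (1 - beta) * trend
    return level, trend


def holt_forecast(
    prefix: np.ndarray, params: HoltParams, horizon: HorizonSpec
) -> np.ndarray:
    """Holt's linear-trend forecast of the next h steps.

    Recursions l_t = a*y_t + (1-a)(l_{t-1} + b_{t-1}),
    b_t = B(l_t - l_{t-1}) + (1-B) b_{t-1}; forecast y-hat_{T+j} = l_T + j b_T.
    Nocturnal 6-h windows carry no seasonal cycle, so no seasonal term.
    """
    y = np.asarray(prefix, dtype=float)
    if len(y) < 2:
        raise DataError("Holt needs at least 2 observations")
    level, trend = _holt_state(y, params.alpha, params.beta,
                               params.level_init, params.trend_init)
    return level + np.arange(1, horizon.steps + 1) * trend


DEFAULT_HOLT_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))


def holt_fit(
    prefix: np.ndarray,
    alphas: Sequence[float] = DEFAULT_HOLT_GRID,
    betas: Sequence[float] = DEFAULT_HOLT_GRID,
    tie_tol: float = 1e-12,
) -> HoltParams:
    """Grid-search (alpha, beta) minimizing in-sample one-step-ahead SSE.

    SSE values within ``tie_tol`` of the minimum count as tied and resolve to
    the smallest alpha, then the smallest beta (so a constant series, where
    every grid point fits perfectly, returns the smallest grid values). The
    recursion is evaluated for the whole grid simultaneously.
    """
    y = np.asarray(prefix, dtype=float)
    if len(y) < 2:
        raise DataError("Holt needs at least 2 observations")
    alphas = np.asarray(sorted(alphas), dtype=float)
    betas = np.asarray(sorted(betas), dtype=float)
    if alphas.size == 0 or betas.size == 0:
        raise ConfigurationError("empty Holt grid")
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    level = np.full_like(A, y[0])
    trend = np.full_like(A, y[1] - y[0])
    sse = np.zeros_like(A)
    for t in range(1, len(y)):
        one_step = level + trend
        sse += (y[t] - one_step) ** 2
        new_level = A * y[t] + (1 - A) * one_step
        trend = B * (new_level - level) + (1 - B) * trend
        level = new_level
    tied = np.argwhere(sse <= sse.min() + tie_tol)
    i, j = tied[0]  # row-major scan: smallest alpha first, then smallest beta
    return HoltParams(alpha=float(alphas[i]), beta=float(betas[j]))


def holt_forecast_batch(
    prefixes: np.ndarray,
    horizon: HorizonSpec,
    alphas: Sequence[float] = DEFAULT_HOLT_GRID,
    betas: Sequence[float] = DEFAULT_HOLT_GRID,
) -> np.ndarray:
    """Per-series grid-searched Holt forecasts for a stack of prefixes."""
    prefixes = np.atleast_2d(np.asarray(prefixes, dtype=float))
    out = np.empty((prefixes.shape[0], horizon.steps))
    for i, y in enumerate(prefixes):
        out[i] = holt_forecast(y, holt_fit(y, alphas, betas), horizon)
    return out


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

BUNDLE_VERSION = 1


def save_model(model, path) -> None:
    """Persist any fitted forecaster as a versioned joblib bundle."""
    joblib.dump({"version": BUNDLE_VERSION, "model": model}, path)


def load_model(path):
    bundle = joblib.load(path)
    if bundle.get("version") != BUNDLE_VERSION:
        raise DataError(f"unsupported model bundle version {bundle.get('version')}")
    return bundle["model"]
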