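"""Dual 10-fold cross-validation and the MSE-R2 / sRMSE metrics.

Two fold-making schemes probe different questions: *conventional* CV
randomly partitions monitoring sites and measures performance at random
locations; *spatially clustered* CV uses k-means clusters of site
coordinates as folds and measures extrapolation far from monitors.  Within
each fold, everything that learns from data — forward selection, PLS,
covariance estimation — is re-fit on the training sites only, so no
information leaks into the held-out predictions.  Metrics are computed over
the pooled held-out predictions on the native concentration scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .model import PLSUniversalKriging


def mse_r2(obs: np.ndarray, pred: np.ndarray) -> float:
    """1 - SSE / SST about the observation mean.

    Measures fit of predictions to the 1:1 line (not the regression line);
    can be negative when predictions are worse than the mean.
    """
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("constant observations: MSE-R2 undefined")
    sse = float(np.sum((pred - obs) ** 2))
    return 1.0 - sse / sst


def srmse(obs: np.ndarray, pred: np.ndarray) -> float:
    """RMSE divided by the mean observed concentration (unitless)."""
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    mean_obs = float(obs.mean())
    if mean_obs <= 0.0:
        raise ValueError("sRMSE requires a positive mean observation")
    return float(np.sqrt(np.mean((pred - obs) ** 2))) / mean_obs


def make_folds(coords: np.ndarray, scheme: str, k_folds: int = 10,
               seed: int = 0, max_retries: int = 5) -> np.ndarray:
    """Assign each site to a fold in 0..k_folds-1.

    conventional: seeded random partition with sizes differing by at most 1.
    clustered: k-means on the site coordinates, one cluster per fold
    (cluster sizes are unequal by nature).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    if n < k_folds:
        raise ValueError(f"{n} sites cannot form {k_folds} folds")
    if scheme == "conventional":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = np.arange(n) % k_folds
        return folds
    if scheme == "clustered":
        for attempt in range(max_retries):
            km = KMeans(n_clusters=k_folds, n_init=50, random_state=seed + attempt)
            labels = km.fit_predict(coords)
            if len(np.unique(labels)) == k_folds:
                return labels
        raise RuntimeError(f"k-means produced an empty cluster {max_retries} times")
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class CVReport:
    """Fold assignments, pooled held-out predictions, and summary metrics."""

    scheme: str
    fold_of_site: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    mse_r2: float
    srmse: float
    n_predictors: int | None
    k_pls: int
    seed: int

    def recompute_metrics(self) -> tuple[float, float]:
        return mse_r2(self.observed, self.predicted), srmse(self.observed, self.predicted)

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": self.fold_of_site,
            "observed": self.observed,
            "predicted": self.predicted,
        })

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("fold_of_site", "observed", "predicted"):
            d[key] = np.asarray(d[key]).tolist()
        return json.dumps(d)

    def save(self, json_path, predictions_csv=None) -> None:
        with open(json_path, "w") as fh:
            fh.write(self.to_json())
        if predictions_csv is not None:
            self.predictions_frame().to_csv(predictions_csv, index=False)


def cross_validate(features: np.ndarray, y_native: np.ndarray, coords: np.ndarray,
                   scheme: str = "conventional", k_pls: int = 2,
                   n_predictors: int | None = None, seed: int = 0,
                   k_folds: int = 10, metric: str = "euclidean",
                   estimator_kwargs: dict | None = None) -> CVReport:
    """10-fold CV of the full PLS-UK pipeline.

    The sqrt transform, forward selection, PLS and covariance fit all happen
    inside each fold on training sites only; held-out predictions are pooled
    and scored on the native scale.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    y_native = np.asarray(y_native, dtype=float).ravel()
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if not (len(features) == len(y_native) == len(coords)):
        raise ValueError("features, y and coords must be aligned")
    folds = make_folds(coords, scheme, k_folds=k_folds, seed=seed)
    X = np.hstack([coords, features])
    predicted = np.full(len(y_native), np.nan)
    for f in range(k_folds):
        test = folds == f
        train = ~test
        if train.sum() < 10:
            raise ValueError(
                f"fold {f} leaves only {train.sum()} training sites; use fewer folds"
            )
        est = PLSUniversalKriging(
            n_components=k_pls, max_predictors=n_predictors, metric=metric,
            sqrt_y=True, **(estimator_kwargs or {}),
        )
        est.fit(X[train], y_native[train])
        predicted[test] = est.predict(X[test])
    assert np.all(np.isfinite(predicted))
    return CVReport(
        scheme=scheme, fold_of_site=folds, observed=y_native, predicted=predicted,
        mse_r2=mse_r2(y_native, predicted), srmse=srmse(y_native, predicted),
        n_predictors=n_predictors, k_pls=k_pls, seed=seed,
    )


def sweep_n_predictors(features, y_native, coords, grid,
                       schemes=("conventional", "clustered"), k_pls: int = 2,
                       seed: int = 0, k_folds: int = 10,
                       metric: str = "euclidean",
                       estimator_kwargs: dict | None = None) -> pd.DataFrame:
    """CV performance as a function of the number of selected predictors.

    Returns a tidy table (n_predictors, scheme, mse_r2, srmse, seed) suitable
    for plotting the overfitting curve: performance typically peaks at a few
    tens of predictors and degrades beyond.
    """
    grid = list(grid)
    if grid != sorted(grid):
        raise ValueError("grid must be sorted ascending")
    rows = []
    for n_pred in grid:
        for scheme in schemes:
            report = cross_validate(
                features, y_native, coords, scheme=scheme, k_pls=k_pls,
                n_predictors=n_pred, seed=seed, k_folds=k_folds, metric=metric,
                estimator_kwargs=estimator_kwargs,
            )
            rows.append({"n_predictors": n_pred, "scheme": scheme,
                         "mse_r2": report.mse_r2, "srmse": report.srmse,
                         "seed": seed})
    return pd.DataFrame(rows)
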