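"""PLS dimension reduction and the combined PLS + universal-kriging model.

The mean structure of the kriging model is not built on the raw ~hundreds of
buffer covariates but on a handful (2-3) of partial-least-squares summary
scores, which maximise covariance with the sqrt-scale concentrations.  The
full pipeline is:

    features -> (optional forward selection) -> standardise -> PLS scores
             -> universal kriging on sqrt scale -> back-transform

`PLSUniversalKriging` is a scikit-learn regressor; its X packs coordinates
into the first two columns and the predictor variables after them, so it
composes with `FeatureExtractor` and sklearn model selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_is_fitted

from .kriging import UniversalKriging
from .qc import back_transform, sqrt_transform


class DegenerateFitError(ValueError):
    """Raised when the response carries no signal for PLS (X'y ~ 0)."""


@dataclass
class PLSModel:
    """Univariate-response PLS fit: centring/scaling plus weight, loading
    and rotation matrices.  ``transform`` maps new data to score space via
    the rotation matrix R = W (P'W)^{-1}."""

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    weights: np.ndarray      # variables x k
    loadings: np.ndarray     # variables x k
    y_loadings: np.ndarray   # k
    rotations: np.ndarray    # variables x k
    scores_train: np.ndarray  # sites x k

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.atleast_2d(np.asarray(X, float)) - self.x_mean) / self.x_scale
        return Xc @ self.rotations


def drop_constant_columns(X: np.ndarray, names=None):
    """Remove zero-variance columns (with a warning); returns (X, kept_idx)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = X.std(axis=0) > 0.0
    if not keep.all():
        dropped = (np.asarray(names, dtype=object)[~keep].tolist()
                   if names is not None else int((~keep).sum()))
        warnings.warn(f"dropping constant predictor columns: {dropped}")
    return X[:, keep], np.flatnonzero(keep)


def fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> PLSModel:
    """Fit univariate-response PLS (NIPALS) with k components.

    X is centred and scaled to unit variance first.  The first weight vector
    is proportional to Xc'y; later components act on the deflated matrix, so
    successive score columns are mutually orthogonal on the training data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if k < 1:
        raise ValueError("need at least one PLS component")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    if np.any(x_scale == 0.0):
        raise ValueError("constant columns must be dropped before PLS")
    Xc = (X - x_mean) / x_scale
    yc = y - y.mean()
    cross = Xc.T @ yc
    if np.linalg.norm(cross) <= 1e-12 * max(np.linalg.norm(yc), 1.0):
        raise DegenerateFitError("response is orthogonal to every predictor column")
    rank = np.linalg.matrix_rank(Xc)
    if k > rank:
        raise ValueError(f"k={k} exceeds rank of centred X ({rank})")
    pls = PLSRegression(n_components=k, scale=False)  # scaling done here
    pls.fit(Xc, yc)
    return PLSModel(
        n_components=k,
        x_mean=x_mean, x_scale=x_scale,
        weights=pls.x_weights_.copy(),
        loadings=pls.x_loadings_.copy(),
        y_loadings=pls.y_loadings_.ravel().copy(),
        rotations=pls.x_rotations_.copy(),
        scores_train=pls.x_scores_.copy(),
    )


class PLSUniversalKriging(RegressorMixin, BaseEstimator):
    """Land-use-regression model: PLS scores as the universal-kriging mean.

    Parameters
    ----------
    n_components : int
        Number of PLS summary predictors (2 or 3 in practice).
    max_predictors : int or None
        When set, greedy forward selection (highest correlation, then
        highest partial F) keeps only this many raw variables before PLS.
    metric : {"euclidean", "greatcircle"}
        Distance metric for the kriging covariance.
    sqrt_y : bool
        Fit on sqrt-transformed concentrations and back-transform
        predictions (clamping negative sqrt-scale values at 0).
    theta : tuple or None
        Fixed (nugget, sigma2, range_km); None means profile-ML estimation.

    Fitted attributes: ``pls_`` (PLSModel), ``uk_`` (UniversalKriging),
    ``selected_idx_`` (column indices kept by selection, into the feature
    block of X), ``kept_idx_`` (non-constant columns within the selection).
    """

    def __init__(self, n_components=2, max_predictors=None, metric="euclidean",
                 sqrt_y=True, theta=None, reml=False, n_restarts=3,
                 optimizer_maxiter=200, pollutant=None, year=None):
        self.n_components = n_components
        self.max_predictors = max_predictors
        self.metric = metric
        self.sqrt_y = sqrt_y
        self.theta = theta
        self.reml = reml
        self.n_restarts = n_restarts
        self.optimizer_maxiter = optimizer_maxiter
        self.pollutant = pollutant
        self.year = year

    def _split(self, X):
        if hasattr(X, "columns"):
            names = [str(c) for c in X.columns[2:]]
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            names = [f"x{j}" for j in range(X.shape[1] - 2)]
        return X[:, :2], X[:, 2:], names

    def fit(self, X, y):
        from .selection import forward_select  # local: avoids module cycle

        coords, features, names = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        y_work = sqrt_transform(y) if self.sqrt_y else y

        if self.max_predictors is not None and self.max_predictors < features.shape[1]:
            path = forward_select(features, y_work, self.max_predictors,
                                  variable_names=names)
            self.selected_idx_ = np.asarray(path.indices, dtype=int)
        else:
            self.selected_idx_ = np.arange(features.shape[1])
        sel = features[:, self.selected_idx_]
        sel_names = [names[i] for i in self.selected_idx_]
        sel, kept = drop_constant_columns(sel, sel_names)
        self.kept_idx_ = kept
        self.variable_names_ = [sel_names[i] for i in kept]
        self.input_variable_names_ = names

        k = min(self.n_components, np.linalg.matrix_rank(sel - sel.mean(axis=0)))
        self.pls_ = fit_pls(sel, y_work, k)
        scores = self.pls_.scores_train
        self.uk_ = UniversalKriging(
            metric=self.metric, theta=self.theta, reml=self.reml,
            n_restarts=self.n_restarts, optimizer_maxiter=self.optimizer_maxiter,
        ).fit(np.hstack([coords, scores]), y_work)
        self.n_features_in_ = X.shape[1]
        self._n_raw_features_ = features.shape[1]
        return self

    def predict(self, X, return_std: bool = False):
        """Native-scale concentration predictions (kriging SD on sqrt scale)."""
        check_is_fitted(self, "uk_")
        coords, features, names = self._split(X)
        if features.shape[1] != self._n_raw_features_:
            raise ValueError(
                f"expected {self._n_raw_features_} predictor columns, got "
                f"{features.shape[1]}; columns must align with training order"
            )
        sel = features[:, self.selected_idx_][:, self.kept_idx_]
        scores = self.pls_.transform(sel)
        out = self.uk_.predict(np.hstack([coords, scores]), return_std=return_std)
        if return_std:
            mean, std = out
        else:
            mean = out
        if self.sqrt_y:
            mean = back_transform(mean)
        return (mean, std) if return_std else mean

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "uk_")
        st = self.uk_._state_
        payload = {
            "meta": {
                "pollutant": self.pollutant, "year": self.year,
                "n_components": int(self.pls_.n_components),
                "metric": self.metric, "sqrt_y": bool(self.sqrt_y),
                "variable_names": self.variable_names_,
                "input_variable_names": self.input_variable_names_,
                "n_raw_features": int(self._n_raw_features_),
            },
            "selection": {
                "selected_idx": self.selected_idx_.tolist(),
                "kept_idx": self.kept_idx_.tolist(),
            },
            "pls": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in asdict(self.pls_).items()},
            "uk": {
                "theta": [float(self.uk_.nugget_), float(self.uk_.partial_sill_),
                          float(self.uk_.range_km_)],
                "coords": st.coords.tolist(),
                "scores": st.F[:, 1:].tolist(),  # design minus intercept
                "y": st.y.tolist(),
            },
        }
        return json.dumps(payload)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PLSUniversalKriging":
        payload = json.loads(text)
        meta = payload["meta"]
        est = cls(n_components=meta["n_components"], metric=meta["metric"],
                  sqrt_y=meta["sqrt_y"], theta=tuple(payload["uk"]["theta"]),
                  pollutant=meta["pollutant"], year=meta["year"])
        est.selected_idx_ = np.asarray(payload["selection"]["selected_idx"], dtype=int)
        est.kept_idx_ = np.asarray(payload["selection"]["kept_idx"], dtype=int)
        est.variable_names_ = list(meta["variable_names"])
        est.input_variable_names_ = list(meta["input_variable_names"])
        est._n_raw_features_ = int(meta["n_raw_features"])
        pls_kwargs = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in payload["pls"].items()
        }
        est.pls_ = PLSModel(**pls_kwargs)
        coords = np.asarray(payload["uk"]["coords"], dtype=float)
        scores = np.asarray(payload["uk"]["scores"], dtype=float)
        y = np.asarray(payload["uk"]["y"], dtype=float)
        # refitting with theta fixed reproduces beta (GLS) and the kriging state
        est.uk_ = UniversalKriging(metric=meta["metric"],
                                   theta=tuple(payload["uk"]["theta"]))
        est.uk_.fit(np.hstack([coords, scores]), y)
        return est

    @classmethod
    def load(cls, path) -> "PLSUniversalKriging":
        with open(path) as fh:
            return cls.from_json(fh.read())
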