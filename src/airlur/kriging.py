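"""Universal kriging with an exponential covariance, fit by profile maximum
likelihood.

Model: y = F beta + e, with Cov(e_i, e_j) = sigma2 * exp(-d_ij / range) +
nugget * 1[i == j].  For fixed covariance parameters theta = (nugget,
sigma2, range), beta has the closed-form generalised-least-squares solution,
so the likelihood is profiled over beta and maximised over log-theta only
(the log parameterisation keeps the optimiser unconstrained; the surface is
multi-modal, hence variogram-guided multi-start).

`UniversalKriging` is a scikit-learn regressor whose design matrix X packs
the site coordinates in the first two columns and the mean covariates (e.g.
PLS scores) in the rest; an intercept is always added internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .geo import pairwise_km

#: NLL returned when the covariance matrix is numerically singular
_SINGULAR_PENALTY = 1e12
_LOG2PI = np.log(2.0 * np.pi)


def exponential_covariance(dist: np.ndarray, sigma2: float, range_km: float) -> np.ndarray:
    """C(h) = sigma2 * exp(-h / range); the nugget is added separately."""
    if range_km <= 0:
        raise ValueError("range must be positive")
    return sigma2 * np.exp(-np.asarray(dist, float) / range_km)


def _design(F: np.ndarray) -> np.ndarray:
    """Prepend an intercept column."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    return np.hstack([np.ones((F.shape[0], 1)), F])


def _profile_nll(theta: tuple[float, float, float], F: np.ndarray, y: np.ndarray,
                 D: np.ndarray, reml: bool = False):
    """Gaussian negative log-likelihood with beta profiled out by GLS.

    Returns (nll, beta_hat, cho_factor) so callers can reuse the
    factorisation; on a singular covariance returns a large penalty.
    """
    nugget, sigma2, range_km = theta
    n, p = F.shape
    sigma = exponential_covariance(D, sigma2, range_km)
    sigma[np.diag_indices_from(sigma)] += nugget
    try:
        cho = linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError:
        return _SINGULAR_PENALTY, None, None
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    si_F = linalg.cho_solve(cho, F)
    si_y = linalg.cho_solve(cho, y)
    FtSiF = F.T @ si_F
    try:
        beta = linalg.solve(FtSiF, F.T @ si_y, assume_a="pos")
    except linalg.LinAlgError:
        return _SINGULAR_PENALTY, None, None
    r = y - F @ beta
    quad = float(r @ linalg.cho_solve(cho, r))
    nll = 0.5 * (n * _LOG2PI + logdet + quad)
    if reml:
        sign, logdet_FtSiF = np.linalg.slogdet(FtSiF)
        if sign <= 0:
            return _SINGULAR_PENALTY, None, None
        nll += 0.5 * (logdet_FtSiF - p * _LOG2PI)
    return nll, beta, cho


def negative_log_likelihood(theta, F, y, coords, metric: str = "euclidean",
                            reml: bool = False) -> float:
    """Profile NLL at theta = (nugget, sigma2, range_km).

    F is the mean design *without* intercept (one is added), coords are site
    locations under the chosen metric.
    """
    nugget, sigma2, range_km = theta
    if nugget < 0 or sigma2 < 0 or range_km <= 0:
        raise ValueError("theta out of domain: need nugget, sigma2 >= 0 and range > 0")
    Fd = _design(F)
    y = np.asarray(y, dtype=float)
    D = pairwise_km(coords, metric=metric)
    nll, _, _ = _profile_nll((nugget, sigma2, range_km), Fd, y, D, reml=reml)
    return float(nll)


@dataclass
class _FitState:
    """Everything needed to krige at new locations."""

    beta: np.ndarray
    cho: tuple
    si_resid: np.ndarray  # Sigma^{-1} (y - F beta)
    FtSiF_inv: np.ndarray
    F: np.ndarray
    y: np.ndarray
    coords: np.ndarray


def _variogram_starts(y_resid: np.ndarray, D: np.ndarray) -> list[tuple[float, float, float]]:
    """Three crude initial thetas from the residual variance and the
    distance scale: nugget-light, balanced, and nugget-heavy splits at
    short/medium range fractions."""
    var = max(float(np.var(y_resid)), 1e-10)
    dmax = max(float(D.max()), 1e-6)
    return [
        (0.05 * var, 0.95 * var, dmax / 4.0),
        (0.5 * var, 0.5 * var, dmax / 10.0),
        (0.9 * var, 0.1 * var, dmax / 2.0),
    ]


class KrigingConvergenceError(RuntimeError):
    """Raised when no optimiser start converges; carries the best theta found."""

    def __init__(self, message, best_theta=None):
        super().__init__(message)
        self.best_theta = best_theta


class UniversalKriging(RegressorMixin, BaseEstimator):
    """Universal kriging regressor with exponential covariance.

    Parameters
    ----------
    metric : {"euclidean", "greatcircle"}
        Distance metric; coordinates are (x, y) km or (lon, lat) degrees.
    theta : tuple or None
        Fixed (nugget, sigma2, range_km); when None the three parameters are
        estimated by profile maximum likelihood with multi-start L-BFGS.
    reml : bool
        Use restricted ML instead of plain ML.
    n_coord_cols : int
        Leading columns of X holding the coordinates (always 2 here; kept a
        parameter for clarity in pipelines).

    Attributes
    ----------
    nugget_, partial_sill_, range_km_ : fitted covariance parameters.
    beta_ : mean coefficients, intercept first.
    nll_ : profile NLL at the optimum.
    """

    def __init__(self, metric="euclidean", theta=None, reml=False,
                 n_restarts=3, optimizer_maxiter=200, n_coord_cols=2):
        self.metric = metric
        self.theta = theta
        self.reml = reml
        self.n_restarts = n_restarts
        self.optimizer_maxiter = optimizer_maxiter
        self.n_coord_cols = n_coord_cols

    def _split(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X[:, : self.n_coord_cols], X[:, self.n_coord_cols :]

    def fit(self, X, y):
        coords, F = self._split(X)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        if n < 10:
            raise ValueError("universal kriging needs at least 10 sites")
        D = pairwise_km(coords, metric=self.metric)
        off = D[~np.eye(n, dtype=bool)]
        if off.size and off.min() == 0.0:
            raise ValueError("duplicate site coordinates are not allowed")
        Fd = _design(F)
        if np.linalg.matrix_rank(Fd) < Fd.shape[1]:
            raise ValueError("mean design is rank deficient")

        if self.theta is not None:
            theta = tuple(float(t) for t in self.theta)
            nll, beta, cho = _profile_nll(theta, Fd, y, D, reml=self.reml)
            if beta is None:
                raise KrigingConvergenceError("fixed theta gives singular covariance")
        else:
            theta, nll, beta, cho = self._optimize(Fd, y, D)

        self.nugget_, self.partial_sill_, self.range_km_ = theta
        self.beta_ = beta
        self.nll_ = float(nll)
        resid = y - Fd @ beta
        si_F = linalg.cho_solve(cho, Fd)
        self._state_ = _FitState(
            beta=beta, cho=cho, si_resid=linalg.cho_solve(cho, resid),
            FtSiF_inv=np.linalg.inv(Fd.T @ si_F), F=Fd, y=y, coords=coords,
        )
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else Fd.shape[1] - 1
        return self

    def _optimize(self, Fd, y, D):
        # OLS residuals seed the variogram-guided starts
        beta_ols, *_ = np.linalg.lstsq(Fd, y, rcond=None)
        resid = y - Fd @ beta_ols

        def objective(log_theta):
            theta = np.exp(log_theta)
            nll, _, _ = _profile_nll(tuple(theta), Fd, y, D, reml=self.reml)
            return nll

        # a range below the typical site spacing is indistinguishable from
        # nugget (likelihood ridge), so bound it by the median nearest-
        # neighbour distance; variances are bounded relative to the residual
        # variance, keeping the procedure scale-equivariant
        n = len(y)
        nn = np.where(np.eye(n, dtype=bool), np.inf, D).min(axis=1)
        r_lo = max(float(np.median(nn)), 1e-6)
        r_hi = 3.0 * float(D.max())
        var = max(float(np.var(resid)), 1e-12)
        bounds = [(np.log(1e-8 * var), np.log(1e2 * var))] * 2 + [
            (np.log(r_lo), np.log(r_hi))
        ]

        best = None
        starts = _variogram_starts(resid, D)[: max(self.n_restarts, 1)]
        for start in starts:
            x0 = np.clip(np.log(start), [b[0] for b in bounds], [b[1] for b in bounds])
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.optimizer_maxiter},
            )
            if res.fun < _SINGULAR_PENALTY and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise KrigingConvergenceError(
                "maximum-likelihood fit failed from all starts",
                best_theta=None,
            )
        theta = tuple(np.exp(best.x))
        nll, beta, cho = _profile_nll(theta, Fd, y, D, reml=self.reml)
        return theta, nll, beta, cho

    def predict(self, X, return_std: bool = False):
        """Universal-kriging prediction F_new beta + c' Sigma^{-1} (y - F beta).

        ``return_std=True`` also returns the kriging standard deviation,
        which accounts for mean-coefficient uncertainty.
        """
        check_is_fitted(self, "_state_")
        coords_new, F_new = self._split(X)
        st = self._state_
        Fd_new = _design(F_new)
        if Fd_new.shape[1] != st.F.shape[1]:
            raise ValueError("prediction design has wrong number of columns")
        c = exponential_covariance(
            pairwise_km(coords_new, st.coords, metric=self.metric),
            self.partial_sill_, self.range_km_,
        )
        mean = Fd_new @ st.beta + c @ st.si_resid
        if not return_std:
            return mean
        si_c = linalg.cho_solve(st.cho, c.T)  # (n_train, n_new)
        var_base = self.partial_sill_ + self.nugget_ - np.einsum("ij,ji->i", c, si_c)
        u = Fd_new.T - st.F.T @ si_c  # (p, n_new)
        var_mean = np.einsum("pi,pq,qi->i", u, st.FtSiF_inv, u)
        var = np.maximum(var_base + var_mean, 0.0)
        return mean, np.sqrt(var)


def fit_uk(scores: np.ndarray, y: np.ndarray, coords: np.ndarray,
           metric: str = "euclidean", **kwargs) -> UniversalKriging:
    """Functional wrapper: fit UK of sqrt-scale y on PLS scores at coords."""
    X = np.hstack([np.atleast_2d(np.asarray(coords, float)),
                   np.atleast_2d(np.asarray(scores, float))])
    return UniversalKriging(metric=metric, **kwargs).fit(X, y)
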