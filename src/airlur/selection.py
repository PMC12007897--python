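"""Greedy forward variable selection by partial F-statistic.

The first variable is the one most correlated (in absolute value) with the
response; each subsequent step adds the candidate that maximises the partial
F of the one-variable-larger OLS model against the current one,

    F = ((SSE_reduced - SSE_full) / 1) / (SSE_full / (n - p_full)),

with p_full counting the intercept.  The statistic is used purely as a
ranking score, not as a hypothesis test.  The scan is implemented by
Gram-Schmidt residualisation of the response and all remaining candidates
against the selected set, which makes each step O(n * n_candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: relative tolerance below which a residualised candidate is treated as
#: collinear with the already-selected set
_COLLINEAR_RTOL = 1e-10


@dataclass
class SelectionPath:
    """Ordered record of a forward-selection run."""

    names: list[str] = field(default_factory=list)
    indices: list[int] = field(default_factory=list)
    partial_f: list[float] = field(default_factory=list)
    sse: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)


def forward_select(X: np.ndarray, y: np.ndarray, max_vars: int,
                   variable_names: list[str] | None = None) -> SelectionPath:
    """Greedy forward selection of up to ``max_vars`` columns of X.

    Ties in the selection score are broken by variable-name order; candidates
    collinear with the selected set are skipped (logged).  The path may be
    shorter than ``max_vars`` when no candidate reduces the SSE.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if max_vars > m:
        raise ValueError(f"max_vars={max_vars} exceeds {m} available variables")
    if variable_names is None:
        variable_names = [f"x{j}" for j in range(m)]
    names = np.asarray(variable_names, dtype=object)

    col_norms = np.linalg.norm(X, axis=0)
    # residualise against the intercept once up front
    Xr = X - X.mean(axis=0)
    yr = y - y.mean()
    sse = float(yr @ yr)
    path = SelectionPath()
    available = np.ones(m, dtype=bool)
    p = 1  # parameters in the current model (intercept)

    while len(path) < max_vars:
        xr_norm2 = np.einsum("ij,ij->j", Xr, Xr)
        usable = available & (np.sqrt(xr_norm2) > _COLLINEAR_RTOL * np.maximum(col_norms, 1.0))
        skipped = available & ~usable
        for j in np.flatnonzero(skipped):
            logger.info("skipping collinear candidate %s", names[j])
            available[j] = False
        if not usable.any():
            break
        cross = Xr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            delta_sse = np.where(usable, cross**2 / xr_norm2, -np.inf)
        sse_full = np.maximum(sse - delta_sse, 0.0)  # guard rounding; 0 = perfect fit
        # partial F vs. current model; monotone in delta_sse at fixed step,
        # so step 1 (max |correlation|) coincides with max F
        dof = n - (p + 1)
        if dof <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = np.where(usable, delta_sse / (sse_full / dof), -np.inf)
        best_f = f_stat[usable].max()  # +inf allowed: a perfect fit wins outright
        if np.isnan(best_f) or best_f <= 0.0:
            break
        ties = np.flatnonzero(f_stat == best_f)
        j = ties[np.argsort(names[ties].astype(str), kind="stable")[0]]

        path.indices.append(int(j))
        path.names.append(str(names[j]))
        path.partial_f.append(float(f_stat[j]))
        sse = float(sse_full[j])
        path.sse.append(sse)
        # deflate the response and remaining candidates against the new column
        q = Xr[:, j] / np.linalg.norm(Xr[:, j])
        yr = yr - q * (q @ yr)
        Xr = Xr - np.outer(q, q @ Xr)
        available[j] = False
        p += 1

    return path
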