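"""Block-level application and population-weighted aggregation.

A fitted model is applied at census-block centroids (blocks with zero
population are excluded upstream), then block estimates are rolled up to
block group, tract and county as population-weighted means,

    pw(g) = sum_i pop_i * conc_i / sum_i pop_i   over member blocks i.

FIPS codes are strings throughout (leading zeros are semantic) and nest by
prefix, so aggregating blocks directly to a coarser level equals aggregating
through any intermediate level — an identity the tests exploit.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .features import assemble_feature_matrix

LEVEL_FIPS = {"block_group": "bg_fips", "tract": "tract_fips", "county": "county_fips"}


def spec_hash(variable_names) -> str:
    return hashlib.sha256("\x1f".join(variable_names).encode()).hexdigest()[:16]


def predict_blocks(model, blocks: pd.DataFrame, landscape, spec,
                   batch_size: int = 1000) -> pd.DataFrame:
    """Predict concentrations at block centroids.

    ``spec`` must be the training variable spec — verified by hashing the
    variable names against the model's record.  Evaluation is batched; the
    kriging predictor is per-point, so output is independent of batch size.
    """
    names = [v.name for v in spec]
    if spec_hash(names) != spec_hash(model.input_variable_names_):
        raise ValueError("variable spec does not match the spec the model was trained on")
    if (blocks["population"] <= 0).any():
        raise ValueError("blocks must have positive population")
    coords = blocks[["x_km", "y_km"]].to_numpy(dtype=float)
    conc = np.empty(len(blocks))
    for start in range(0, len(blocks), batch_size):
        sl = slice(start, start + batch_size)
        fm = assemble_feature_matrix(landscape, coords[sl], spec)
        X = np.hstack([coords[sl], fm.values])
        conc[sl] = model.predict(X)
    out = blocks[["block_fips", "bg_fips", "tract_fips", "county_fips",
                  "lon", "lat", "population"]].copy()
    out["concentration"] = conc
    return out


def population_weighted_aggregate(estimates: pd.DataFrame, level: str) -> pd.DataFrame:
    """Population-weighted mean concentration per geography at ``level``."""
    if len(estimates) == 0:
        raise ValueError("no block estimates to aggregate")
    if level not in LEVEL_FIPS:
        raise ValueError(f"level must be one of {sorted(LEVEL_FIPS)}")
    key = LEVEL_FIPS[level]
    df = estimates.copy()
    pop = df["population"].to_numpy(dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive")  # guarded despite invariant
    df["_w"] = pop * df["concentration"]
    g = df.groupby(key, sort=True)
    out = pd.DataFrame({
        "fips": g.size().index,
        "pw_concentration": (g["_w"].sum() / g["population"].sum()).to_numpy(),
        "total_population": g["population"].sum().to_numpy(),
        "n_blocks": g.size().to_numpy(),
    })
    out["geography_level"] = level
    return out.reset_index(drop=True)


def reaggregate(estimates: pd.DataFrame, coarser: str) -> pd.DataFrame:
    """Aggregate an already-aggregated table to a coarser level by re-weighting
    with total_population; exact by associativity of weighted means."""
    key = LEVEL_FIPS[coarser]
    prefix_len = {"county": 5, "tract": 11, "block_group": 12}[coarser]
    df = estimates.copy()
    df[key] = df["fips"].str[:prefix_len]
    df = df.rename(columns={"pw_concentration": "concentration",
                            "total_population": "population"})
    out = population_weighted_aggregate(df, coarser)
    out["n_blocks"] = df.groupby(key, sort=True)["n_blocks"].sum().to_numpy()
    return out


def write_estimates(estimates: pd.DataFrame, level: str, pollutant: str,
                    year: int, path) -> None:
    """Distributable CSV: fips, year, pollutant, pw_concentration,
    total_population, n_blocks — sorted by FIPS string."""
    df = estimates.sort_values("fips")
    out = pd.DataFrame({
        "fips": df["fips"].astype(str),
        "year": year,
        "pollutant": pollutant,
        "pw_concentration": df["pw_concentration"],
        "total_population": df["total_population"].astype(int),
        "n_blocks": df["n_blocks"].astype(int),
    })
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing estimates to {path}: {exc}") from exc


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"fips": str})
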