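"""Synthetic study system: landscape, truth field, monitors, census blocks.

Everything the pipeline consumes can be generated here with known
parameters, so each downstream stage has a recoverable truth:

* a **landscape** of road segments, point emission sources, a fine
  population raster and a coarse satellite-proxy raster on a square
  projected domain (km);
* a **truth field**: sqrt-scale concentration = positive linear mean in
  landscape-derived covariates + a stationary Gaussian random field with
  exponential covariance (simulated exactly by Cholesky factorisation and
  extended lazily by conditional simulation, so the surface is evaluable at
  any coordinate and consistent across calls);
* **monitor series**: hourly (gases) or daily (PM) records at urban-biased
  or uniform sites, with everyday / 1-in-3 / 1-in-6 reporting schedules,
  missing-completely-at-random dropout and an optional planted contiguous
  gap per site (the 45-day QC rule is untestable under MCAR alone);
* **census blocks** with positive population and prefix-consistent FIPS
  nesting (block -> block group -> tract -> county).

All generators are deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.ndimage import gaussian_filter

from .features import LineLayer, PointLayer, Raster
from .geo import km_to_lonlat, pairwise_km
from .kriging import exponential_covariance
from .qc import MonitorSeries, GAS_POLLUTANTS

STATE_FIPS = "30"  # arbitrary synthetic state


# ---------------------------------------------------------------------------
# Landscape


@dataclass
class Landscape:
    """Geographic predictor layers on the square domain (0, L) x (0, L) km."""

    domain_km: float
    roads: LineLayer
    sources: PointLayer
    population: Raster
    developed: Raster
    satellite: Raster
    seed: int

    def __post_init__(self) -> None:
        L = self.domain_km
        if self.roads.segments.size:
            pts = self.roads.segments.reshape(-1, 2)
            if pts.min() < 0 or pts.max() > L:
                raise ValueError("road segments outside domain bounds")
        if self.sources.points.size:
            if self.sources.points.min() < 0 or self.sources.points.max() > L:
                raise ValueError("point sources outside domain bounds")
        if np.any(self.population.values < 0):
            raise ValueError("population must be non-negative")
        if self.satellite.cellsize <= self.population.cellsize:
            raise ValueError("satellite grid must be strictly coarser than population grid")

    def layers(self) -> dict:
        return {
            "roads": self.roads,
            "major_roads": self.roads.subset("major"),
            "sources": self.sources,
            "population": self.population,
            "developed": self.developed,
            "satellite": self.satellite,
        }

    def urban_foci(self, n: int = 4) -> np.ndarray:
        """Coordinates (km) of the n most populous raster cells."""
        pop = self.population
        flat = np.argsort(pop.values, axis=None)[::-1][:n]
        iy, ix = np.unravel_index(flat, pop.values.shape)
        return np.column_stack([
            pop.xmin + (ix + 0.5) * pop.cellsize,
            pop.ymin + (iy + 0.5) * pop.cellsize,
        ])


def generate_landscape(seed: int, n_roads: int = 40, n_sources: int = 25,
                       domain_km: float = 100.0, pop_cellsize_km: float = 2.0,
                       satellite_cellsize_km: float = 10.0) -> Landscape:
    """Random but reproducible landscape with urban population structure."""
    if domain_km <= 0:
        raise ValueError("domain extent must be positive")
    if n_roads < 0 or n_sources < 0:
        raise ValueError("feature counts must be non-negative")
    rng = np.random.default_rng(seed)
    L = domain_km

    # population: a few exponential urban foci on a lognormal rural floor
    n_cells = int(np.ceil(L / pop_cellsize_km))
    xc = (np.arange(n_cells) + 0.5) * pop_cellsize_km
    gx, gy = np.meshgrid(xc, xc)
    foci = rng.uniform(0.15 * L, 0.85 * L, size=(3, 2))
    weights = rng.uniform(2e3, 8e3, size=3)
    density = np.zeros_like(gx)
    for (fx, fy), w in zip(foci, weights):
        d = np.hypot(gx - fx, gy - fy)
        density += w * np.exp(-d / (0.06 * L))
    density += 20.0 * rng.lognormal(mean=0.0, sigma=0.8, size=density.shape)
    population = Raster(0.0, 0.0, pop_cellsize_km, density)

    developed = Raster(0.0, 0.0, pop_cellsize_km, 1.0 - np.exp(-density / 500.0))

    # roads: major roads radiate between foci, local roads are random chords
    segments = []
    tags = []
    n_major = n_roads // 4
    for i in range(n_major):
        a = foci[i % len(foci)] + rng.normal(0, 0.02 * L, 2)
        b = foci[(i + 1) % len(foci)] + rng.normal(0, 0.02 * L, 2)
        segments.append([*np.clip(a, 0, L), *np.clip(b, 0, L)])
        tags.append("major")
    for _ in range(n_roads - n_major):
        centre = foci[rng.integers(len(foci))] + rng.normal(0, 0.15 * L, 2)
        half = rng.normal(0, 0.04 * L, 2)
        a = np.clip(centre - half, 0, L)
        b = np.clip(centre + half, 0, L)
        segments.append([*a, *b])
        tags.append("local")
    roads = LineLayer(np.asarray(segments, dtype=float).reshape(-1, 4), tuple(tags))

    # point sources near the foci, with lognormal emission magnitudes
    if n_sources:
        src = foci[rng.integers(len(foci), size=n_sources)] + rng.normal(0, 0.12 * L, (n_sources, 2))
        src = np.clip(src, 0.0, L)
    else:
        src = np.empty((0, 2))
    sources = PointLayer(src, rng.lognormal(1.0, 0.8, size=n_sources))

    # satellite proxy: smoothed population + source signal on a coarse grid
    n_sat = int(np.ceil(L / satellite_cellsize_km))
    fine = gaussian_filter(density, sigma=3.0)
    ratio = max(n_cells // n_sat, 1)
    coarse = fine[: n_sat * ratio, : n_sat * ratio].reshape(n_sat, ratio, n_sat, ratio).mean(axis=(1, 3))
    coarse = coarse / coarse.max() * 10.0 + rng.normal(0, 0.2, coarse.shape)
    satellite = Raster(0.0, 0.0, satellite_cellsize_km, coarse)

    return Landscape(domain_km=L, roads=roads, sources=sources,
                     population=population, developed=developed,
                     satellite=satellite, seed=seed)


# ---------------------------------------------------------------------------
# Truth field

#: covariate names entering the truth mean, in order
TRUTH_COVARIATES = ("log_pop_density", "source_proximity", "road_proximity", "satellite")

DEFAULT_TRUTH_COEFFS = np.array([0.25, 0.8, 0.5, 0.08])
DEFAULT_TRUTH_OFFSET = 1.5


@dataclass
class TruthField:
    """Noise-free sqrt-scale concentration surface, evaluable anywhere.

    mean(s) = offset + coeffs . covariates(s), kept positive by the offset;
    the spatial residual is an exact Gaussian random field with exponential
    covariance, extended to new points by conditional simulation on a cache
    (so repeated evaluation at a point returns the same value).
    """

    landscape: Landscape
    coeffs: np.ndarray
    offset: float
    partial_sill: float
    range_km: float
    nugget: float
    seed: int
    _cache_pts: np.ndarray = field(default=None, repr=False)
    _cache_vals: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.partial_sill < 0 or self.nugget < 0:
            raise ValueError("variance parameters must be non-negative")
        if self.range_km <= 0:
            raise ValueError("range must be positive")
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self._rng = np.random.default_rng(self.seed)
        self._cache_pts = np.empty((0, 2))
        self._cache_vals = np.empty(0)

    def covariates(self, points: np.ndarray) -> np.ndarray:
        """Landscape-derived covariates at points (km): log population
        density, exponential source/road proximity, satellite sample."""
        from .features import sample_grid  # local import keeps module load light

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pop = np.array([sample_grid(self.landscape.population, p) for p in pts])
        sat = np.array([sample_grid(self.landscape.satellite, p) for p in pts])
        src = self.landscape.sources.points
        if src.size:
            d_src = pairwise_km(pts, src).min(axis=1)
        else:
            d_src = np.full(len(pts), np.inf)
        segs = self.landscape.roads.segments
        if segs.size:
            d_road = np.array([_min_dist_to_segments(p, segs) for p in pts])
        else:
            d_road = np.full(len(pts), np.inf)
        return np.column_stack([
            np.log1p(pop),
            np.exp(-d_src / 5.0),
            np.exp(-d_road / 2.0),
            sat,
        ])

    def mean(self, points: np.ndarray) -> np.ndarray:
        m = self.offset + self.covariates(points) @ self.coeffs
        return np.maximum(m, 0.0)  # offset keeps this inactive in practice

    def _grf(self, points: np.ndarray) -> np.ndarray:
        """Exact GRF values at points, conditional on all earlier queries."""
        if self.partial_sill == 0.0:
            return np.zeros(len(points))
        out = np.empty(len(points))
        known = {tuple(np.round(p, 9)): i for i, p in enumerate(self._cache_pts)}
        new_idx = []
        seen_new: dict[tuple, int] = {}
        for i, p in enumerate(points):
            key = tuple(np.round(p, 9))
            if key in known:
                out[i] = self._cache_vals[known[key]]
            elif key in seen_new:
                new_idx.append((i, seen_new[key]))
            else:
                seen_new[key] = len(seen_new)
                new_idx.append((i, seen_new[key]))
        if not seen_new:
            return out
        Q = np.array([list(k) for k in seen_new])
        C_QQ = exponential_covariance(pairwise_km(Q), self.partial_sill, self.range_km)
        if len(self._cache_pts):
            C_QP = exponential_covariance(
                pairwise_km(Q, self._cache_pts), self.partial_sill, self.range_km)
            C_PP = exponential_covariance(
                pairwise_km(self._cache_pts), self.partial_sill, self.range_km)
            C_PP[np.diag_indices_from(C_PP)] += 1e-10
            solve = linalg.solve(C_PP, C_QP.T, assume_a="pos")
            mean_q = C_QP @ linalg.solve(C_PP, self._cache_vals, assume_a="pos")
            cov_q = C_QQ - C_QP @ solve
        else:
            mean_q = np.zeros(len(Q))
            cov_q = C_QQ
        cov_q[np.diag_indices_from(cov_q)] += 1e-10
        chol = linalg.cholesky(cov_q, lower=True)
        vals = mean_q + chol @ self._rng.standard_normal(len(Q))
        self._cache_pts = np.vstack([self._cache_pts, Q])
        self._cache_vals = np.concatenate([self._cache_vals, vals])
        for i, j in new_idx:
            out[i] = vals[j]
        return out

    def truth_fn(self, points: np.ndarray) -> np.ndarray:
        """Noise-free sqrt-scale concentration at arbitrary coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.mean(pts) + self._grf(pts)


def _min_dist_to_segments(p: np.ndarray, segs: np.ndarray) -> float:
    a = segs[:, :2]
    d = segs[:, 2:] - a
    ap = p - a
    denom = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.divide(np.einsum("ij,ij->i", ap, d), denom,
                          out=np.zeros_like(denom), where=denom > 0), 0.0, 1.0)
    closest = a + t[:, None] * d
    return float(np.hypot(*(closest - p).T).min())


def generate_truth_field(landscape: Landscape, coeffs=None, partial_sill: float = 0.05,
                         range_km: float = 20.0, nugget: float = 0.01,
                         offset: float = DEFAULT_TRUTH_OFFSET,
                         seed: int = 0) -> TruthField:
    """Truth surface = positive linear mean in landscape covariates + GRF."""
    coeffs = DEFAULT_TRUTH_COEFFS if coeffs is None else np.asarray(coeffs, float)
    return TruthField(landscape=landscape, coeffs=coeffs, offset=offset,
                      partial_sill=partial_sill, range_km=range_km,
                      nugget=nugget, seed=seed)


# ---------------------------------------------------------------------------
# Monitor series

SCHEDULE_PERIODS = {"everyday": 1, "one_in_three": 3, "one_in_six": 6}


def sample_monitor_series(truth: TruthField, n_sites: int, year: int = 2016,
                          pollutant: str = "PM25",
                          schedule_mix: dict[str, float] | None = None,
                          missingness: float = 0.0, clustered: bool = False,
                          seed: int = 0, gap_days: int | None = None,
                          gap_prob: float = 0.0,
                          hour_missingness: float = 0.0) -> list[MonitorSeries]:
    """Simulate one year of monitor records at n_sites locations.

    Sites are uniform over the domain, or drawn around the landscape's urban
    foci when ``clustered`` (what real monitoring networks look like, and
    what makes spatially clustered CV informative).  Each site's sqrt-scale
    annual level is truth + N(0, nugget); daily values fluctuate around the
    back-transformed annual mean with a seasonal cycle and lognormal noise.
    Whole scheduled days are dropped MCAR at rate ``missingness``; with
    probability ``gap_prob`` a site additionally loses a contiguous run of
    ``gap_days`` days.  Gas pollutants get 24 hourly records per kept day
    (each hour dropped at ``hour_missingness``); PM gets one daily record.
    """
    if n_sites < 2:
        raise ValueError("kriging is undefined below 2 sites")
    if not (0.0 <= missingness < 1.0):
        raise ValueError("missingness must be in [0, 1)")
    schedule_mix = schedule_mix or {"everyday": 1.0}
    if abs(sum(schedule_mix.values()) - 1.0) > 1e-9:
        raise ValueError("schedule proportions must sum to 1")
    rng = np.random.default_rng(seed)
    L = truth.landscape.domain_km

    if clustered:
        foci = truth.landscape.urban_foci(4)
        which = rng.integers(len(foci), size=n_sites)
        sites = np.clip(foci[which] + rng.normal(0, 0.06 * L, (n_sites, 2)), 0.0, L)
    else:
        sites = rng.uniform(0.0, L, size=(n_sites, 2))

    sqrt_level = truth.truth_fn(sites) + rng.normal(0, np.sqrt(truth.nugget), n_sites)
    native_level = np.maximum(sqrt_level, 0.0) ** 2

    schedules = rng.choice(list(schedule_mix), size=n_sites,
                           p=list(schedule_mix.values()))
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = np.arange(len(days))
    cadence = "hourly" if pollutant in GAS_POLLUTANTS else "daily"
    hours = np.arange(24)
    # diurnal shape with mean one; midday peak suits O3-like photochemistry
    diurnal = 1.0 + 0.4 * np.sin(2 * np.pi * (hours - 9) / 24.0)

    out: list[MonitorSeries] = []
    for i in range(n_sites):
        period = SCHEDULE_PERIODS[schedules[i]]
        offset = int(rng.integers(period))
        scheduled = doy[offset::period]
        keep = scheduled[rng.random(len(scheduled)) >= missingness]
        if gap_days and rng.random() < gap_prob and len(doy) > gap_days:
            start = int(rng.integers(0, len(doy) - gap_days))
            keep = keep[(keep < start) | (keep >= start + gap_days)]
        seasonal = 1.0 + 0.3 * np.sin(2 * np.pi * (keep - 30) / 365.25)
        noise = rng.lognormal(mean=-0.02, sigma=0.2, size=len(keep))
        daily = native_level[i] * seasonal * noise
        lonlat = km_to_lonlat(sites[i])
        if cadence == "daily":
            index = days[keep]
            values = daily
        else:
            stamps = []
            vals = []
            for d, v in zip(keep, daily):
                kept_hours = hours[rng.random(24) >= hour_missingness]
                stamps.extend(days[d] + pd.to_timedelta(kept_hours, unit="h"))
                hv = v * diurnal[kept_hours] * rng.lognormal(-0.005, 0.1, len(kept_hours))
                vals.extend(hv)
            index = pd.DatetimeIndex(stamps)
            values = np.asarray(vals)
        out.append(MonitorSeries(
            site_id=f"S{i:04d}", lon=float(lonlat[0]), lat=float(lonlat[1]),
            pollutant=pollutant, cadence=cadence, year=year,
            records=pd.Series(values, index=index),
        ))
    return out


def monitor_series_to_csv(series_list: list[MonitorSeries], path) -> None:
    """Serialise monitor series to the standard long-format CSV."""
    frames = []
    for s in series_list:
        col = "datetime" if s.cadence == "hourly" else "date"
        df = pd.DataFrame({
            "site_id": s.site_id, "lon": s.lon, "lat": s.lat,
            col: s.records.index, "pollutant": s.pollutant,
            "value": s.records.to_numpy(),
        })
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def site_coords_km(series_list: list[MonitorSeries]) -> np.ndarray:
    from .geo import lonlat_to_km

    return lonlat_to_km(np.array([[s.lon, s.lat] for s in series_list]))


# ---------------------------------------------------------------------------
# Census blocks


def generate_blocks(n_blocks: int, landscape: Landscape, seed: int = 0) -> pd.DataFrame:
    """Block centroid table with positive population and nested FIPS codes.

    Counties tile the domain 2 x 2; tracts tile each county 4 x 4; block
    groups tile each tract 2 x 2.  FIPS codes are built by prefix, so block
    -> block group -> tract -> county nesting is consistent by construction.
    Centroids are drawn proportionally to the population raster.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)
    L = landscape.domain_km
    pop = landscape.population
    weights = pop.values.ravel() / pop.values.sum()
    cells = rng.choice(pop.values.size, size=n_blocks, p=weights)
    iy, ix = np.unravel_index(cells, pop.values.shape)
    x = pop.xmin + (ix + rng.random(n_blocks)) * pop.cellsize
    y = pop.ymin + (iy + rng.random(n_blocks)) * pop.cellsize
    x = np.clip(x, 0, np.nextafter(L, 0))
    y = np.clip(y, 0, np.nextafter(L, 0))

    county_ix = np.minimum((x / (L / 2)).astype(int), 1)
    county_iy = np.minimum((y / (L / 2)).astype(int), 1)
    county = np.array([f"{STATE_FIPS}{1 + 2 * cy + cx:03d}"
                       for cx, cy in zip(county_ix, county_iy)])
    tract_ix = np.minimum((x / (L / 8)).astype(int), 7) % 4
    tract_iy = np.minimum((y / (L / 8)).astype(int), 7) % 4
    tract = np.array([f"{c}{100 * (1 + 4 * ty + tx):06d}"
                      for c, tx, ty in zip(county, tract_ix, tract_iy)])
    bg_ix = np.minimum((x / (L / 16)).astype(int), 15) % 2
    bg_iy = np.minimum((y / (L / 16)).astype(int), 15) % 2
    bg = np.array([f"{t}{1 + 2 * by + bx:d}" for t, bx, by in zip(tract, bg_ix, bg_iy)])
    block = np.array([f"{g}{i:06d}" for i, g in enumerate(bg)])

    population = np.maximum(rng.lognormal(3.0, 1.0, n_blocks).astype(int), 1)
    lonlat = km_to_lonlat(np.column_stack([x, y]))
    return pd.DataFrame({
        "block_fips": block, "bg_fips": bg, "tract_fips": tract,
        "county_fips": county, "lon": lonlat[:, 0], "lat": lonlat[:, 1],
        "population": population, "x_km": x, "y_km": y,
    })


def write_blocks_csv(blocks: pd.DataFrame, path) -> None:
    cols = ["block_fips", "bg_fips", "tract_fips", "county_fips",
            "lon", "lat", "population"]
    blocks[cols].to_csv(path, index=False)


def read_blocks_csv(path) -> pd.DataFrame:
    from .geo import lonlat_to_km

    df = pd.read_csv(path, dtype={c: str for c in
                                  ("block_fips", "bg_fips", "tract_fips", "county_fips")})
    km = lonlat_to_km(df[["lon", "lat"]].to_numpy())
    df["x_km"], df["y_km"] = km[:, 0], km[:, 1]
    return df


# ---------------------------------------------------------------------------
# Landscape serialisation (GeoJSON + ESRI ASCII grid)


def _write_ascii_grid(raster: Raster, path) -> None:
    header = (f"ncols {raster.nx}\nnrows {raster.ny}\n"
              f"xllcorner {raster.xmin}\nyllcorner {raster.ymin}\n"
              f"cellsize {raster.cellsize}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values[::-1], fmt="%.6g")  # rows north to south


def _read_ascii_grid(path) -> Raster:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    return Raster(head["xllcorner"], head["yllcorner"], head["cellsize"],
                  np.atleast_2d(values)[::-1])


def write_landscape(landscape: Landscape, directory) -> None:
    """Roads/sources as GeoJSON (lon/lat), rasters as ESRI ASCII grids (km)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    road_features = []
    for seg, tag in zip(landscape.roads.segments, landscape.roads.tags):
        coords = km_to_lonlat(seg.reshape(2, 2)).tolist()
        road_features.append({"type": "Feature",
                              "properties": {"class": tag},
                              "geometry": {"type": "LineString", "coordinates": coords}})
    src_features = []
    mags = landscape.sources.magnitudes
    for i, pt in enumerate(landscape.sources.points):
        src_features.append({"type": "Feature",
                             "properties": {"magnitude": float(mags[i]) if mags is not None else None},
                             "geometry": {"type": "Point",
                                          "coordinates": km_to_lonlat(pt).tolist()}})
    for name, feats in (("roads", road_features), ("sources", src_features)):
        with open(directory / f"{name}.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    _write_ascii_grid(landscape.population, directory / "population.asc")
    _write_ascii_grid(landscape.developed, directory / "developed.asc")
    _write_ascii_grid(landscape.satellite, directory / "satellite.asc")
    with open(directory / "meta.json", "w") as fh:
        json.dump({"domain_km": landscape.domain_km, "seed": landscape.seed}, fh)


def read_landscape(directory) -> Landscape:
    from .geo import lonlat_to_km

    directory = Path(directory)
    with open(directory / "meta.json") as fh:
        meta = json.load(fh)
    with open(directory / "roads.geojson") as fh:
        roads_gj = json.load(fh)
    segs, tags = [], []
    for feat in roads_gj["features"]:
        km = lonlat_to_km(np.asarray(feat["geometry"]["coordinates"]))
        segs.append(km.ravel())
        tags.append(feat["properties"]["class"])
    with open(directory / "sources.geojson") as fh:
        src_gj = json.load(fh)
    pts = [lonlat_to_km(np.asarray(f["geometry"]["coordinates"]))
           for f in src_gj["features"]]
    mags = [f["properties"].get("magnitude") for f in src_gj["features"]]
    return Landscape(
        domain_km=meta["domain_km"],
        roads=LineLayer(np.asarray(segs, dtype=float).reshape(-1, 4), tuple(tags)),
        sources=PointLayer(np.asarray(pts, dtype=float).reshape(-1, 2),
                           np.asarray(mags, dtype=float) if mags and mags[0] is not None else None),
        population=_read_ascii_grid(directory / "population.asc"),
        developed=_read_ascii_grid(directory / "developed.asc"),
        satellite=_read_ascii_grid(directory / "satellite.asc"),
        seed=meta["seed"],
    )
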