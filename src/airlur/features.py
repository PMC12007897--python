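"""Buffer-based geographic predictor variables.

Land-use-regression covariates are summaries of geographic layers around
each point of interest: counts of point sources, clipped road length, and
apportioned population within circular buffers of 50 m to 15 km radius,
plus point variables (coordinates, nearest-source distance, coarse-grid
satellite samples).  Buffers are planar circles in the projected km plane.

Line clipping is exact (analytic segment-disk intersection) so that, e.g.,
a straight road through the buffer centre contributes exactly 2r of length.
Polygon/raster-cell overlap uses shapely with a finely discretised circle;
its own polygonal area is the area-fraction denominator, so full coverage
yields exactly 1.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, Point
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

MIN_BUFFER_M = 50.0
MAX_BUFFER_M = 15_000.0
#: vertices per quarter circle for polygon overlap work
_CIRCLE_QUAD_SEGS = 64

Measure = Literal["count", "length", "area_fraction"]


@dataclass(frozen=True)
class Raster:
    """Regular grid in the projected plane; cell (ix, iy) covers the
    half-open box (xmin+ix*cs, xmin+(ix+1)*cs] x (ymin+iy*cs, ymin+(iy+1)*cs]
    so a point on a shared edge belongs to the lower-left cell."""

    xmin: float
    ymin: float
    cellsize: float
    values: np.ndarray  # shape (ny, nx), values[iy, ix]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def xmax(self) -> float:
        return self.xmin + self.nx * self.cellsize

    @property
    def ymax(self) -> float:
        return self.ymin + self.ny * self.cellsize

    def cell_index(self, x: float, y: float) -> tuple[int, int, bool]:
        """Containing cell (clamped) and an in-extent flag."""
        inside = (self.xmin <= x <= self.xmax) and (self.ymin <= y <= self.ymax)
        ix = int(np.ceil((x - self.xmin) / self.cellsize)) - 1
        iy = int(np.ceil((y - self.ymin) / self.cellsize)) - 1
        ix = min(max(ix, 0), self.nx - 1)
        iy = min(max(iy, 0), self.ny - 1)
        return ix, iy, inside


@dataclass(frozen=True)
class LineLayer:
    """Line segments ((x0, y0), (x1, y1)) in km with a class tag each."""

    segments: np.ndarray  # shape (n, 4): x0, y0, x1, y1
    tags: tuple[str, ...] = ()

    def subset(self, tag: str) -> "LineLayer":
        mask = np.array([t == tag for t in self.tags])
        return LineLayer(self.segments[mask], tuple(np.array(self.tags)[mask]))


@dataclass(frozen=True)
class PointLayer:
    """Point features (e.g. emission sources) with optional magnitudes."""

    points: np.ndarray  # shape (n, 2) km
    magnitudes: np.ndarray | None = None


def _check_radius(radius_m: float) -> float:
    if not (MIN_BUFFER_M <= radius_m <= MAX_BUFFER_M):
        raise ValueError(
            f"buffer radius {radius_m} m outside [{MIN_BUFFER_M}, {MAX_BUFFER_M}] m"
        )
    return radius_m / 1000.0  # km


def segment_length_in_disk(p0, p1, centre, radius_km: float) -> float:
    """Exact length of the part of segment p0-p1 inside the disk.

    Solves |p0 + t (p1 - p0) - c|^2 = r^2 for t and clips to [0, 1].
    """
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    f = p0 - np.asarray(centre, dtype=float)
    a = float(d @ d)
    if a == 0.0:
        return 0.0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - radius_km**2
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return 0.0
    root = np.sqrt(disc)
    t_lo = max((-b - root) / (2.0 * a), 0.0)
    t_hi = min((-b + root) / (2.0 * a), 1.0)
    return max(t_hi - t_lo, 0.0) * np.sqrt(a)


def buffer_aggregate(layer, site, radius_m: float, measure: Measure) -> float:
    """Aggregate a geometry layer within a circular buffer around ``site``.

    count: points within the radius; length: total clipped line length (km);
    area_fraction: overlap area over buffer area, weighting raster cells by
    their (fractional) values, in [0, 1].
    """
    r_km = _check_radius(radius_m)
    site = np.asarray(site, dtype=float)
    if measure == "count":
        if not isinstance(layer, PointLayer):
            raise TypeError("count requires a PointLayer")
        if layer.points.size == 0:
            return 0.0
        d = np.hypot(*(layer.points - site).T)
        return float(np.sum(d <= r_km))
    if measure == "length":
        if not isinstance(layer, LineLayer):
            raise TypeError("length requires a LineLayer")
        return float(sum(
            segment_length_in_disk(seg[:2], seg[2:], site, r_km)
            for seg in layer.segments
        ))
    if measure == "area_fraction":
        if not isinstance(layer, Raster):
            raise TypeError("area_fraction requires a Raster")
        total, _ = _raster_disk_overlap(layer, site, r_km, weighted=True)
        return total
    raise ValueError(f"unknown measure {measure!r}")


def _raster_disk_overlap(raster: Raster, site, r_km: float, weighted: bool):
    """(value-weighted area fraction, value-weighted total) of cells in the disk."""
    circle = Point(*site).buffer(r_km, quad_segs=_CIRCLE_QUAD_SEGS)
    cs = raster.cellsize
    ix0 = max(int(np.floor((site[0] - r_km - raster.xmin) / cs)), 0)
    ix1 = min(int(np.ceil((site[0] + r_km - raster.xmin) / cs)), raster.nx)
    iy0 = max(int(np.floor((site[1] - r_km - raster.ymin) / cs)), 0)
    iy1 = min(int(np.ceil((site[1] + r_km - raster.ymin) / cs)), raster.ny)
    frac_sum = 0.0
    value_sum = 0.0
    cell_area = cs * cs
    for iy in range(iy0, iy1):
        for ix in range(ix0, ix1):
            cell = box(raster.xmin + ix * cs, raster.ymin + iy * cs,
                       raster.xmin + (ix + 1) * cs, raster.ymin + (iy + 1) * cs)
            overlap = circle.intersection(cell).area
            if overlap > 0.0:
                v = float(raster.values[iy, ix])
                frac_sum += (v if weighted else 1.0) * overlap
                value_sum += v * overlap / cell_area
    return frac_sum / circle.area, value_sum


def population_in_buffer(population: Raster, site, radius_m: float) -> float:
    """People within the buffer, apportioned from grid cells by area overlap."""
    r_km = _check_radius(radius_m)
    _, total = _raster_disk_overlap(population, np.asarray(site, float), r_km, weighted=True)
    return total


def distance_to_nearest(sources: PointLayer | np.ndarray, site) -> float:
    """Euclidean distance (metres) from ``site`` to the nearest source point."""
    pts = sources.points if isinstance(sources, PointLayer) else np.asarray(sources, float)
    if pts.size == 0:
        raise ValueError("source set is empty; caller must substitute a cap")
    d = np.hypot(*(np.atleast_2d(pts) - np.asarray(site, float)).T)
    return float(d.min()) * 1000.0


def sample_grid(grid: Raster, site) -> float:
    """Value of the raster cell containing ``site`` (no interpolation).

    Out-of-extent sites fall back to the nearest cell, with a log entry.
    """
    x, y = float(site[0]), float(site[1])
    ix, iy, inside = grid.cell_index(x, y)
    if not inside:
        logger.warning("site (%.3f, %.3f) outside grid extent; nearest cell used", x, y)
    return float(grid.values[iy, ix])


# ---------------------------------------------------------------------------
# Feature matrix assembly


@dataclass(frozen=True)
class VariableSpec:
    """One predictor variable: a layer, a measure, and an optional buffer."""

    name: str
    layer: str  # key into the landscape's layer mapping
    measure: Literal["count", "length", "area_fraction", "population",
                     "distance", "grid_sample", "coordinate"]
    radius_m: float | None = None
    coordinate_axis: Literal["x", "y"] | None = None


@dataclass
class FeatureMatrix:
    """Sites x predictor variables with per-variable buffer metadata."""

    site_ids: list[str]
    variable_names: list[str]
    values: np.ndarray
    buffer_metadata: dict[str, dict] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "site_id", self.site_ids)
        return df

    def write_csv(self, path, sidecar_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.buffer_metadata, fh, indent=1)

    @classmethod
    def read_csv(cls, path, sidecar_path=None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = {}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = json.load(fh)
        names = [c for c in df.columns if c != "site_id"]
        return cls(site_ids=df["site_id"].astype(str).tolist(),
                   variable_names=names,
                   values=df[names].to_numpy(dtype=float),
                   buffer_metadata=meta)


DEFAULT_BUFFERS_M = (100.0, 500.0, 1000.0, 5000.0, 15000.0)


def default_variable_spec(buffers_m: Sequence[float] = DEFAULT_BUFFERS_M) -> list[VariableSpec]:
    """Synthetic analogue of the ~360-variable national covariate list:
    every buffered category at every radius, plus the point variables."""
    spec: list[VariableSpec] = []
    for r in buffers_m:
        tag = f"{int(r)}m"
        spec.append(VariableSpec(f"road_length_{tag}", "roads", "length", r))
        spec.append(VariableSpec(f"major_road_length_{tag}", "major_roads", "length", r))
        spec.append(VariableSpec(f"source_count_{tag}", "sources", "count", r))
        spec.append(VariableSpec(f"population_{tag}", "population", "population", r))
        spec.append(VariableSpec(f"developed_frac_{tag}", "developed", "area_fraction", r))
    spec.append(VariableSpec("dist_source_m", "sources", "distance"))
    spec.append(VariableSpec("satellite", "satellite", "grid_sample"))
    spec.append(VariableSpec("coord_x_km", "", "coordinate", coordinate_axis="x"))
    spec.append(VariableSpec("coord_y_km", "", "coordinate", coordinate_axis="y"))
    return spec


def _evaluate_variable(var: VariableSpec, layers: dict, site: np.ndarray) -> float:
    if var.measure == "coordinate":
        return float(site[0] if var.coordinate_axis == "x" else site[1])
    layer = layers[var.layer]
    if var.measure in ("count", "length", "area_fraction"):
        return buffer_aggregate(layer, site, var.radius_m, var.measure)
    if var.measure == "population":
        return population_in_buffer(layer, site, var.radius_m)
    if var.measure == "distance":
        return distance_to_nearest(layer, site)
    if var.measure == "grid_sample":
        return sample_grid(layer, site)
    raise ValueError(f"unknown measure {var.measure!r}")


def assemble_feature_matrix(landscape, sites: np.ndarray,
                            spec: Sequence[VariableSpec],
                            site_ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Evaluate every spec variable at every site (coordinates in km).

    Column order follows the spec order and is identical across calls, so
    train and prediction matrices align by construction.
    """
    if len(spec) == 0:
        raise ValueError("variable spec must be non-empty")
    names = [v.name for v in spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in spec")
    layers = landscape.layers() if hasattr(landscape, "layers") else dict(landscape)
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    values = np.empty((len(sites), len(spec)))
    for j, var in enumerate(spec):
        for i, site in enumerate(sites):
            values[i, j] = _evaluate_variable(var, layers, site)
    if site_ids is None:
        site_ids = [f"site_{i:04d}" for i in range(len(sites))]
    meta = {
        v.name: {"category": v.layer or "position", "measure": v.measure,
                 "buffer_m": v.radius_m if v.radius_m is not None else "point"}
        for v in spec
    }
    return FeatureMatrix(list(site_ids), names, values, meta)


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """sklearn transformer: site coordinates (km) -> predictor matrix.

    Stateless apart from its configuration; ``fit`` exists for pipeline
    compatibility.  ``transform`` prepends the raw coordinates as the first
    two columns so the output feeds the kriging estimators directly.
    """

    def __init__(self, landscape=None, spec=None, prepend_coords=True):
        self.landscape = landscape
        self.spec = spec
        self.prepend_coords = prepend_coords

    def fit(self, X, y=None):
        if self.landscape is None:
            raise ValueError("FeatureExtractor requires a landscape")
        self.spec_ = list(self.spec) if self.spec is not None else default_variable_spec()
        self.variable_names_ = [v.name for v in self.spec_]
        return self

    def transform(self, X) -> np.ndarray:
        fm = assemble_feature_matrix(self.landscape, np.asarray(X, float), self.spec_)
        if self.prepend_coords:
            return np.hstack([np.atleast_2d(np.asarray(X, float)), fm.values])
        return fm.values

    def get_feature_names_out(self, input_features=None):
        names = list(self.variable_names_)
        if self.prepend_coords:
            names = ["coord_x", "coord_y"] + names
        return np.asarray(names, dtype=object)
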