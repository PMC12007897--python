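"""Coordinate conventions and distance metrics.

All synthetic geometry lives in a local projected plane with coordinates in
kilometres.  A fixed affine mapping ties that plane to lon/lat so downstream
code can exercise both conventions: the plane's origin is pinned to
(LON0, LAT0) and one km of easting/northing maps to the corresponding number
of degrees at that reference latitude.  Kriging distances are always metric
(km), either Euclidean in the plane or great-circle on lon/lat.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

# Reference point of the local projection (roughly the CONUS centroid).
LON0 = -98.35
LAT0 = 39.50

KM_PER_DEG_LAT = 110.574
KM_PER_DEG_LON = 111.320 * np.cos(np.deg2rad(LAT0))

EARTH_RADIUS_KM = 6371.0


def km_to_lonlat(xy_km: np.ndarray) -> np.ndarray:
    """Map projected (x, y) km coordinates to (lon, lat) degrees."""
    xy = np.asarray(xy_km, dtype=float)
    out = np.empty_like(xy)
    out[..., 0] = LON0 + xy[..., 0] / KM_PER_DEG_LON
    out[..., 1] = LAT0 + xy[..., 1] / KM_PER_DEG_LAT
    return out


def lonlat_to_km(lonlat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`km_to_lonlat`."""
    ll = np.asarray(lonlat, dtype=float)
    out = np.empty_like(ll)
    out[..., 0] = (ll[..., 0] - LON0) * KM_PER_DEG_LON
    out[..., 1] = (ll[..., 1] - LAT0) * KM_PER_DEG_LAT
    return out


def great_circle_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances in km between (lon, lat) arrays."""
    a = np.deg2rad(np.asarray(a, dtype=float))
    b = np.deg2rad(np.asarray(b, dtype=float))
    lon1, lat1 = a[:, None, 0], a[:, None, 1]
    lon2, lat2 = b[None, :, 0], b[None, :, 1]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_km(a: np.ndarray, b: np.ndarray | None = None, metric: str = "euclidean") -> np.ndarray:
    """Distance matrix in km.

    Parameters
    ----------
    a, b : arrays of shape (n, 2)
        Coordinates; (x, y) km for ``"euclidean"``, (lon, lat) degrees for
        ``"greatcircle"``.  ``b=None`` means distances of ``a`` with itself.
    metric : {"euclidean", "greatcircle"}
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = a if b is None else np.atleast_2d(np.asarray(b, dtype=float))
    if metric == "euclidean":
        return cdist(a, b)
    if metric == "greatcircle":
        return great_circle_km(a, b)
    raise ValueError(f"unknown metric {metric!r}; use 'euclidean' or 'greatcircle'")
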