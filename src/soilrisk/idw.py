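"""Inverse-distance-weighted spatial prediction and leave-one-out accuracy.

IDW predicts a concentration at an unsampled location as the weighted mean
of the observations with weights d^-p (default power p = 2) — closer
points count more.  Predictions are convex combinations of the data, so a
surface can never over- or undershoot the observed range.  Distances are
great-circle (haversine, km) by default since coordinates are geographic
degrees; a Euclidean option exists for unit-square fixtures.  Accuracy is
quantified by leave-one-out cross-validated RMSE in the data's units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SampleTable
from .errors import ValidationError

__all__ = ["GridSpec", "Surface", "idw_predict", "loocv_rmse", "make_surface"]

_EARTH_RADIUS_KM = 6371.0088
#: Targets closer than this (km or unit) to a sample coincide with it.
_COINCIDENT_EPS = 1e-9


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _distances(lats, lons, tlat, tlon, metric):
    if metric == "haversine":
        return _haversine_km(lats, lons, tlat, tlon)
    if metric == "euclidean":
        return np.hypot(lats - tlat, lons - tlon)
    raise ValidationError(f"unknown metric {metric!r}")


def idw_predict(points, target, p: float = 2.0, *, metric: str = "haversine",
                k: int | None = None) -> float:
    """Predict at ``target`` = (lat, lon) from ``points`` = [(lat, lon, value), ...].

    A target coinciding with a sample point (distance < 1e-9) returns that
    sample's value exactly.  ``k`` restricts the neighbourhood to the k
    nearest points (default: all).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValidationError("idw_predict requires at least one point")
    pts = pts.reshape(-1, 3)
    if not np.all(np.isfinite(pts)):
        raise ValidationError("point coordinates and values must be finite")
    if not p > 0:
        raise ValidationError(f"power must be > 0, got {p}")
    d = _distances(pts[:, 0], pts[:, 1], float(target[0]), float(target[1]), metric)
    hit = d < _COINCIDENT_EPS
    if hit.any():
        return float(pts[hit, 2][0])
    if k is not None and k < len(pts):
        keep = np.argsort(d)[:k]
        pts, d = pts[keep], d[keep]
    w = d ** (-p)
    # anchor at the minimum so a constant field is reproduced exactly
    base = pts[:, 2].min()
    return float(base + np.sum(w * (pts[:, 2] - base)) / np.sum(w))


def loocv_rmse(points, p: float = 2.0, *, metric: str = "haversine",
               k: int | None = None) -> float:
    """Leave-one-out RMSE: each observation predicted from all the others."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 2:
        raise ValidationError("LOOCV requires at least 2 points")
    coords = pts[:, :2]
    for i in range(len(pts)):
        same = np.all(np.abs(coords - coords[i]) < _COINCIDENT_EPS, axis=1)
        if np.any(same & (np.abs(pts[:, 2] - pts[i, 2]) > 0)):
            raise ValidationError(
                "duplicate coordinates with different values: hold-out prediction undefined"
            )
    errs = []
    for i in range(len(pts)):
        rest = np.delete(pts, i, axis=0)
        pred = idw_predict(rest, (pts[i, 0], pts[i, 1]), p, metric=metric, k=k)
        errs.append(pred - pts[i, 2])
    return float(np.sqrt(np.mean(np.square(errs))))


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid over a lat/lon bounding box.

    ``cell_size`` in degrees; predictions are made at cell centers.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float
    power: float = 2.0
    k: int | None = None
    metric: str = "haversine"

    def __post_init__(self) -> None:
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValidationError("degenerate bounding box")
        if not self.cell_size > 0:
            raise ValidationError("cell size must be > 0")
        if not self.power > 0:
            raise ValidationError("power must be > 0")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        lats = np.arange(self.lat_min + self.cell_size / 2, self.lat_max, self.cell_size)
        lons = np.arange(self.lon_min + self.cell_size / 2, self.lon_max, self.cell_size)
        return lats, lons


@dataclass
class Surface:
    """Gridded predicted concentrations for one metal (mg/kg)."""

    metal: str
    lats: np.ndarray        # cell-center latitudes, shape (nlat,)
    lons: np.ndarray        # cell-center longitudes, shape (nlon,)
    values: np.ndarray      # shape (nlat, nlon)

    def to_dataframe(self) -> pd.DataFrame:
        lat_g, lon_g = np.meshgrid(self.lats, self.lons, indexing="ij")
        return pd.DataFrame({
            "lat": lat_g.ravel(), "lon": lon_g.ravel(), "value": self.values.ravel(),
        })

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def make_surface(samples: SampleTable, metal: str, grid: GridSpec) -> Surface:
    """IDW-predict one metal over every grid cell center."""
    df = samples.data
    conc = pd.to_numeric(df[metal], errors="coerce")
    mask = conc.notna()
    if not mask.any():
        raise ValidationError(f"no non-missing values for metal {metal!r}")
    pts = np.column_stack([
        df.loc[mask, "lat"].to_numpy(float),
        df.loc[mask, "lon"].to_numpy(float),
        conc[mask].to_numpy(float),
    ])
    lats, lons = grid.centers()
    values = np.empty((len(lats), len(lons)))
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            values[i, j] = idw_predict(pts, (la, lo), grid.power,
                                       metric=grid.metric, k=grid.k)
    return Surface(metal, lats, lons, values)
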