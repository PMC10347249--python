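"""Inverse-distance-weighted interpolation of point samples onto a grid.

Point measurements (station suitability indices, soil salinity) are spread
onto a regular lon/lat raster with IDW: each cell takes the weighted mean of
the k nearest samples with weights d^(-p). Distances use an equirectangular
local approximation (adequate for a study area a few degrees across), with a
great-circle option. A cultivated-land mask and a threshold classifier turn
the salinity surface into a four-class suitability map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "Grid",
    "IDWInterpolator",
    "idw_interpolate",
    "apply_mask",
    "classify_grid",
    "read_ascii_grid",
    "CLASS_LABELS",
]

EARTH_RADIUS_KM = 6371.0
CLASS_LABELS = ("suitable", "moderately suitable", "less suitable", "not suitable")


@dataclass
class Grid:
    """Regular lon/lat raster: origin at the lower-left cell center.

    ``values`` is (n_rows, n_cols) with row 0 the southernmost row; masked
    cells carry NaN. ``mask`` (optional) flags cultivated cells True.
    """

    lon0: float
    lat0: float
    cell_size: float
    n_rows: int
    n_cols: int
    values: np.ndarray = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have positive cell size and dimensions")
        if self.values is None:
            self.values = np.full((self.n_rows, self.n_cols), np.nan)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with ({self.n_rows}, {self.n_cols})"
            )
        if self.mask is not None and np.shape(self.mask) != (self.n_rows, self.n_cols):
            raise ValueError("mask shape does not match grid dimensions")

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) lon/lat coordinates, row-major from the south."""
        lons = self.lon0 + self.cell_size * np.arange(self.n_cols)
        lats = self.lat0 + self.cell_size * np.arange(self.n_rows)
        gx, gy = np.meshgrid(lons, lats)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def to_frame(self, value_name: str = "value") -> pd.DataFrame:
        pts = self.cell_centers()
        return pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1], value_name: self.values.ravel()})

    def write_ascii(self, path) -> None:
        """ESRI ASCII grid (row order: north to south; NODATA -9999)."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.lon0 - self.cell_size / 2:.10g}\n")
            fh.write(f"yllcorner {self.lat0 - self.cell_size / 2:.10g}\n")
            fh.write(f"cellsize {self.cell_size:.10g}\n")
            fh.write("NODATA_value -9999\n")
            vals = np.where(np.isnan(self.values), -9999.0, self.values)
            for row in vals[::-1]:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid written by :meth:`Grid.write_ascii`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows[::-1], dtype=float)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    cs = header["cellsize"]
    return Grid(
        lon0=header["xllcorner"] + cs / 2,
        lat0=header["yllcorner"] + cs / 2,
        cell_size=cs,
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        values=values,
    )


def _project(coords: np.ndarray, lat_ref: float, metric: str) -> np.ndarray:
    """Scale lon/lat to km for distance computation."""
    if metric == "equirectangular":
        k = math.pi / 180.0 * EARTH_RADIUS_KM
        out = np.empty_like(coords, dtype=float)
        out[:, 0] = coords[:, 0] * k * math.cos(math.radians(lat_ref))
        out[:, 1] = coords[:, 1] * k
        return out
    raise ValueError(f"unknown metric {metric!r}")


def _great_circle_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Haversine distances (km) between one point array and one point."""
    lon1, lat1 = np.radians(a[:, 0]), np.radians(a[:, 1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    h = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * math.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighted spatial predictor.

    Parameters
    ----------
    power : float, default 2.0
        Distance-decay exponent p in w = d^(-p).
    k_neighbors : int or None, default None
        Number of nearest samples per prediction point; None uses all.
    metric : {'equirectangular', 'great_circle'}
        Distance model on lon/lat coordinates.
    eps_km : float
        A prediction point within this distance of a sample returns the
        sample value exactly.
    """

    def __init__(
        self,
        power: float = 2.0,
        k_neighbors: int | None = None,
        metric: str = "equirectangular",
        eps_km: float = 1e-9,
    ):
        self.power = power
        self.k_neighbors = k_neighbors
        self.metric = metric
        self.eps_km = eps_km

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must be (n, 2) lon/lat coordinates")
        if self.power <= 0:
            raise ValueError("power must be positive")
        self.X_ = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        self.lat_ref_ = float(np.mean(self.X_[:, 1]))
        if self.metric == "equirectangular":
            self._xy = _project(self.X_, self.lat_ref_, self.metric)
            self.tree_ = cKDTree(self._xy)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = check_array(np.asarray(X, dtype=float))
        n = self.X_.shape[0]
        k = n if self.k_neighbors is None else min(self.k_neighbors, n)
        if self.metric == "equirectangular":
            q = _project(X, self.lat_ref_, self.metric)
            d, idx = self.tree_.query(q, k=k)
            if k == 1:
                d, idx = d[:, None], idx[:, None]
        else:
            d = np.vstack([_great_circle_km(self.X_, row) for row in X])
            idx = np.argsort(d, axis=1)[:, :k]
            d = np.take_along_axis(d, idx, axis=1)
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            di, vi = d[i], self.y_[idx[i]]
            if di[0] < self.eps_km:
                out[i] = vi[0]
                continue
            w = di ** (-self.power)
            out[i] = float(np.dot(w, vi) / w.sum())
        return out


def idw_interpolate(
    samples: pd.DataFrame,
    grid: Grid,
    power: float = 2.0,
    k_neighbors: int | None = None,
    metric: str = "equirectangular",
) -> Grid:
    """Interpolate (lon, lat, value) samples onto the grid geometry."""
    if len(samples) == 0:
        raise ValueError("at least one sample is required")
    est = IDWInterpolator(power=power, k_neighbors=k_neighbors, metric=metric)
    est.fit(samples[["lon", "lat"]].to_numpy(), samples["value"].to_numpy())
    vals = est.predict(grid.cell_centers()).reshape(grid.n_rows, grid.n_cols)
    return Grid(grid.lon0, grid.lat0, grid.cell_size, grid.n_rows, grid.n_cols, vals, grid.mask)


def apply_mask(grid: Grid, mask: np.ndarray) -> Grid:
    """Blank non-cultivated cells (mask False -> NaN); True cells unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.values.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.values.shape}")
    vals = np.where(mask, grid.values, np.nan)
    return Grid(grid.lon0, grid.lat0, grid.cell_size, grid.n_rows, grid.n_cols, vals, mask)


def classify_grid(grid: Grid, thresholds: tuple[float, float, float]) -> Grid:
    """Label each cell 0..3 (suitable .. not suitable) by salinity breakpoints.

    Interval edges belong to the more-suitable class: value <= t1 is class 0,
    t1 < value <= t2 class 1, t2 < value <= t3 class 2, value > t3 class 3.
    Masked/NaN cells stay NaN.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.size != 3 or not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be three strictly increasing breakpoints")
    v = grid.values
    labels = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    labels[ok] = np.searchsorted(t, v[ok], side="left")
    return Grid(grid.lon0, grid.lat0, grid.cell_size, grid.n_rows, grid.n_cols, labels, grid.mask)
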