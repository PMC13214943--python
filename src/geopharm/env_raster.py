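"""Scattered-point environmental fields interpolated onto a global raster.

Scattered (lat, lon, value) measurement points are triangulated (Delaunay,
in planar lon/lat degree coordinates — no spherical correction, no
antimeridian wrap) and each raster cell center inside the convex hull gets
the barycentric-weighted (piecewise-linear) combination of its triangle's
vertex values; cells outside the hull (chiefly polar caps) are filled with
the nearest measurement point's value.

The Delaunay construction is delegated to ``scipy.spatial.Delaunay``; point
location and barycentric evaluation are implemented here.  Ties where a
query sits on a shared edge are resolved by the first containing triangle
in ascending triangle-index order (the values agree from either side, so
the choice affects only bookkeeping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "OUTSIDE_HULL",
    "RasterGrid",
    "Triangulation",
    "EnvironmentalRaster",
    "build_grid",
    "triangulate",
    "interpolate_linear",
    "fill_nearest",
    "build_raster",
]

#: Marker returned by :func:`interpolate_linear` for queries outside the
#: convex hull of the measurement network.
OUTSIDE_HULL = float("nan")

_EPS = 1e-12  # barycentric containment slack


@dataclass(frozen=True)
class RasterGrid:
    """Regular global grid of cell centers at a fixed resolution."""

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    resolution: float

    @property
    def n_cells(self) -> int:
        return len(self.lat_centers) * len(self.lon_centers)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lat_centers), len(self.lon_centers)


def build_grid(resolution: float) -> RasterGrid:
    """Global grid with cell centers at half-resolution offsets from the
    -90/-180 corner; ``resolution`` must divide 180 evenly (1 degree gives
    180 x 360 = 64,800 cells)."""
    if resolution <= 0:
        raise InvalidInputError("resolution must be positive")
    nlat = 180.0 / resolution
    if abs(nlat - round(nlat)) > 1e-9:
        raise InvalidInputError(f"resolution {resolution} does not divide 180")
    nlat = int(round(nlat))
    nlon = 2 * nlat
    lat = -90.0 + (np.arange(nlat) + 0.5) * resolution
    lon = -180.0 + (np.arange(nlon) + 0.5) * resolution
    return RasterGrid(lat_centers=lat, lon_centers=lon, resolution=float(resolution))


def _as_points(points) -> tuple[np.ndarray, np.ndarray]:
    """Extract (n, 2) planar (lon, lat) coordinates and values."""
    if isinstance(points, pd.DataFrame):
        xy = points[["lon", "lat"]].to_numpy(dtype=float)
        vals = points["value"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        xy = arr[:, [1, 0]]  # rows are (lat, lon, value)
        vals = arr[:, 2]
    if not np.all(np.abs(xy[:, 1]) <= 90.0):
        raise InvalidInputError("latitude outside [-90, 90]")
    return xy, vals


@dataclass
class Triangulation:
    """Delaunay triangulation of a measurement network, with precomputed
    per-triangle barycentric transforms."""

    xy: np.ndarray            # (n, 2) planar (lon, lat)
    values: np.ndarray        # (n,)
    simplices: np.ndarray     # (nt, 3) vertex indices
    hull: np.ndarray          # hull vertex indices, counterclockwise
    _tinv: np.ndarray = field(repr=False, default=None)  # (nt, 2, 2)
    _ref: np.ndarray = field(repr=False, default=None)   # (nt, 2) third vertex

    def __post_init__(self):
        if self._tinv is None:
            a = self.xy[self.simplices[:, 0]]
            b = self.xy[self.simplices[:, 1]]
            c = self.xy[self.simplices[:, 2]]
            # columns of M are edge vectors; weights solve M @ (w0, w1) = q - c
            m = np.stack([a - c, b - c], axis=-1)           # (nt, 2, 2)
            det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
            inv = np.empty_like(m)
            inv[:, 0, 0] = m[:, 1, 1]
            inv[:, 0, 1] = -m[:, 0, 1]
            inv[:, 1, 0] = -m[:, 1, 0]
            inv[:, 1, 1] = m[:, 0, 0]
            self._tinv = inv / det[:, None, None]
            self._ref = c

    @property
    def n_triangles(self) -> int:
        return len(self.simplices)

    def barycentric(self, tri_index: int, query_xy: np.ndarray) -> np.ndarray:
        """Barycentric weights of planar queries w.r.t. one triangle."""
        q = np.atleast_2d(np.asarray(query_xy, dtype=float))
        w01 = (self._tinv[tri_index] @ (q - self._ref[tri_index]).T).T
        return np.column_stack([w01, 1.0 - w01.sum(axis=1)])


def triangulate(points) -> Triangulation:
    """Delaunay-triangulate measurement points in planar (lon, lat) degrees.

    Raises :class:`DegenerateGeometryError` for fewer than three points or a
    collinear network.
    """
    xy, vals = _as_points(points)
    if len(xy) < 3:
        raise DegenerateGeometryError("need at least 3 points to triangulate")
    try:
        dt = Delaunay(xy)
        hull = ConvexHull(xy).vertices
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    if dt.simplices.size == 0:
        raise DegenerateGeometryError("all points are collinear")
    order = np.lexsort(dt.simplices.T[::-1])  # stable triangle scan order
    return Triangulation(xy=xy, values=vals,
                         simplices=np.sort(dt.simplices, axis=1)[order],
                         hull=hull)


def _locate(tri: Triangulation, query_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First containing triangle (ascending index scan) and barycentric
    weights for each planar query; -1 where outside every triangle."""
    q = np.atleast_2d(np.asarray(query_xy, dtype=float))
    nq = len(q)
    found = np.full(nq, -1, dtype=int)
    weights = np.zeros((nq, 3))
    # vectorised over triangles in chunks; first containing triangle wins
    chunk = max(1, int(2e6) // max(nq, 1))
    for t0 in range(0, tri.n_triangles, chunk):
        t1 = min(t0 + chunk, tri.n_triangles)
        todo = np.flatnonzero(found < 0)
        if todo.size == 0:
            break
        d = q[todo, None, :] - tri._ref[None, t0:t1, :]            # (m, tc, 2)
        w01 = np.einsum("tij,mtj->mti", tri._tinv[t0:t1], d)       # (m, tc, 2)
        w2 = 1.0 - w01.sum(axis=2, keepdims=True)
        w = np.concatenate([w01, w2], axis=2)                      # (m, tc, 3)
        inside = (w >= -_EPS).all(axis=2)                          # (m, tc)
        has = inside.any(axis=1)
        first = inside.argmax(axis=1)
        hit = todo[has]
        found[hit] = t0 + first[has]
        weights[hit] = w[has, first[has]]
    return found, weights


def interpolate_linear(points, tri: Triangulation, query: tuple[float, float]):
    """Piecewise-linear value at ``query = (lat, lon)``: the barycentric
    combination of the containing triangle's vertex values, or
    :data:`OUTSIDE_HULL` (NaN) outside the hull."""
    lat, lon = query
    idx, w = _locate(tri, np.array([[lon, lat]]))
    if idx[0] < 0:
        return OUTSIDE_HULL
    verts = tri.simplices[idx[0]]
    return float(w[0] @ tri.values[verts])


def fill_nearest(points, query: tuple[float, float]) -> float:
    """Value of the point nearest the query in planar (lon, lat) Euclidean
    distance; ties go to the lowest point index."""
    xy, vals = _as_points(points)
    if len(xy) == 0:
        raise InvalidInputError("empty point set")
    lat, lon = query
    d2 = (xy[:, 0] - lon) ** 2 + (xy[:, 1] - lat) ** 2
    return float(vals[int(np.argmin(d2))])


def _interpolate_field_on_grid(points, grid: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate one field onto every grid cell center.

    Returns (values, nearest_flag) shaped (nlat, nlon); nearest_flag marks
    cells outside the convex hull that received nearest-neighbour fill.
    """
    xy, vals = _as_points(points)
    tri = triangulate(points)
    lon_g, lat_g = np.meshgrid(grid.lon_centers, grid.lat_centers)
    q = np.column_stack([lon_g.ravel(), lat_g.ravel()])
    idx, w = _locate(tri, q)
    out = np.empty(len(q))
    inside = idx >= 0
    vi = tri.simplices[idx[inside]]                  # (m, 3)
    out[inside] = np.einsum("mi,mi->m", w[inside], tri.values[vi])
    # nearest-neighbour fill outside the hull, chunked argmin (lowest index
    # wins ties by argmin semantics)
    out_idx = np.flatnonzero(~inside)
    for c0 in range(0, out_idx.size, 4096):
        sel = out_idx[c0:c0 + 4096]
        d2 = ((q[sel, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        out[sel] = vals[np.argmin(d2, axis=1)]
    return out.reshape(grid.shape), (~inside).reshape(grid.shape)


@dataclass
class EnvironmentalRaster:
    """Per-cell UV and PM2.5 values on a :class:`RasterGrid`, with flags
    recording which cells required nearest-neighbour fill."""

    grid: RasterGrid
    uv_annual: np.ndarray     # (nlat, nlon) UVI
    pm25_ug_m3: np.ndarray    # (nlat, nlon) ug/m3
    uv_nearest: np.ndarray    # bool, True = filled outside UV hull
    pm25_nearest: np.ndarray

    def to_frame(self, include_fill_flag: bool = False) -> pd.DataFrame:
        """Long-form raster table (lat-major, lon-minor row order), columns
        lat, lon, UV_Annual, PM25_ug_m3 and optionally the fill flags."""
        lon_g, lat_g = np.meshgrid(self.grid.lon_centers, self.grid.lat_centers)
        df = pd.DataFrame({
            "lat": lat_g.ravel(),
            "lon": lon_g.ravel(),
            "UV_Annual": self.uv_annual.ravel(),
            "PM25_ug_m3": self.pm25_ug_m3.ravel(),
        })
        if include_fill_flag:
            flag = {True: "nearest-neighbour", False: "interpolated"}
            df["uv_fill"] = [flag[b] for b in self.uv_nearest.ravel()]
            df["pm25_fill"] = [flag[b] for b in self.pm25_nearest.ravel()]
        return df

    def write_csv(self, path: str | Path, include_fill_flag: bool = False) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame(include_fill_flag).to_csv(path, index=False)
        return path


def build_raster(uv_points, pm25_points, resolution: float = 1.0,
                 out_csv: str | Path | None = None) -> EnvironmentalRaster:
    """Interpolate both measurement networks onto a shared global grid.

    Every cell receives a finite value: linear interpolation inside each
    network's convex hull, nearest-neighbour fill outside it.
    """
    grid = build_grid(resolution)
    uv, uv_nn = _interpolate_field_on_grid(uv_points, grid)
    pm, pm_nn = _interpolate_field_on_grid(pm25_points, grid)
    raster = EnvironmentalRaster(grid=grid, uv_annual=uv, pm25_ug_m3=pm,
                                 uv_nearest=uv_nn, pm25_nearest=pm_nn)
    if out_csv is not None:
        raster.write_csv(out_csv)
    return raster
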