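"""Ordinary kriging of population values with a spherical semivariogram.

The empirical semivariogram is binned at equal lag widths up to half the
maximum pairwise great-circle distance; a spherical model
``gamma(h) = c0 + c1*(1.5 h/a - 0.5 (h/a)^3)`` for ``h <= a`` (sill
``c0 + c1`` beyond the range ``a``) is fitted by weighted least squares
with pair-count weights and a deterministic multi-start grid; the ordinary
kriging system is then solved at every grid node with the unbiasedness
constraint (weights summing to 1).  Great-circle distances feed the
variogram and the kriging system directly; no map projection is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares

from .datatypes import InvalidArgumentError
from .spatial import SpatialFrame, great_circle_km, pairwise_distances

NODATA = -9999.0


# ---------------------------------------------------------------------------
# Variogram
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalVariogram:
    h: np.ndarray        # lag-bin centers, km
    gamma: np.ndarray    # semivariance estimates, value-units^2
    counts: np.ndarray   # pairs per bin
    max_lag: float


@dataclass
class VariogramModel:
    """Spherical model: nugget c0, partial sill c1 (value-units²), range a (km)."""

    c0: float
    c1: float
    a: float
    model: str = "spherical"
    flat: bool = False   # set when fitted to an all-zero empirical variogram

    def __post_init__(self):
        if self.c0 < 0 or self.c1 < 0 or self.a <= 0:
            raise InvalidArgumentError("require c0 >= 0, c1 >= 0, a > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = np.minimum(h / self.a, 1.0)
        g = self.c0 + self.c1 * (1.5 * r - 0.5 * r ** 3)
        return np.where(h == 0.0, 0.0, g)  # gamma(0) = 0 by definition


def spherical_gamma(h, c0: float, c1: float, a: float) -> np.ndarray:
    """Spherical semivariogram evaluated at lags h > 0."""
    h = np.asarray(h, dtype=float)
    r = np.minimum(h / a, 1.0)
    return c0 + c1 * (1.5 * r - 0.5 * r ** 3)


def empirical_semivariogram(frame: SpatialFrame, n_lags: int = 10,
                            max_lag_km: Optional[float] = None) -> EmpiricalVariogram:
    """Method-of-moments semivariogram with equal-width lag bins.

    ``gamma(h) = (1/2N(h)) sum (z_i - z_j)^2`` over pairs whose distance
    falls in the bin; bins with no pairs are omitted.  Default maximum lag
    is half the maximum pairwise distance.
    """
    if frame.n < 5:
        raise InvalidArgumentError("need at least 5 sites for a semivariogram")
    d = pairwise_distances(frame)
    iu, ju = np.triu_indices(frame.n, k=1)
    dist = d[iu, ju]
    sq = (frame.values[iu] - frame.values[ju]) ** 2
    if max_lag_km is None:
        max_lag_km = float(dist.max()) / 2.0
    edges = np.linspace(0.0, max_lag_km, n_lags + 1)
    inside = dist <= max_lag_km
    which = np.clip(np.digitize(dist[inside], edges) - 1, 0, n_lags - 1)
    h, g, cnt = [], [], []
    for b in range(n_lags):
        sel = which == b
        if not np.any(sel):
            continue
        h.append(0.5 * (edges[b] + edges[b + 1]))
        g.append(0.5 * sq[inside][sel].mean())
        cnt.append(int(sel.sum()))
    return EmpiricalVariogram(h=np.array(h), gamma=np.array(g),
                              counts=np.array(cnt), max_lag=max_lag_km)


def fit_spherical(emp: EmpiricalVariogram) -> VariogramModel:
    """Fit the spherical model by pair-count-weighted least squares.

    Multi-start over a deterministic coarse grid (nugget and partial sill
    scaled by the empirical sill proxy max(gamma), range scaled by the
    maximum lag), refined by bounded least squares; the best weighted
    objective wins.  An all-zero empirical variogram returns a flat model
    with the ``flat`` flag set.
    """
    if emp.h.size < 3:
        raise InvalidArgumentError("need at least 3 non-empty lag bins")
    scale = float(emp.gamma.max())
    if scale <= 0.0:
        return VariogramModel(c0=0.0, c1=0.0, a=emp.max_lag, flat=True)
    w = np.sqrt(emp.counts.astype(float))
    lo = np.array([0.0, 0.0, 1e-9])
    hi = np.array([np.inf, np.inf, 2.0 * emp.max_lag])

    def resid(theta):
        return w * (spherical_gamma(emp.h, *theta) - emp.gamma)

    best, best_cost = None, np.inf
    for f0 in (0.0, 0.25, 0.5):
        for f1 in (0.5, 1.0):
            for fa in (0.25, 0.5, 1.0):
                x0 = np.array([f0 * scale, f1 * scale, fa * emp.max_lag])
                x0 = np.clip(x0, lo + 1e-12, hi)
                sol = least_squares(resid, x0, bounds=(lo, hi),
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15)
                if sol.cost < best_cost:
                    best, best_cost = sol.x, sol.cost
    return VariogramModel(c0=float(best[0]), c1=float(best[1]), a=float(best[2]))


# ---------------------------------------------------------------------------
# Grids and ordinary kriging
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular node-centered lat/lon grid with a single cell size (degrees)."""

    lat_min: float
    lon_min: float
    cellsize: float
    nrows: int
    ncols: int

    @classmethod
    def from_frame(cls, frame: SpatialFrame, ncols: int = 100,
                   padding: float = 0.05) -> "GridSpec":
        """Bounding box of the sites padded by ``padding`` per side."""
        lat0, lat1 = float(frame.lat.min()), float(frame.lat.max())
        lon0, lon1 = float(frame.lon.min()), float(frame.lon.max())
        dlat, dlon = max(lat1 - lat0, 1e-6), max(lon1 - lon0, 1e-6)
        lat0, lat1 = lat0 - padding * dlat, lat1 + padding * dlat
        lon0, lon1 = lon0 - padding * dlon, lon1 + padding * dlon
        cell = (lon1 - lon0) / (ncols - 1)
        nrows = max(2, int(np.ceil((lat1 - lat0) / cell)) + 1)
        return cls(lat_min=lat0, lon_min=lon0, cellsize=cell,
                   nrows=nrows, ncols=ncols)

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.cellsize * np.arange(self.nrows)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.cellsize * np.arange(self.ncols)


@dataclass
class KrigingGrid:
    """Predictions and kriging variances on a regular grid (lats ascending)."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray     # (nrows, ncols); NaN = no data
    variance: np.ndarray   # (nrows, ncols)

    def __post_init__(self):
        if self.values.shape != (self.lats.size, self.lons.size):
            raise InvalidArgumentError("grid value shape inconsistent with axes")


def ordinary_krige(frame: SpatialFrame, model: VariogramModel,
                   grid: Optional[GridSpec] = None) -> KrigingGrid:
    """Ordinary kriging predictions over a regular grid.

    Solves ``[Gamma 1; 1' 0] [lambda; mu] = [gamma0; 1]`` per node with
    ``Gamma_ij = gamma(d_ij)`` between sites and ``gamma0_i = gamma(d_i0)``
    site-to-node, all distances great-circle km.  Prediction is
    ``lambda' z``; kriging variance ``lambda' gamma0 + mu`` (tiny negative
    values from round-off are clipped to 0).
    """
    if frame.n < 3:
        raise InvalidArgumentError("need at least 3 sites to krige")
    d = pairwise_distances(frame)
    off = ~np.eye(frame.n, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        raise InvalidArgumentError(
            f"duplicate coordinates: {frame.names[i]!r} / {frame.names[j]!r}")
    if grid is None:
        grid = GridSpec.from_frame(frame)
    n = frame.n
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = model(d)
    K[n, :n] = K[:n, n] = 1.0
    K[n, n] = 0.0
    try:
        lu = lu_factor(K)
    except Exception as exc:  # pragma: no cover - scipy raises LinAlgError
        raise InvalidArgumentError(f"singular kriging system: {exc}")

    glats, glons = grid.lats, grid.lons
    gg_lat = np.repeat(glats, glons.size)
    gg_lon = np.tile(glons, glats.size)
    d0 = great_circle_km(frame.lat[:, None], frame.lon[:, None],
                         gg_lat[None, :], gg_lon[None, :])
    rhs = np.vstack([model(d0), np.ones(gg_lat.size)])
    sol = lu_solve(lu, rhs)
    lam, mu = sol[:n], sol[n]
    wsum = lam.sum(axis=0)
    if np.any(np.abs(wsum - 1.0) > 1e-8):
        raise InvalidArgumentError("kriging weights failed the unbiasedness constraint")
    pred = lam.T @ frame.values
    var = np.einsum("ij,ij->j", lam, model(d0)) + mu
    if np.any(var < -1e-9):
        raise InvalidArgumentError("negative kriging variance beyond numerical floor")
    var = np.clip(var, 0.0, None)
    shape = (glats.size, glons.size)
    return KrigingGrid(lats=glats, lons=glons,
                       values=pred.reshape(shape), variance=var.reshape(shape))


# ---------------------------------------------------------------------------
# ESRI ASCII grid export
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: KrigingGrid, path) -> None:
    """Write predictions as an ESRI ASCII grid (row-major from north).

    Node-centered values; the header's llcorner is offset by half a cell.
    NaN nodes are written as the NODATA value.
    """
    dlat = np.diff(grid.lats)
    dlon = np.diff(grid.lons)
    if dlat.size == 0 or dlon.size == 0:
        raise InvalidArgumentError("grid must have at least 2 rows and columns")
    cell = dlon[0]
    if (np.any(np.abs(dlat - cell) > 1e-9) or np.any(np.abs(dlon - cell) > 1e-9)):
        raise InvalidArgumentError("irregular grid: need one common cell size")
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.lons.size}\n")
        fh.write(f"nrows {grid.lats.size}\n")
        fh.write(f"xllcorner {grid.lons[0] - cell / 2.0:.10f}\n")
        fh.write(f"yllcorner {grid.lats[0] - cell / 2.0:.10f}\n")
        fh.write(f"cellsize {cell:.10f}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        for row in vals[::-1]:  # from north
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> KrigingGrid:
    """Read back an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    vals = np.array([[float(v) for v in line.split()] for line in lines[6:6 + nrows]])
    vals = vals[::-1]
    vals[vals == header["nodata_value"]] = np.nan
    lats = header["yllcorner"] + cell / 2.0 + cell * np.arange(nrows)
    lons = header["xllcorner"] + cell / 2.0 + cell * np.arange(ncols)
    return KrigingGrid(lats=lats, lons=lons, values=vals,
                       variance=np.full_like(vals, np.nan))
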