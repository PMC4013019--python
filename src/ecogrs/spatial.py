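"""Spatial autocorrelation of population-level values.

Great-circle distances (haversine on a sphere of mean radius 6371.0088 km),
spatial weight matrices (inverse-distance, binary-threshold or
distance-class binary; optionally row standardized), global Moran's I and
Geary's C with randomization (permutation) tests, and equal-count
distance-class correlograms.

Defaults follow the directional hypothesis of positive spatial
autocorrelation of a clinal surface: the Moran test is one-sided "greater"
and the Geary test one-sided "less"; correlogram classes are tested
two-sided because long-range classes of a cline are expected negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import InvalidArgumentError, UndefinedResultError

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


# ---------------------------------------------------------------------------
# Frames, distances, weights
# ---------------------------------------------------------------------------

@dataclass
class SpatialFrame:
    """Population values on geographic coordinates (decimal degrees)."""

    names: list
    lat: np.ndarray
    lon: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if not (self.lat.shape == self.lon.shape == self.values.shape == (n,)):
            raise InvalidArgumentError("names/lat/lon/values lengths differ")
        _check_coords(self.lat, self.lon)
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str,
                   name_col: str = "population") -> "SpatialFrame":
        return cls(names=df[name_col].tolist(), lat=df["lat"].to_numpy(),
                   lon=df["lon"].to_numpy(), values=df[value_col].to_numpy())


def _check_coords(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise InvalidArgumentError("coordinates must be finite")
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise InvalidArgumentError("coordinates out of range")


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (vectorised)."""
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((p2 - p1) / 2.0) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def pairwise_distances(frame: SpatialFrame) -> np.ndarray:
    """n x n symmetric great-circle distance matrix in km."""
    return great_circle_km(frame.lat[:, None], frame.lon[:, None],
                           frame.lat[None, :], frame.lon[None, :])


@dataclass
class SpatialWeights:
    """Non-negative weight matrix with zero diagonal."""

    matrix: np.ndarray
    scheme: str
    row_standardized: bool = False

    def __post_init__(self):
        w = np.asarray(self.matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError("weight matrix must be square")
        if np.any(w < 0) or np.any(np.diag(w) != 0):
            raise InvalidArgumentError("weights must be non-negative with zero diagonal")
        if w.sum() <= 0:
            raise InvalidArgumentError("weight matrix has zero total weight")
        self.matrix = w

    @property
    def s0(self) -> float:
        return float(self.matrix.sum())


def build_weights(frame: SpatialFrame, scheme: str = "inverse_distance",
                  threshold: Optional[float] = None,
                  d_range: Optional[tuple] = None,
                  row_standardize: bool = True) -> SpatialWeights:
    """Build a spatial weight matrix from great-circle distances.

    Schemes: ``inverse_distance`` (w = 1/d km), ``binary`` (w = 1 iff
    d <= threshold km), ``class`` (w = 1 iff d_range[0] <= d < d_range[1]).
    Row standardization divides each nonzero row by its sum.
    """
    if frame.n < 3:
        raise InvalidArgumentError("need at least 3 locations")
    d = pairwise_distances(frame)
    off = ~np.eye(frame.n, dtype=bool)
    if scheme == "inverse_distance":
        if np.any(d[off] == 0):
            i, j = np.argwhere((d == 0) & off)[0]
            raise InvalidArgumentError(
                f"duplicate coordinates: {frame.names[i]!r} and "
                f"{frame.names[j]!r} (infinite inverse-distance weight)")
        w = np.zeros_like(d)
        w[off] = 1.0 / d[off]
    elif scheme == "binary":
        if threshold is None:
            raise InvalidArgumentError("binary scheme needs a distance threshold")
        w = ((d <= threshold) & off).astype(float)
    elif scheme == "class":
        if d_range is None:
            raise InvalidArgumentError("class scheme needs a (lo, hi) distance range")
        lo, hi = d_range
        w = ((d >= lo) & (d < hi) & off).astype(float)
    else:
        raise InvalidArgumentError(f"unknown weighting scheme {scheme!r}")
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeights(matrix=w, scheme=scheme, row_standardized=row_standardize)


# ---------------------------------------------------------------------------
# Global statistics
# ---------------------------------------------------------------------------

def _centered(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    if np.all(z == 0):
        raise UndefinedResultError("zero variance in values")
    return z


def morans_i(values, W: SpatialWeights) -> float:
    """Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i² (z centered)."""
    z = _centered(values)
    n = z.size
    return float((n / W.s0) * (z @ W.matrix @ z) / (z @ z))


def gearys_c(values, W: SpatialWeights) -> float:
    """Geary's C = ((n-1)/(2 S0)) * sum_ij w_ij (x_i - x_j)² / sum_i z_i²."""
    x = np.asarray(values, dtype=float)
    z = _centered(values)
    n = z.size
    diff2 = (x[:, None] - x[None, :]) ** 2
    return float(((n - 1) / (2.0 * W.s0)) * np.sum(W.matrix * diff2) / (z @ z))


@dataclass
class AutocorrResult:
    statistic: str          # "I" or "C"
    observed: float
    perm_mean: float
    p: float
    n_perm: int
    alternative: str
    seed: int


def _perm_stats(stat: str, values: np.ndarray, W: SpatialWeights,
                perms: np.ndarray) -> np.ndarray:
    """Statistic over rows of a (n_perm, n) matrix of permuted values."""
    n = values.size
    if stat == "I":
        Z = perms - perms.mean(axis=1, keepdims=True)
        denom = np.einsum("ij,ij->i", Z, Z)
        quad = np.einsum("ij,jk,ik->i", Z, W.matrix, Z)
        return (n / W.s0) * quad / denom
    # Geary: expand sum w_ij (x_i - x_j)^2 = sum_ij w_ij (x_i^2 + x_j^2 - 2 x_i x_j)
    Z = perms - perms.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", Z, Z)
    X2 = perms ** 2
    row = W.matrix.sum(axis=1)
    col = W.matrix.sum(axis=0)
    s_sq = X2 @ row + X2 @ col
    cross = np.einsum("ij,jk,ik->i", perms, W.matrix, perms)
    num = s_sq - 2.0 * cross
    return ((n - 1) / (2.0 * W.s0)) * num / denom


def randomization_test(stat: str, values, W: SpatialWeights,
                       n_perm: int = 999, alternative: Optional[str] = None,
                       seed: int = 0) -> AutocorrResult:
    """Permutation test of Moran's I or Geary's C.

    Values are permuted over locations ``n_perm`` times;
    ``p = (1 + #extreme) / (n_perm + 1)`` with the observed arrangement
    counted among the permutations.  Default alternatives target positive
    spatial autocorrelation ("greater" for I, "less" for C); "two-sided"
    doubles the smaller tail.
    """
    if stat not in ("I", "C"):
        raise InvalidArgumentError("stat must be 'I' or 'C'")
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InvalidArgumentError("need n >= 4 for a randomization test")
    if n_perm < 99:
        raise InvalidArgumentError("need at least 99 permutations")
    if alternative is None:
        alternative = "greater" if stat == "I" else "less"
    func = morans_i if stat == "I" else gearys_c
    observed = func(x, W)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    sims = _perm_stats(stat, x, W, perms)
    tol = 1e-12 * max(1.0, abs(observed))
    n_ge = int(np.sum(sims >= observed - tol))
    n_le = int(np.sum(sims <= observed + tol))
    if alternative == "greater":
        p = (1 + n_ge) / (n_perm + 1)
    elif alternative == "less":
        p = (1 + n_le) / (n_perm + 1)
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min((1 + n_ge), (1 + n_le)) / (n_perm + 1))
    else:
        raise InvalidArgumentError(f"unknown alternative {alternative!r}")
    return AutocorrResult(statistic=stat, observed=observed,
                          perm_mean=float(sims.mean()), p=float(p),
                          n_perm=n_perm, alternative=alternative, seed=seed)


# ---------------------------------------------------------------------------
# Correlogram
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Per-distance-class Moran/Geary statistics and permutation p-values."""

    table: pd.DataFrame  # class, d_min_km, d_max_km, n_pairs, moran_i, geary_c, p_i, p_c


def correlogram(frame: SpatialFrame, n_classes: int = 6, n_perm: int = 999,
                seed: int = 0, alternative: str = "two-sided") -> Correlogram:
    """Equal-count distance-class correlogram of Moran's I and Geary's C.

    All n(n-1)/2 pairwise distances are split into ``n_classes`` classes of
    near-equal pair counts (ties broken by a stable sort of pair index);
    each class defines a binary weight matrix over its pairs, on which both
    statistics and their permutation p-values are computed.
    """
    n = frame.n
    n_pairs = n * (n - 1) // 2
    if n_pairs < n_classes:
        raise InvalidArgumentError("fewer pairs than distance classes")
    d = pairwise_distances(frame)
    iu, ju = np.triu_indices(n, k=1)
    dist = d[iu, ju]
    order = np.argsort(dist, kind="stable")
    chunks = np.array_split(order, n_classes)
    if any(len(c) == 0 for c in chunks):
        raise InvalidArgumentError(
            "a distance class has zero pairs; use fewer classes")
    rows = []
    for c, chunk in enumerate(chunks, start=1):
        w = np.zeros((n, n))
        w[iu[chunk], ju[chunk]] = 1.0
        w[ju[chunk], iu[chunk]] = 1.0
        W = SpatialWeights(matrix=w, scheme="class")
        res_i = randomization_test("I", frame.values, W, n_perm=n_perm,
                                   alternative=alternative, seed=seed + c)
        res_c = randomization_test("C", frame.values, W, n_perm=n_perm,
                                   alternative=alternative, seed=seed + c)
        rows.append({"class": c,
                     "d_min_km": float(dist[chunk].min()),
                     "d_max_km": float(dist[chunk].max()),
                     "n_pairs": int(len(chunk)),
                     "moran_i": res_i.observed, "geary_c": res_c.observed,
                     "p_i": res_i.p, "p_c": res_c.p})
    return Correlogram(table=pd.DataFrame(rows))
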