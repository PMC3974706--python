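"""Spatial indices on yearly rectangle maps.

A *yearly map* is a DataFrame of rectangle observations for one survey year
with columns ``lat, lon`` (cell centres, degrees) and one or more value
columns (``density``, ``condition``).  Three families of indices are
computed on such maps:

Centre of gravity (COG)
    The value-weighted mean position, restricted to cells strictly above the
    within-year median of the variable so that the index tracks the location
    of *maximum* density or condition.  Uncertainty comes from exact
    leave-one-out enumeration: the COG is recomputed with each cell deleted
    in turn, the point estimate is the coordinate-wise median of the
    resulting distribution and the 95% interval its 2.5-97.5 percentile
    range.  The scheme is fully deterministic (no resampling RNG).

COG separation
    Per-year signed and absolute differences between two COG series (e.g.
    density vs condition), plus their Euclidean distance in degree space;
    diverging series diagnose spatially opposed fields.

Moran's I
    Spatial autocorrelation as a patchiness proxy,

        I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with distance-decay weights ``w_ij = 1 - d_ij / d_max`` (``d`` Euclidean
    in degree space by default, zero diagonal, the farthest pair getting
    weight zero) and ``S0`` the sum of all weights.  Values toward +1
    indicate clustering (patchy fields), toward -1 dispersion; the null
    expectation is ``-1/(n-1)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from seascape.errors import DegenerateSpatialError, InsufficientDataError

logger = logging.getLogger(__name__)

_EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class CogEstimate:
    """Centre of gravity for one year and variable with leave-one-out CI."""

    year: int
    variable: str
    lat: float
    lon: float
    lat_lo: float
    lat_hi: float
    lon_lo: float
    lon_hi: float
    n_used: int


@dataclass(frozen=True)
class MoranResult:
    """Moran's I for one yearly map; ``expected_null`` is -1/(n-1)."""

    year: int
    variable: str
    I: float
    n: int
    expected_null: float


class DegenerateYearWarning(UserWarning):
    """All values equal within a year: the above-median subset is empty."""


def above_median_filter(ymap: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Cells whose ``variable`` is strictly above the within-year median.

    Ties at the median are excluded.  If all values are equal the subset is
    empty and a :class:`DegenerateYearWarning` is emitted.
    """
    values = ymap[variable]
    if values.notna().sum() < 2:
        raise InsufficientDataError(
            f"above_median_filter needs >= 2 cells with {variable!r}"
        )
    sub = ymap[values > values.median()]
    if sub.empty:
        warnings.warn(
            f"degenerate year: all {variable!r} values equal; empty above-median subset",
            DegenerateYearWarning,
            stacklevel=2,
        )
    return sub


def centre_of_gravity(ymap: pd.DataFrame, variable: str) -> tuple[float, float]:
    """Weighted mean position (lat, lon) with ``variable`` as weights.

    Raises
    ------
    DegenerateSpatialError
        If all weights are zero (COG undefined).
    """
    w = ymap[variable].to_numpy(dtype=float)
    if len(w) == 0:
        raise InsufficientDataError("centre_of_gravity: empty map")
    if np.any(w < 0):
        raise ValueError("centre_of_gravity: negative weights")
    if w.sum() == 0:
        raise DegenerateSpatialError("centre_of_gravity: all weights zero")
    lat = float(np.average(ymap["lat"].to_numpy(dtype=float), weights=w))
    lon = float(np.average(ymap["lon"].to_numpy(dtype=float), weights=w))
    return lat, lon


def _leave_one_out_cogs(ymap: pd.DataFrame, variable: str) -> np.ndarray:
    """All n delete-one COGs, shape (n, 2), columns (lat, lon)."""
    w = ymap[variable].to_numpy(dtype=float)
    lat = ymap["lat"].to_numpy(dtype=float)
    lon = ymap["lon"].to_numpy(dtype=float)
    sw, swlat, swlon = w.sum(), (w * lat).sum(), (w * lon).sum()
    denom = sw - w
    if np.any(denom <= 0):
        raise DegenerateSpatialError(
            "leave-one-out COG undefined: a single cell carries all weight"
        )
    return np.column_stack(((swlat - w * lat) / denom, (swlon - w * lon) / denom))


def jackknife_cog(
    ymap: pd.DataFrame,
    variable: str,
    *,
    min_cells: int = 10,
    ci_level: float = 0.95,
    above_median: bool = True,
    year: int | None = None,
) -> CogEstimate | None:
    """Above-median COG with exact leave-one-out confidence interval.

    The map is first restricted to cells strictly above the within-year
    median of ``variable`` (disable with ``above_median=False``).  The COG is
    then recomputed with every cell deleted in turn; the point estimate is
    the coordinate-wise median of those n COGs and the CI the central
    ``ci_level`` percentile interval, per coordinate.

    Returns ``None`` when fewer than ``min_cells`` cells survive filtering:
    such years are excluded to preserve consistent spatial coverage.
    """
    sub = above_median_filter(ymap, variable) if above_median else ymap
    n = len(sub)
    if n < min_cells:
        logger.info(
            "year %s variable %s excluded: %d cells after filtering < min_cells=%d",
            year, variable, n, min_cells,
        )
        return None
    loo = _leave_one_out_cogs(sub, variable)
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    lat_lo, lat_hi = np.percentile(loo[:, 0], [alpha, 100.0 - alpha])
    lon_lo, lon_hi = np.percentile(loo[:, 1], [alpha, 100.0 - alpha])
    if year is None:
        year = int(sub["year"].iloc[0]) if "year" in sub.columns else -1
    return CogEstimate(
        year=int(year),
        variable=variable,
        lat=float(np.median(loo[:, 0])),
        lon=float(np.median(loo[:, 1])),
        lat_lo=float(lat_lo),
        lat_hi=float(lat_hi),
        lon_lo=float(lon_lo),
        lon_hi=float(lon_hi),
        n_used=n,
    )


def cog_separation(cogs_a: pd.DataFrame, cogs_b: pd.DataFrame) -> pd.DataFrame:
    """Per-year separation between two COG series (inner join on year).

    Parameters
    ----------
    cogs_a, cogs_b
        Tables with columns ``year, lat, lon`` (extra columns ignored).

    Returns
    -------
    DataFrame
        ``year, dlat, dlon, abs_dlat, abs_dlon, distance`` where the signed
        differences are a minus b and ``distance`` is the Euclidean norm in
        degree space.  Empty (with a warning) if the year sets are disjoint.
    """
    merged = cogs_a.merge(cogs_b, on="year", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        logger.warning("cog_separation: no overlapping years")
    out = pd.DataFrame({"year": merged["year"]})
    out["dlat"] = merged["lat_a"] - merged["lat_b"]
    out["dlon"] = merged["lon_a"] - merged["lon_b"]
    out["abs_dlat"] = out["dlat"].abs()
    out["abs_dlon"] = out["dlon"].abs()
    out["distance"] = np.hypot(out["dlat"], out["dlon"])
    return out.sort_values("year").reset_index(drop=True)


def _great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) from (lat, lon) degrees."""
    rad = np.radians(coords)
    dlat = rad[:, None, 0] - rad[None, :, 0]
    dlon = rad[:, None, 1] - rad[None, :, 1]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(rad[:, None, 0]) * np.cos(rad[None, :, 0]) * np.sin(dlon / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def moran_weights(coords, metric: str = "degrees") -> np.ndarray:
    """Distance-decay weight matrix ``w_ij = 1 - d_ij / d_max``.

    ``coords`` is an (n, 2) array of (lat, lon).  By default ``d`` is the
    Euclidean distance in raw degree space (matching the conventional
    computation on survey grids); ``metric="great_circle_km"`` switches to
    haversine distances for reuse at larger extents.  The diagonal is forced
    to zero (self-pairs are excluded from the index), the matrix is
    symmetric, entries lie in [0, 1] and the farthest pair has weight 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("moran_weights: coords must be an (n>=2, 2) array")
    if metric == "degrees":
        d = cdist(coords, coords)
    elif metric == "great_circle_km":
        d = _great_circle_km(coords)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    d_max = d.max()
    if d_max == 0:
        raise DegenerateSpatialError("moran_weights: all points coincident (d_max = 0)")
    w = 1.0 - d / d_max
    np.fill_diagonal(w, 0.0)
    return w


def moran_i(
    values,
    weights: np.ndarray,
    *,
    year: int = -1,
    variable: str = "",
) -> MoranResult:
    """Moran's I of ``values`` under the given weight matrix.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 observations.
    DegenerateSpatialError
        Zero variance (constant seascape): I is undefined.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"moran_i needs n >= 3, got {n}")
    if weights.shape != (n, n):
        raise ValueError("moran_i: weights shape does not match values")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateSpatialError("moran_i undefined: zero variance")
    s0 = float(weights.sum())
    i_val = (n / s0) * float(z @ weights @ z) / denom
    return MoranResult(
        year=int(year),
        variable=variable,
        I=i_val,
        n=n,
        expected_null=-1.0 / (n - 1),
    )
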