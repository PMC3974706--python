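"""Yearly means, spatial correlations and autocorrelation-adjusted tests.

Two kinds of correlation are computed.  *Spatial* correlations relate
density to condition across rectangles within one year (Spearman, so any
monotone density-condition coupling scores +/-1 regardless of its shape).
*Temporal* associations relate year-indexed series to one another; because
survey time series are autocorrelated, their Spearman tests use an effective
sample size in place of n (modified Chelton estimator):

    1/n_eff = 1/n + (2/n) * sum_{j=1..L} r_xx(j) * r_yy(j),   L = floor(n/5)

with r_xx, r_yy the sample autocorrelations of the two series.  n_eff is
clipped to [2, n] and the p-value comes from the t approximation with
n_eff - 2 degrees of freedom (fractional df are accepted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import acf

from seascape.errors import InsufficientDataError

logger = logging.getLogger(__name__)

#: Minimum complete (density, condition) pairs for a yearly spatial rho.
MIN_SPATIAL_PAIRS = 4

#: Minimum overlapping years for a temporal association test.
MIN_OVERLAP = 5


@dataclass(frozen=True)
class CorrelationTest:
    """Spearman association with autocorrelation-adjusted significance.

    ``n_eff`` is the effective sample size in [2, n]; ``p_raw`` uses n - 2
    degrees of freedom, ``p_adjusted`` uses n_eff - 2.
    """

    rho: float
    n: int
    n_eff: float
    p_raw: float
    p_adjusted: float


def yearly_means(observations: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-year means of density and condition over cells.

    Cells lacking condition are skipped for the condition mean only.
    Returns a DataFrame indexed by year with columns
    ``mean_density, mean_condition``.
    """
    if observations.empty:
        raise InsufficientDataError("yearly_means: empty observation table")
    cols = {"mean_density": ("density", "mean")}
    if "condition" in observations.columns:
        cols["mean_condition"] = ("condition", "mean")
    out = observations.groupby("year").agg(**cols).sort_index()
    if "mean_condition" not in out.columns:
        out["mean_condition"] = np.nan
    return out


def spatial_correlation_by_year(
    observations: pd.DataFrame, min_pairs: int = MIN_SPATIAL_PAIRS
) -> pd.DataFrame:
    """Spearman rho between density and condition across cells, per year.

    Pairwise-complete: cells missing either variable are dropped.  Years
    with fewer than ``min_pairs`` complete pairs are omitted with a warning.
    Returns ``year, rho, n_cells`` (year-sorted).
    """
    rows = []
    for year, grp in observations.groupby("year"):
        pairs = grp[["density", "condition"]].dropna()
        if len(pairs) < min_pairs:
            logger.warning(
                "year %s omitted from spatial correlation: %d complete pairs < %d",
                year, len(pairs), min_pairs,
            )
            continue
        rho = stats.spearmanr(pairs["density"], pairs["condition"]).statistic
        rows.append({"year": year, "rho": float(rho), "n_cells": len(pairs)})
    return pd.DataFrame(rows, columns=["year", "rho", "n_cells"])


def _spearman_t_pvalue(rho: float, df: float) -> float:
    """Two-sided p for Spearman rho via the t approximation with ``df`` df."""
    if df <= 0:
        return 1.0
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * math.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(t, df))


def effective_sample_size(
    x: np.ndarray, y: np.ndarray, max_lag: int | None = None
) -> float:
    """Modified-Chelton effective sample size for two aligned series.

    ``max_lag`` defaults to floor(n/5).  The result is clipped to [2, n];
    if the estimated 1/n_eff is non-positive (negative autocorrelation
    products) the clip returns n.
    """
    n = len(x)
    if max_lag is None:
        max_lag = n // 5
    max_lag = max(0, min(max_lag, n - 2))
    if max_lag == 0:
        return float(n)
    r_xx = acf(x, nlags=max_lag, fft=False)
    r_yy = acf(y, nlags=max_lag, fft=False)
    inv = 1.0 / n + (2.0 / n) * float(np.sum(r_xx[1:] * r_yy[1:]))
    if inv <= 0:
        return float(n)
    return float(np.clip(1.0 / inv, 2.0, n))


def adjusted_spearman(
    x: pd.Series, y: pd.Series, max_lag: int | None = None
) -> CorrelationTest:
    """Spearman association between two year-indexed series, adjusted for
    autocorrelation.

    The series are aligned on their common (sorted) years.  rho is the
    ordinary Spearman coefficient; significance is tested twice, with n - 2
    df (``p_raw``) and with n_eff - 2 df (``p_adjusted``) where n_eff comes
    from :func:`effective_sample_size` on the aligned raw series.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 overlapping years.
    """
    common = x.index.intersection(y.index).sort_values()
    if len(common) < MIN_OVERLAP:
        raise InsufficientDataError(
            f"adjusted_spearman needs >= {MIN_OVERLAP} overlapping years, "
            f"got {len(common)}"
        )
    xa = x.loc[common].to_numpy(dtype=float)
    ya = y.loc[common].to_numpy(dtype=float)
    n = len(common)
    rho = float(stats.spearmanr(xa, ya).statistic)
    n_eff = effective_sample_size(xa, ya, max_lag=max_lag)
    return CorrelationTest(
        rho=rho,
        n=n,
        n_eff=n_eff,
        p_raw=_spearman_t_pvalue(rho, n - 2),
        p_adjusted=_spearman_t_pvalue(rho, n_eff - 2.0),
    )


#: The association tests reported by the pipeline, in output order.
HEADLINE_PAIRS = (
    "mean_density_vs_mean_condition",
    "cog_lat_density_vs_condition",
    "cog_lon_density_vs_condition",
    "spatial_rho_vs_mean_density",
    "moran_density_vs_mean_density",
    "cog_separation_vs_year",
)


def headline_associations(
    *,
    means: pd.DataFrame,
    cog: pd.DataFrame,
    spatial_rho: pd.DataFrame,
    moran: pd.DataFrame,
    separation: pd.DataFrame,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """The pipeline's six temporal association tests.

    Tests (all autocorrelation-adjusted Spearman):

    1. mean yearly density vs mean yearly condition;
    2. COG latitude of density vs COG latitude of condition;
    3. same for longitude;
    4. yearly spatial density-condition rho vs mean yearly density;
    5. Moran's I of density vs mean yearly density;
    6. COG separation distance vs year (trajectory divergence).

    Parameters are the pipeline's own tables (see :mod:`seascape.pipeline`).
    Pairs with insufficient overlap are skipped with a warning; if every
    pair is insufficient an :class:`InsufficientDataError` is raised.

    Returns ``pair, rho, n, n_eff, p_raw, p_adjusted``.
    """
    def series(df: pd.DataFrame, col: str, mask: pd.Series | None = None) -> pd.Series:
        sub = df if mask is None else df[mask]
        return sub.set_index("year")[col].astype(float)

    means_idx = means if means.index.name == "year" else means.set_index("year")
    cog_d = cog["variable"] == "density"
    cog_c = cog["variable"] == "condition"
    sep_dist = series(separation, "distance")
    year_series = pd.Series(sep_dist.index.to_numpy(dtype=float), index=sep_dist.index)

    pairs: dict[str, tuple[pd.Series, pd.Series]] = {
        "mean_density_vs_mean_condition": (
            means_idx["mean_density"].dropna(), means_idx["mean_condition"].dropna()),
        "cog_lat_density_vs_condition": (
            series(cog, "lat", cog_d), series(cog, "lat", cog_c)),
        "cog_lon_density_vs_condition": (
            series(cog, "lon", cog_d), series(cog, "lon", cog_c)),
        "spatial_rho_vs_mean_density": (
            series(spatial_rho, "rho"), means_idx["mean_density"]),
        "moran_density_vs_mean_density": (
            series(moran, "I", moran["variable"] == "density"),
            means_idx["mean_density"]),
        "cog_separation_vs_year": (sep_dist, year_series),
    }

    rows, failures = [], []
    for name in HEADLINE_PAIRS:
        xs, ys = pairs[name]
        try:
            test = adjusted_spearman(xs, ys, max_lag=max_lag)
        except InsufficientDataError as exc:
            logger.warning("association %s skipped: %s", name, exc)
            failures.append(name)
            continue
        rows.append({
            "pair": name,
            "rho": test.rho,
            "n": test.n,
            "n_eff": test.n_eff,
            "p_raw": test.p_raw,
            "p_adjusted": test.p_adjusted,
        })
    if not rows:
        raise InsufficientDataError(
            f"no association test had sufficient overlap: {', '.join(failures)}"
        )
    return pd.DataFrame(rows, columns=["pair", "rho", "n", "n_eff", "p_raw", "p_adjusted"])
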