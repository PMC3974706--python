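"""Fish body condition from length-weight data.

Condition is measured by Fulton's factor ``K = TW / TL^b`` where TW is total
weight (g), TL total length (cm) and ``b`` the slope of the pooled
ln(TL)-ln(TW) ordinary least-squares regression across all years and cells.
With ``b`` close to 3, K tracks relative plumpness and, for clupeids, the
lipid/energy content of the fish.

Measurement conventions applied before any computation mirror standard survey
practice: weights are recorded to the nearest gram (half-up) and lengths are
recorded in 0.5 cm classes, truncated downwards.  Rectangle-level condition is
the mean K of the specimens in a fixed length window (default 120-130 mm,
inclusive), which keeps the index comparable across years and cells.

No x100 scale factor is applied to K; every downstream comparison is
rank-based (Spearman), so the scale of K is irrelevant.  TL is expressed in
cm inside both the regression and K, which keeps K near its conventional
magnitude; the fitted slope ``b`` is unit-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from seascape.errors import DegenerateFitError
from seascape.ices import is_valid_rect, rect_to_centre

logger = logging.getLogger(__name__)

#: Default specimen length window (mm, inclusive) for rectangle condition.
DEFAULT_LENGTH_WINDOW = (120.0, 130.0)

FISH_COLUMNS = ["year", "rect", "length_mm", "weight_g"]


@dataclass(frozen=True)
class LengthWeightFit:
    """Pooled ln-ln length-weight regression.

    Attributes
    ----------
    b
        Slope of ln(TW) on ln(TL in cm); the exponent of ``K = TW / TL^b``.
    intercept
        Intercept on the log scale (ln of the condition coefficient).
    n
        Number of records used.
    r_squared
        Coefficient of determination of the fit.
    """

    b: float
    intercept: float
    n: int
    r_squared: float


def round_measurements(records: pd.DataFrame) -> pd.DataFrame:
    """Apply survey measurement rounding to raw fish records.

    Weights are rounded to the nearest 1 g (exact halves round up); lengths
    are truncated down to the nearest 0.5 cm and returned in mm.  Records
    with non-positive length or weight are rejected and logged.

    Parameters
    ----------
    records
        Table with columns ``year, rect, length_mm, weight_g``.

    Returns
    -------
    DataFrame
        Same columns, rounded, invalid rows dropped.  Idempotent: applying
        twice equals applying once.
    """
    out = records.copy()
    bad = ~((out["length_mm"] > 0) & (out["weight_g"] > 0))
    if bad.any():
        for idx in out.index[bad]:
            logger.warning(
                "rejected fish record %s: non-positive length or weight "
                "(length_mm=%s, weight_g=%s)",
                idx, out.at[idx, "length_mm"], out.at[idx, "weight_g"],
            )
        out = out.loc[~bad]
    # Half-up to the nearest gram (numpy's round is half-even, so do it by hand).
    out["weight_g"] = np.floor(out["weight_g"].to_numpy(dtype=float) + 0.5)
    # Truncate down to the 0.5 cm class, i.e. to a multiple of 5 mm.
    out["length_mm"] = np.floor(out["length_mm"].to_numpy(dtype=float) / 5.0) * 5.0
    # measurements too small for the recording grid round to zero: reject them
    zero = (out["length_mm"] == 0) | (out["weight_g"] == 0)
    if zero.any():
        for idx in out.index[zero]:
            logger.warning(
                "rejected fish record %s: rounds to zero on the measurement grid",
                idx,
            )
        out = out.loc[~zero]
    return out


def fit_length_weight(records: pd.DataFrame) -> LengthWeightFit:
    """Fit the pooled ln(TL)-ln(TW) relationship by OLS.

    Lengths are converted from mm to cm before taking logs.  The regression
    pools all years and cells; ``b`` is fitted once for the whole data set.

    Raises
    ------
    DegenerateFitError
        Fewer than 3 records, or fewer than 2 distinct lengths.
    """
    tl_cm = records["length_mm"].to_numpy(dtype=float) / 10.0
    tw = records["weight_g"].to_numpy(dtype=float)
    if len(tl_cm) < 3:
        raise DegenerateFitError(f"need >= 3 records to fit, got {len(tl_cm)}")
    if np.unique(tl_cm).size < 2:
        raise DegenerateFitError("all lengths identical; slope undefined")
    res = stats.linregress(np.log(tl_cm), np.log(tw))
    return LengthWeightFit(
        b=float(res.slope),
        intercept=float(res.intercept),
        n=len(tl_cm),
        r_squared=float(res.rvalue**2),
    )


def fulton_k(weight_g, length_cm, b: float):
    """Fulton's condition factor ``K = TW / TL^b`` (TL in cm, no scaling).

    Accepts scalars or arrays; raises ``ValueError`` on non-positive inputs.
    """
    weight_g = np.asarray(weight_g, dtype=float)
    length_cm = np.asarray(length_cm, dtype=float)
    if np.any(length_cm <= 0):
        raise ValueError("total length must be positive")
    if np.any(weight_g <= 0):
        raise ValueError("total weight must be positive")
    k = weight_g / length_cm**b
    return float(k) if k.ndim == 0 else k


def condition_by_cell(
    records: pd.DataFrame,
    fit: LengthWeightFit,
    length_window: tuple[float, float] = DEFAULT_LENGTH_WINDOW,
) -> pd.DataFrame:
    """Mean Fulton's K per (year, rectangle) over in-window specimens.

    Parameters
    ----------
    records
        Rounded fish records (``year, rect, length_mm, weight_g``).
    fit
        Pooled length-weight fit supplying the exponent ``b``.
    length_window
        Inclusive (min, max) total-length window in mm; only specimens
        inside it contribute.

    Returns
    -------
    DataFrame
        Columns ``year, rect, lat, lon, condition, n_fish``; cells with no
        in-window specimens are absent (never reported as zero).  ``lat`` and
        ``lon`` are rectangle centres where ``rect`` parses as an ICES code,
        NaN otherwise.
    """
    if records.empty:
        logger.warning("condition_by_cell: empty input, returning empty table")
        return pd.DataFrame(
            columns=["year", "rect", "lat", "lon", "condition", "n_fish"]
        )
    lo, hi = length_window
    sel = records[(records["length_mm"] >= lo) & (records["length_mm"] <= hi)].copy()
    sel["k"] = fulton_k(sel["weight_g"], sel["length_mm"] / 10.0, fit.b)
    grouped = (
        sel.groupby(["year", "rect"], as_index=False)
        .agg(condition=("k", "mean"), n_fish=("k", "size"))
    )
    centres = {
        code: (rect_to_centre(code) if is_valid_rect(code) else (np.nan, np.nan))
        for code in grouped["rect"].unique()
    }
    grouped["lat"] = grouped["rect"].map(lambda c: centres[c][0])
    grouped["lon"] = grouped["rect"].map(lambda c: centres[c][1])
    return grouped[["year", "rect", "lat", "lon", "condition", "n_fish"]]
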