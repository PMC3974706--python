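"""End-to-end analysis pipeline: condition -> spatial indices -> correlations.

``run_analysis`` reads a rectangle observation table (and optionally raw
fish records, from which rectangle condition is computed and takes
precedence over any precomputed condition column), computes yearly means,
above-median jackknife centres of gravity for density and condition, their
separation trajectory, per-year spatial density-condition correlations,
Moran's I patchiness per year and variable, and the six headline temporal
association tests — then writes every table as CSV plus a machine-readable
run manifest.

Everything downstream of the inputs is deterministic (the jackknife is
enumerative), so rerunning with the same inputs and configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import seascape
from seascape import condition as cond_mod
from seascape import correlation as corr_mod
from seascape import spatial as spatial_mod
from seascape.errors import (
    DegenerateSpatialError,
    InsufficientDataError,
    ValidationError,
)
from seascape.ices import is_valid_rect, rect_to_centre

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "yearly_means.csv",
    "cog.csv",
    "cog_separation.csv",
    "moran.csv",
    "spatial_rho.csv",
    "associations.csv",
)


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    obs_path: str | Path
    fish_path: str | Path | None = None
    outdir: str | Path = "seascape_out"
    length_window: tuple[float, float] = cond_mod.DEFAULT_LENGTH_WINDOW
    min_cells: int = 10
    ci_level: float = 0.95
    moran_metric: str = "degrees"          # "degrees" | "great_circle_km"
    max_lag: int | None = None             # None -> floor(n/5)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_cells < 3:
            raise ValueError("min_cells must be >= 3")
        self.length_window = tuple(self.length_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)


@dataclass
class AnalysisResult:
    """Bundle of every table the pipeline produces."""

    yearly_means: pd.DataFrame
    cog: pd.DataFrame
    cog_separation: pd.DataFrame
    moran: pd.DataFrame
    spatial_rho: pd.DataFrame
    associations: pd.DataFrame
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# input loading and validation


def _check_row(row: pd.Series, kind: str, line: int) -> list[dict]:
    issues = []
    def issue(column: str, message: str) -> None:
        issues.append({"line": line, "column": column, "message": message})

    if kind == "observations":
        numeric = ["density"] + (["condition"] if "condition" in row.index else [])
        numeric += [c for c in ("lat", "lon") if c in row.index]
    else:
        numeric = ["length_mm", "weight_g"]
    for col in ["year"] + numeric:
        if col in row.index and pd.isna(pd.to_numeric(row[col], errors="coerce")):
            if not (col == "condition" and (pd.isna(row[col]) or row[col] == "")):
                issue(col, f"non-numeric value {row[col]!r}")
    if kind == "observations":
        dens = pd.to_numeric(row.get("density"), errors="coerce")
        if pd.notna(dens) and dens < 0:
            issue("density", f"negative density {dens}")
        if "rect" in row.index and not is_valid_rect(str(row["rect"])):
            issue("rect", f"invalid ICES rectangle code {row['rect']!r}")
    else:
        for col in ("length_mm", "weight_g"):
            val = pd.to_numeric(row.get(col), errors="coerce")
            if pd.notna(val) and val <= 0:
                issue(col, f"non-positive {col} {val}")
    return issues


def validate_inputs(path: str | Path, kind: str = "observations") -> dict:
    """Validate an input CSV row by row.

    ``kind`` is ``"observations"`` (needs ``year`` + ``density`` and either
    ``rect`` or ``lat``/``lon``) or ``"fish"`` (needs
    ``year, rect, length_mm, weight_g``).  Returns a report dict with keys
    ``ok``, ``n_rows``, ``issues`` (list of ``{line, column, message}``;
    line numbers count the header as line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    issues: list[dict] = []
    required = (
        {"year", "density"} if kind == "observations"
        else {"year", "rect", "length_mm", "weight_g"}
    )
    missing = required - set(df.columns)
    if kind == "observations" and "rect" not in df.columns and not (
        {"lat", "lon"} <= set(df.columns)
    ):
        missing.add("rect (or lat+lon)")
    if missing:
        issues.append({
            "line": 1, "column": ",".join(sorted(missing)),
            "message": "missing required column(s)",
        })
    else:
        for i, row in df.iterrows():
            issues.extend(_check_row(row, kind, line=i + 2))
        key = ["year", "rect"] if "rect" in df.columns else ["year", "lat", "lon"]
        if kind == "observations":
            dups = df.duplicated(subset=key)
            for i in df.index[dups]:
                issues.append({
                    "line": int(i) + 2, "column": ",".join(key),
                    "message": "duplicate (year, cell) observation",
                })
    return {"path": str(path), "kind": kind, "ok": not issues,
            "n_rows": len(df), "issues": issues}


def load_observations(path: str | Path) -> pd.DataFrame:
    """Read and normalise an observation CSV to
    ``year, rect, lat, lon, density[, condition]``.

    Accepts either a ``rect`` column (ICES codes; centres are derived) or
    explicit ``lat``/``lon`` columns (``rect`` left empty).
    """
    report = validate_inputs(path, "observations")
    if not report["ok"]:
        lines = "; ".join(
            f"line {i['line']} [{i['column']}]: {i['message']}"
            for i in report["issues"][:20]
        )
        raise ValidationError(f"{path}: {len(report['issues'])} issue(s): {lines}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "rect" in df.columns and not {"lat", "lon"} <= set(df.columns):
        centres = df["rect"].astype(str).map(rect_to_centre)
        df["lat"] = centres.map(lambda c: c[0])
        df["lon"] = centres.map(lambda c: c[1])
    if "rect" not in df.columns:
        df["rect"] = ""
    return df


def load_fish_records(path: str | Path) -> pd.DataFrame:
    report = validate_inputs(path, "fish")
    if not report["ok"]:
        raise ValidationError(
            f"{path}: {len(report['issues'])} validation issue(s)"
        )
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# the run


def _condition_from_fish(obs: pd.DataFrame, fish: pd.DataFrame,
                         config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Replace/attach rectangle condition computed from fish records."""
    rounded = cond_mod.round_measurements(fish)
    fit = cond_mod.fit_length_weight(rounded)
    cell_k = cond_mod.condition_by_cell(rounded, fit, config.length_window)
    if "condition" in obs.columns:
        logger.warning(
            "both precomputed condition and fish records supplied; "
            "fish records take precedence"
        )
        obs = obs.drop(columns=["condition"])
    obs = obs.merge(cell_k[["year", "rect", "condition"]], on=["year", "rect"],
                    how="left")
    fit_info = dataclasses.asdict(fit)
    return obs, fit_info


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Execute the full analysis and write all outputs under ``outdir``.

    Writes the six CSV tables plus ``manifest.json`` (configuration echo,
    package/library versions, length-weight fit if fish records were used,
    and the per-year exclusions with reasons).  Years excluded for spatial
    coverage stay in ``yearly_means.csv``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)

    obs = load_observations(config.obs_path)
    fit_info = None
    if config.fish_path is not None:
        fish = load_fish_records(config.fish_path)
        obs, fit_info = _condition_from_fish(obs, fish, config)
    if "condition" not in obs.columns:
        obs["condition"] = np.nan

    means = corr_mod.yearly_means(obs)
    excluded: list[dict] = []
    cog_rows, moran_rows = [], []
    for year, ymap in obs.groupby("year"):
        for variable in ("density", "condition"):
            valid = ymap.dropna(subset=[variable, "lat", "lon"])
            # centre of gravity (above-median, jackknife CI)
            try:
                est = spatial_mod.jackknife_cog(
                    valid, variable, min_cells=config.min_cells,
                    ci_level=config.ci_level, year=int(year),
                )
            except (InsufficientDataError, DegenerateSpatialError) as exc:
                est = None
                excluded.append({"year": int(year), "variable": variable,
                                 "index": "cog", "reason": str(exc)})
            else:
                if est is None:
                    excluded.append({
                        "year": int(year), "variable": variable, "index": "cog",
                        "reason": f"fewer than min_cells={config.min_cells} "
                                  "cells above the median",
                    })
            if est is not None:
                cog_rows.append(dataclasses.asdict(est))
            # Moran's I on the full yearly map
            try:
                w = spatial_mod.moran_weights(
                    valid[["lat", "lon"]].to_numpy(), metric=config.moran_metric)
                mres = spatial_mod.moran_i(
                    valid[variable].to_numpy(), w, year=int(year), variable=variable)
                moran_rows.append({"year": mres.year, "variable": mres.variable,
                                   "I": mres.I, "n": mres.n,
                                   "expected_null": mres.expected_null})
            except (InsufficientDataError, DegenerateSpatialError, ValueError) as exc:
                excluded.append({"year": int(year), "variable": variable,
                                 "index": "moran", "reason": str(exc)})

    cog = pd.DataFrame(cog_rows, columns=[
        "year", "variable", "lat", "lon",
        "lat_lo", "lat_hi", "lon_lo", "lon_hi", "n_used"])
    moran = pd.DataFrame(moran_rows, columns=[
        "year", "variable", "I", "n", "expected_null"])
    separation = spatial_mod.cog_separation(
        cog[cog["variable"] == "density"], cog[cog["variable"] == "condition"])
    spatial_rho = corr_mod.spatial_correlation_by_year(obs)
    try:
        associations = corr_mod.headline_associations(
            means=means, cog=cog, spatial_rho=spatial_rho, moran=moran,
            separation=separation, max_lag=config.max_lag)
    except InsufficientDataError as exc:
        logger.warning("associations unavailable: %s", exc)
        associations = pd.DataFrame(
            columns=["pair", "rho", "n", "n_eff", "p_raw", "p_adjusted"])

    manifest = {
        "package": {"name": "seascape", "version": seascape.__version__},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            **{k: (str(v) if isinstance(v, Path) else v)
               for k, v in dataclasses.asdict(config).items()},
            "length_window": list(config.length_window),
        },
        "length_weight_fit": fit_info,
        "n_years": int(obs["year"].nunique()),
        "n_cells_total": int(len(obs)),
        "excluded": excluded,
        "outputs": list(OUTPUT_FILES),
    }

    result = AnalysisResult(
        yearly_means=means.reset_index(), cog=cog, cog_separation=separation,
        moran=moran, spatial_rho=spatial_rho, associations=associations,
        manifest=manifest)
    _write_outputs(result, outdir)
    return result


def _write_outputs(result: AnalysisResult, outdir: Path) -> None:
    tables = {
        "yearly_means.csv": result.yearly_means,
        "cog.csv": result.cog,
        "cog_separation.csv": result.cog_separation,
        "moran.csv": result.moran,
        "spatial_rho.csv": result.spatial_rho,
        "associations.csv": result.associations,
    }
    for name, df in tables.items():
        # shortest round-trip float formatting: re-reading a table yields
        # bit-identical values, so downstream recomputation is exact
        df.to_csv(outdir / name, index=False, float_format=lambda x: str(float(x)))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d tables and manifest.json to %s", len(tables), outdir)


def _setup_logging(outdir: Path, level: str) -> None:
    """Attach a run-log file handler (no timestamps: runs stay byte-identical)."""
    root = logging.getLogger("seascape")
    root.setLevel(level.upper())
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    for handler in list(root.handlers):
        if getattr(handler, "_seascape_run_log", False):
            root.removeHandler(handler)
            handler.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(fmt)
    fh._seascape_run_log = True  # type: ignore[attr-defined]
    root.addHandler(fh)
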