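"""Synthetic seascape generator.

Generates gridded survey data with the statistical structure the analysis
pipeline assumes, emulating a Baltic-Proper-like setting: a 0.5 x 1 degree
rectangle grid, ~25 annual maps, an early regime with spatially homogeneous
density and condition, a later regime with density concentrated toward one
corner (north-east by default) and maximum condition pushed toward the
opposite corner, and a negative density-to-condition coupling observed with
noise.

Model
-----
Density for cell *c* in year *t*:

    density(c, t) = A(t) * exp(kappa(t) * g_t(c)) * eps,   eps ~ lognormal(0, sigma)

where ``A(t)`` is the abundance trajectory, ``kappa(t)`` the patch
concentration and ``g_t`` a unit gradient (1 at the year-t hotspot, 0 at the
farthest cell); the hotspot drifts linearly between a start and end position
over the simulated years.  Condition:

    condition(c, t) = K0 * (1 - beta * density_norm(c, t)) + eta,
    eta ~ Normal(0, sigma_K)

with ``density_norm`` a min-max normalisation of density (global across
years by default, so that the *absolute* density level governs how much
condition is suppressed: low-abundance early years show little spatial
condition signal relative to noise, high-abundance late years a strong
negative gradient — the density-dependent regime shift the analysis is
designed to detect).  Condition is floored at ``0.1 * K0``.

Individual fish records are drawn per cell with total length uniform on the
0.5 cm classes in 120-130 mm and weight ``K_cell * TL_cm^3`` under lognormal
noise, then passed through the survey rounding rules — providing an
end-to-end exercise of the condition module.

All randomness derives from a single seed via spawned child streams (one per
stage), so each stage is independently reproducible and a full run is
bit-for-bit deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from seascape.condition import round_measurements
from seascape.ices import centre_to_rect

logger = logging.getLogger(__name__)

_CORNERS = ("NE", "NW", "SE", "SW", "centre")


@dataclass
class SeascapeConfig:
    """Full parameterisation of the synthetic seascape.

    Defaults emulate the study conditions: a 10 x 10 grid of ICES-sized
    cells over a Baltic-Proper-like extent (54-59 N, 14-24 E), 25 survey
    years, abundance ramping 4-fold, patch concentration ramping 0 -> 3
    with the density hotspot drifting from the grid centre to the NE
    corner, coupling beta = 0.6, and observation noise on both fields.
    """

    seed: int
    n_rows: int = 10
    n_cols: int = 10
    lat0: float = 54.0           # southern edge of the grid, degrees N
    lon0: float = 14.0           # western edge, degrees E
    years: int = 25
    start_year: int = 1985
    abundance_start: float = 5000.0   # mean density scale, number / nmi^2
    abundance_end: float = 20000.0
    abundance_trajectory: list[float] | None = None  # explicit override
    kappa_start: float = 0.0     # patch concentration (dimensionless)
    kappa_end: float = 3.0
    kappa_trajectory: list[float] | None = None
    hotspot_start: str | tuple[float, float] = "centre"
    hotspot_end: str | tuple[float, float] = "NE"
    coupling_beta: float = 0.6   # fractional condition suppression at peak density
    condition_base: float = 0.0066   # Fulton's K scale for TL in cm, b = 3
    density_noise_sd: float = 0.3    # lognormal sigma on density
    condition_noise_sd: float = 2e-4  # additive Gaussian sd on condition
    density_norm_scope: str = "global"  # "global" | "year" min-max for coupling
    fish_per_cell: int = 20
    weight_noise_sd: float = 0.03    # lognormal sigma on individual weight

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("grid must be at least 3 x 3")
        if self.years < 2:
            raise ValueError("need at least 2 years")
        if self.coupling_beta < 0:
            raise ValueError("coupling_beta must be >= 0")
        if min(self.density_noise_sd, self.condition_noise_sd,
               self.weight_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.density_norm_scope not in ("global", "year"):
            raise ValueError("density_norm_scope must be 'global' or 'year'")
        if self.fish_per_cell < 0:
            raise ValueError("fish_per_cell must be >= 0")
        for spot in (self.hotspot_start, self.hotspot_end):
            if isinstance(spot, str) and spot not in _CORNERS:
                raise ValueError(f"unknown hotspot {spot!r}; use one of {_CORNERS}")

    # -- derived geometry ---------------------------------------------------

    def cell_centres(self) -> pd.DataFrame:
        """Grid cell centres with their ICES rectangle codes."""
        lats = self.lat0 + 0.25 + 0.5 * np.arange(self.n_rows)
        lons = self.lon0 + 0.5 + np.arange(self.n_cols)
        lat_g, lon_g = np.meshgrid(lats, lons, indexing="ij")
        df = pd.DataFrame({"lat": lat_g.ravel(), "lon": lon_g.ravel()})
        df["rect"] = [centre_to_rect(la, lo) for la, lo in zip(df["lat"], df["lon"])]
        return df[["rect", "lat", "lon"]]

    def _resolve_hotspot(self, spot: str | tuple[float, float]) -> np.ndarray:
        if not isinstance(spot, str):
            return np.asarray(spot, dtype=float)
        lat_lo, lat_hi = self.lat0 + 0.25, self.lat0 + 0.25 + 0.5 * (self.n_rows - 1)
        lon_lo, lon_hi = self.lon0 + 0.5, self.lon0 + 0.5 + (self.n_cols - 1)
        table = {
            "NE": (lat_hi, lon_hi),
            "NW": (lat_hi, lon_lo),
            "SE": (lat_lo, lon_hi),
            "SW": (lat_lo, lon_lo),
            "centre": ((lat_lo + lat_hi) / 2, (lon_lo + lon_hi) / 2),
        }
        return np.asarray(table[spot], dtype=float)

    def trajectories(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-year abundance A(t), concentration kappa(t), hotspot (lat, lon)."""
        t = np.linspace(0.0, 1.0, self.years)
        a = (np.asarray(self.abundance_trajectory, dtype=float)
             if self.abundance_trajectory is not None
             else self.abundance_start + t * (self.abundance_end - self.abundance_start))
        k = (np.asarray(self.kappa_trajectory, dtype=float)
             if self.kappa_trajectory is not None
             else self.kappa_start + t * (self.kappa_end - self.kappa_start))
        if len(a) != self.years or len(k) != self.years:
            raise ValueError("explicit trajectories must have one value per year")
        if np.any(k < 0):
            raise ValueError("patch concentration must be >= 0")
        start = self._resolve_hotspot(self.hotspot_start)
        end = self._resolve_hotspot(self.hotspot_end)
        hotspots = start[None, :] + t[:, None] * (end - start)[None, :]
        return a, k, hotspots

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("hotspot_start", "hotspot_end"):
            if not isinstance(d[key], str):
                d[key] = list(d[key])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeascapeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        if "seed" not in raw:
            raise ValueError(f"{path}: 'seed' is mandatory in seascape configs")
        for key in ("hotspot_start", "hotspot_end"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _streams(config: SeascapeConfig) -> dict[str, np.random.Generator]:
    """Independent child RNG streams, one per generation stage."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return {
        "density": np.random.default_rng(children[0]),
        "condition": np.random.default_rng(children[1]),
        "fish": np.random.default_rng(children[2]),
    }


def generate_density_maps(
    config: SeascapeConfig, *, noise_free: bool = False
) -> pd.DataFrame:
    """Yearly density maps: columns ``year, rect, lat, lon, density``.

    ``noise_free=True`` returns the expectation field ``A(t) exp(kappa g)``
    without the lognormal multiplier (useful for analytic checks).
    """
    cells = config.cell_centres()
    coords = cells[["lat", "lon"]].to_numpy()
    a_traj, k_traj, hotspots = config.trajectories()
    rng = _streams(config)["density"]
    frames = []
    for i in range(config.years):
        d = np.hypot(coords[:, 0] - hotspots[i, 0], coords[:, 1] - hotspots[i, 1])
        d_max = d.max()
        g = 1.0 - d / d_max if d_max > 0 else np.ones_like(d)
        mean_field = a_traj[i] * np.exp(k_traj[i] * g)
        if noise_free or config.density_noise_sd == 0:
            density = mean_field
        else:
            density = mean_field * np.exp(
                rng.normal(0.0, config.density_noise_sd, size=len(cells))
            )
        frame = cells.copy()
        frame.insert(0, "year", config.start_year + i)
        frame["density"] = density
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def attach_condition(maps: pd.DataFrame, config: SeascapeConfig) -> pd.DataFrame:
    """Add a ``condition`` column coupled negatively to density.

    condition = K0 * (1 - beta * density_norm) + Normal(0, sigma_K), floored
    at 0.1 * K0 (floored cells are counted in the log).  ``density_norm`` is
    a min-max normalisation of density, across all years (default) or within
    each year, per ``config.density_norm_scope``.
    """
    out = maps.copy()
    dens = out["density"]
    if config.density_norm_scope == "global":
        rng_span = dens.max() - dens.min()
        norm = (dens - dens.min()) / rng_span if rng_span > 0 else dens * 0.0
    else:
        def _norm(s: pd.Series) -> pd.Series:
            span = s.max() - s.min()
            return (s - s.min()) / span if span > 0 else s * 0.0
        norm = dens.groupby(out["year"]).transform(_norm)
    k0 = config.condition_base
    cond = k0 * (1.0 - config.coupling_beta * norm.to_numpy())
    if config.condition_noise_sd > 0:
        rng = _streams(config)["condition"]
        cond = cond + rng.normal(0.0, config.condition_noise_sd, size=len(out))
    floor = 0.1 * k0
    n_floored = int(np.sum(cond < floor))
    if n_floored:
        logger.info("attach_condition: floored %d condition values at 0.1*K0", n_floored)
    out["condition"] = np.maximum(cond, floor)
    return out


#: Total-length classes (mm) emitted for synthetic fish: the 0.5 cm grid in
#: the 120-130 mm window.
FISH_LENGTH_CLASSES_MM = (120.0, 125.0, 130.0)


def emit_fish_records(
    maps: pd.DataFrame, config: SeascapeConfig, *, apply_rounding: bool = True
) -> pd.DataFrame:
    """Individual fish records consistent with each cell's condition.

    Per (year, cell), ``fish_per_cell`` fish with TL drawn uniformly from
    the 0.5 cm classes in 120-130 mm and TW = K_cell * TL_cm^3 under
    lognormal weight noise.  With ``apply_rounding`` (default) the survey
    rounding rules are applied, so the condition module can recover K_cell
    up to rounding error.
    """
    if "condition" not in maps.columns:
        raise ValueError("emit_fish_records: attach_condition first")
    m = config.fish_per_cell
    if m == 0 or maps.empty:
        return pd.DataFrame(columns=["year", "rect", "length_mm", "weight_g"])
    rng = _streams(config)["fish"]
    n_cells = len(maps)
    lengths = rng.choice(FISH_LENGTH_CLASSES_MM, size=(n_cells, m))
    k = maps["condition"].to_numpy()[:, None]
    weights = k * (lengths / 10.0) ** 3
    if config.weight_noise_sd > 0:
        weights = weights * np.exp(rng.normal(0.0, config.weight_noise_sd,
                                              size=weights.shape))
    records = pd.DataFrame({
        "year": np.repeat(maps["year"].to_numpy(), m),
        "rect": np.repeat(maps["rect"].to_numpy(), m),
        "length_mm": lengths.ravel(),
        "weight_g": weights.ravel(),
    })
    return round_measurements(records) if apply_rounding else records


def simulate(config: SeascapeConfig, outdir: str | Path | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full generator; optionally write the pipeline's input CSVs.

    Returns ``(observations, fish_records)``; with ``outdir`` set, writes
    ``observations.csv`` (year, rect, lat, lon, density, condition) and
    ``fish_records.csv`` (year, rect, length_mm, weight_g) there.
    """
    obs = attach_condition(generate_density_maps(config), config)
    fish = emit_fish_records(obs, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = lambda x: str(float(x))  # shortest round-trip representation
        obs.to_csv(outdir / "observations.csv", index=False, float_format=fmt,
                   columns=["year", "rect", "lat", "lon", "density", "condition"])
        fish.to_csv(outdir / "fish_records.csv", index=False, float_format=fmt)
    return obs, fish
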