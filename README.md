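# seascape

Spatio-temporal density-dependence analysis for gridded fish surveys.

Pelagic fish populations can regulate individual growth through local
competition: where the population concentrates, per-capita food intake and
body condition drop. Detecting this *spatial* density-dependence from survey
data requires tracking, year by year, where the population is, where the
best-conditioned fish are, and how patchy both fields are. `seascape`
implements that workflow for rectangle-resolution survey tables of the kind
produced by hydroacoustic surveys on the ICES statistical-rectangle grid
(0.5° latitude x 1° longitude) — the setting in which the method was
developed for Baltic sprat — and ships a synthetic seascape generator so the
entire pipeline is testable without access to the survey databases.

It is aimed at fisheries and spatial-ecology analysts who have (a) a
rectangle-level table of densities (and optionally condition) per year and
(b) optionally an individual length-weight table, and want the standard
distribution indices with honest uncertainty and autocorrelation-aware
significance tests.

## The statistics

**Body condition.** Fulton's condition factor per fish,

    K = TW / TL^b,

with TW total weight (g), TL total length (cm) and `b` the slope of the
pooled ln(TL)–ln(TW) OLS regression. Survey measurement conventions are
applied first (weights to the nearest 1 g, lengths truncated down to 0.5 cm
classes); rectangle condition is the mean K of the specimens in a fixed
120–130 mm length window.

**Centres of gravity (COG).** The value-weighted mean position of a yearly
map, restricted to cells strictly above the within-year median so the index
tracks the location of *maximum* density / condition:

    COG = ( Σᵢ wᵢ latᵢ / Σᵢ wᵢ ,  Σᵢ wᵢ lonᵢ / Σᵢ wᵢ ).

Uncertainty comes from exact leave-one-out enumeration: the COG is
recomputed with each cell deleted in turn; the point estimate is the
coordinate-wise median of that distribution and the 95 % interval its
2.5–97.5 percentile range. Years with too few cells are excluded and
reported. The per-year separation of two COG series (signed, absolute, and
Euclidean distance in degree space) tracks trajectory divergence.

**Patchiness.** Moran's I per yearly map,

    I = (n / S₀) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²,

with distance-decay weights wᵢⱼ = 1 − dᵢⱼ/d_max (Euclidean in degree space,
zero diagonal) and S₀ = Σᵢⱼ wᵢⱼ. Values toward +1 mean clustered (patchy)
fields, toward −1 dispersed; the null expectation is −1/(n−1).

**Correlations.** Spearman's rho between density and condition across cells
within each year measures the strength of spatial density-dependence; the
resulting time series (and the COG, Moran and yearly-mean series) are then
associated with one another using Spearman tests whose degrees of freedom
are reduced for serial autocorrelation via the modified Chelton effective
sample size,

    1/n_eff = 1/n + (2/n) Σⱼ r_xx(j) r_yy(j),  j = 1 … ⌊n/5⌋,

with the p-value from the t approximation on n_eff − 2 df.

## Worked example

```python
from seascape import SeascapeConfig, simulate, RunConfig, run_analysis

config = SeascapeConfig(seed=42)           # 10x10 grid, 25 years, kappa 0->3
obs, fish = simulate(config, "seascape_demo")
result = run_analysis(RunConfig(
    obs_path="seascape_demo/observations.csv",
    fish_path="seascape_demo/fish_records.csv",
    outdir="seascape_demo/out",
))
print(result.associations.round(3).to_string(index=False))
print(f"\nfitted length-weight slope b = {result.manifest['length_weight_fit']['b']:.3f}")
```

prints

```
                          pair    rho  n  n_eff  p_raw  p_adjusted
mean_density_vs_mean_condition -0.992 25  4.828  0.000       0.001
  cog_lat_density_vs_condition -0.412 25 17.253  0.041       0.097
  cog_lon_density_vs_condition -0.932 25  4.176  0.000       0.055
   spatial_rho_vs_mean_density -0.969 25  4.686  0.000       0.010
 moran_density_vs_mean_density  0.965 25  4.531  0.000       0.015
        cog_separation_vs_year  0.990 25  4.306  0.000       0.005

fitted length-weight slope b = 3.005
```

Reading the table: as the simulated population grows and concentrates, mean
condition falls with mean density (rho = −0.99), the density and condition
centres of gravity move in opposite directions (negative latitude/longitude
associations, separation increasing over time, rho = 0.99), the spatial
density–condition correlation becomes more negative the denser the
population (rho = −0.97), and density patchiness rises with abundance
(rho = 0.97). Note how the autocorrelation adjustment shrinks 25 years of
strongly trending data to n_eff ≈ 4–5 equivalent independent observations,
turning vanishing raw p-values into honest ones. The pooled length–weight
slope recovers the cubic growth law built into the generator.

The same run from the shell:

```sh
seascape simulate --config config.yaml --outdir demo    # config.yaml: SeascapeConfig fields, seed mandatory
seascape run --obs demo/observations.csv --fish demo/fish_records.csv --outdir demo/out
seascape validate demo/observations.csv
```

Outputs under `demo/out/`: `yearly_means.csv`, `cog.csv`,
`cog_separation.csv`, `moran.csv`, `spatial_rho.csv`, `associations.csv`,
`manifest.json` (configuration echo, versions, fit, excluded years) and
`run.log`. Reruns with identical inputs are byte-identical.

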