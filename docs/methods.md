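# Methods

This note records the models, conventions and design choices behind
`seascape`, in the order the pipeline applies them.

## Condition

Fulton's factor `K = TW / TL^b` is used verbatim, with no ×100 scale
constant. Two unit conventions had to be fixed:

* **TL in cm** inside both the ln–ln regression and K. The slope `b` is
  invariant to the length unit (a unit change only shifts the intercept),
  so only K's absolute scale depends on this choice; cm keeps K near its
  conventional magnitude (≈ 0.007 for a 13 g, 12.5 cm clupeid at b = 3).
  Every downstream comparison is rank-based (Spearman), so the choice is
  immaterial to all results.
* **Measurement grid**: weights to the nearest 1 g with exact halves
  rounded *up* (a convention that had to be fixed; "nearest" alone does not
  decide ties), lengths truncated *down* to 0.5 cm classes. Rounding is
  idempotent, and measurements that round to zero are rejected as outside
  the recording grid.

`b` is fitted once, pooled over all years and cells — it is a property of
the overall length–weight relationship, not of single years. Rectangle
condition is the mean K over specimens in an inclusive 120–130 mm window,
the length range best covered across years and cells in the motivating
surveys; cells without in-window fish are absent from the output rather
than zero. When both a precomputed condition column and fish records are
supplied, the fish records win (they are the rawer source) and a warning is
logged.

## Centres of gravity

The COG of a yearly map is the value-weighted mean (lat, lon) over cells,
computed on the subset of cells *strictly above* the within-year median of
the variable: the index is meant to locate the maximum of the field, and
the strict inequality is the literal reading of "above the median" (ties at
the median are excluded; an all-constant year has an empty subset and is
flagged degenerate).

Uncertainty is estimated by exact delete-one enumeration rather than random
resampling: with n cells there are exactly n leave-one-out COGs, the point
estimate is the coordinate-wise median of that distribution, and the 95 %
interval its 2.5–97.5 percentile range (the interval type had to be chosen;
percentile intervals are the natural reading for a resampling distribution
summarised by its median). The scheme is deterministic, which is what makes
the whole pipeline byte-reproducible. Years with fewer than `min_cells`
cells after filtering (default 10; configurable — the appropriate threshold
depends on survey coverage) are excluded from COG and separation outputs
but retained in yearly means, which remain meaningful at lower coverage.

Coordinates are ICES rectangle centres; there is no within-cell
positioning, so a COG is never more precise than the 0.5° × 1° grid.

## Moran's I

Computed per yearly map, per variable, on **all** cells of the map (the
patchiness of the whole seascape is the quantity of interest, not that of
the above-median subset), with weights

    w_ij = 1 − d_ij / d_max,  w_ii = 0,

where d is the Euclidean distance in raw degree space and d_max the maximum
pairwise distance *within that map* (weights are rebuilt per year; maps
with different cell coverage get different weight matrices). Degree-space
distance matches the conventional computation on survey grids at this
extent; a great-circle-km metric is available behind a config switch for
reuse at larger scales, where meridian convergence matters. Zero-variance
maps (constant field) have undefined I and are excluded with a reason. No
significance test is attached to individual I values — the index is used as
a yearly patchiness series, and inference happens at the series level.

## Temporal associations

Survey series are short (~25 years) and strongly autocorrelated, so naive
Spearman p-values overstate significance badly. The package adjusts the
degrees of freedom with the modified Chelton effective sample size

    1/n_eff = 1/n + (2/n) Σ_{j=1}^{L} r_xx(j) r_yy(j),

with sample autocorrelations of the two raw series and lag truncation
L = ⌊n/5⌋ by default (configurable; the appropriate truncation is a
bias–variance trade-off and no single rule is canonical). n_eff is clipped
to [2, n] — the estimator can exceed n by sampling noise, and values below
2 leave no degrees of freedom. p-values come from the t approximation with
n_eff − 2 (possibly fractional) df; both the raw (df = n − 2) and adjusted
p are reported. In the worked example this adjustment shrinks 25 trending
years to n_eff ≈ 4–5, which is the honest information content of two
monotone series.

The pipeline reports six associations: mean density vs mean condition, the
density-vs-condition COG latitude and longitude series, spatial rho vs mean
density, Moran's I of density vs mean density, and COG separation distance
vs year.

## Synthetic seascapes

The generator emulates the statistical structure the analysis assumes, on a
Baltic-Proper-like domain (10 × 10 ICES-sized cells, 54–59° N / 14–24° E,
25 years by default):

* **Density** `A(t) · exp(κ(t) · g_t(cell)) · ε` with a linear abundance
  ramp A (5 000 → 20 000 fish / nmi², a realistic acoustic-density scale),
  patch concentration κ ramping 0 → 3, a hotspot drifting linearly from the
  grid centre to the NE corner, and lognormal noise (σ = 0.3) — positive
  and right-skewed, as acoustic densities are.
* **Condition** `K₀ (1 − β · density_norm) + η`, K₀ = 0.0066, β = 0.6,
  Gaussian η (σ = 2·10⁻⁴, ≈ 3 % of K₀), floored at 0.1 K₀.
  `density_norm` is a min-max normalisation of density taken **across all
  years** by default: suppression then scales with *absolute* density, so
  early low-abundance years show almost no spatial condition signal
  relative to noise (the homogeneous regime) while late high-abundance
  years are strongly coupled — the density-dependent regime shift the
  analysis is designed to detect. A within-year normalisation
  (`density_norm_scope="year"`) is available but makes the coupling equally
  strong in every year, which removes the regime shift and can even reverse
  the sign of the spatial-rho-vs-density trend; it is not the default for
  that reason.
* **Fish records**: per cell, fish with TL uniform on the 0.5 cm classes in
  120–130 mm and TW = K_cell · TL³(cm) under lognormal weight noise
  (σ = 0.03), passed through the measurement rounding — an end-to-end
  exercise of the condition module. With noise off, rectangle condition is
  recoverable to the 0.5 g / cell bound (≤ 0.5/12³ ≈ 2.9·10⁻⁴ in K).

All randomness flows from one seed through spawned child streams (one per
stage), so each stage is independently reproducible and whole runs are
bit-identical.

**What the generator does not emulate**: survey gaps and partial coverage
(every cell is observed every year), vessel/calibration effects,
within-rectangle sampling error of the acoustic integration, age structure,
migration dynamics, or any mechanistic predator or hydrography field. A
pipeline that passes on these seascapes is demonstrated to recover the
built-in spatial structure through the full measurement chain; it is not
thereby validated against the messiness of real survey data.

## Numerical and degenerate-input choices

* Exact CSV fidelity: tables are written with shortest round-trip float
  formatting and read back with round-trip parsing, so recomputing an index
  from a written table reproduces the written result bit-for-bit.
* Leave-one-out COG requires the remaining weight to be positive; a single
  cell carrying all weight is a degeneracy error.
* Spearman p at |rho| = 1 is 0; effective df ≤ 0 yields p = 1.
* ICES codes: row 01 starts at 36° N; the A column block is truncated to
  44–40° W; the letter I is not part of the standard and is rejected.
* Problem sizes in the test-suite simulations (grids 4×5 to 10×10, 2–100
  years, up to 20 replicates) were chosen as the smallest scales at which
  each property is statistically unambiguous.

## Known limitations

* The COG interval reflects leave-one-out sensitivity, not full sampling
  error of the underlying acoustic estimates; it will understate
  uncertainty when single rectangles dominate the field.
* Moran's I with 1 − d/d_max weights depends on map extent through d_max;
  comparisons across years assume similar coverage.
* The effective-sample-size adjustment uses estimated autocorrelations and
  is itself noisy at n ≈ 25; its p-values are honest in expectation, not
  exact.
* Rank-based statistics discard magnitude information by design; the
  package reports no effect sizes on original scales beyond the yearly
  means.
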