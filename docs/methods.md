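# Methods

## Cumulative impact model

Per-cell cumulative human impact (CHI) is the sum over stressors of rescaled
intensity × habitat-aggregated vulnerability. Two habitat aggregations are
supported: the default divides the summed presence-weighted vulnerabilities by
the number of habitats present in the cell (mean-over-present-habitats, the
convention of the cumulative-impact mapping literature); `habitat_agg: "sum"`
keeps the straight sum. The underlying global CHI products do not document
which convention their distributed layers used, so the choice is exposed in
configuration rather than hard-coded.

Raw intensities are rescaled to [0, 1] by log(x+1) transform, clipping at the
`clip_quantile` quantile (default 0.9999) of the transformed values, and
division by the clip value. A snapshot analysis computes the clip value within
one period; a change analysis pools both periods of a stressor so that the
two periods share one scale — the only way a 2013 − 2008 difference is
meaningful. Cells missing in a single stressor contribute zero to sums (with
a logged count); a cell missing in *every* stressor is missing in the totals.
The clip value can be zero (an all-zero layer); the rescaled layer is then
all-zero and a warning is logged rather than dividing by zero.

Change in CHI is restricted to change-eligible stressors. The default
registry marks seven of the 19 stressors ineligible — sea-level rise,
shipping, invasive species and ocean pollution (no comparable data in both
periods) plus ocean acidification, artisanal fishing and inorganic pollution
(no difference between periods). Ineligible layers contribute exactly zero to
ΔCHI, so a world in which only ineligible layers differ yields an identically
zero change raster.

## Zonal aggregation

Cells belong to a zone when their centre lies inside the polygon
(cell-centre-in-polygon, the common zonal-statistics default; unbiased for
interior zones). BCU polygons are clipped to the union of EEZs — the 200-nm
rule that removes terrestrial artifacts — and intersected with each EEZ to
produce per-country portions. A BCU is one ecological unit, so its summary
pools the cells of all its portions. Country summaries default to the
unweighted mean of the country's portion means; because the source phrasing
("averaged across BCUs in each country" vs. "calculated across only the
portion … in a country's EEZ") is ambiguous between that and a cell-pooled
mean, the pipeline writes both (`country_summary.csv` and
`country_summary_<other mode>.csv`). Geometries pass a validity-repair step
(`make_valid`) before any predicate, since shapefile dialects commonly carry
invalid rings.

The packaged membership table transcribes the published BCU–country listing:
66 rows, 50 distinct BCUs, 28 countries; 38 BCUs (76%) in one country, 8 in
two and 4 in three; Australia holds 6 and Indonesia 14. One derived statement
in the source text ("nearly one-third (28%) of countries contained one BCU")
does not match a direct count on its own table — the direct count is 16 of 28
countries (57%) with exactly one BCU. The package reports the direct count
and leaves the discrepancy documented here rather than reconciled.

## Management index

Directional min-max normalization is computed across the analyzed country set
only, not hypothetical global ranges. Lower-is-better metrics are inverted
after min-max, which for min-max is mathematically identical to inverting the
raw values first. Imputation operates on normalized scores (a missing country
takes the mean score of observed countries in its region; an entirely
unobserved region falls back to the global mean, logged) and never alters an
observed score. The index is the equal-weight arithmetic mean of the
completed components; collinear pairs (Pearson, two-sided t test on r with
n−2 df, α = 0.05) are reported but never down-weighted or dropped, matching
the equal-weighting convention of composite management indices. A metric with
zero spread yields 0.5 for all observed countries with a warning; a metric
observed nowhere is unusable and raises.

## Association analyses

Impacts (y) are regressed on indices (x) with OLS. Adjusted R² is the
headline statistic — unlike raw R² it can be negative, which is the honest
report when a fit is worse than the intercept-only model — and raw R² is also
emitted. Quadrant classification uses across-unit medians with ties counted
as "high". Outlier sensitivity supports a rule-based mode (1.5×IQR fences on
either variable) and a named-exclusion mode, because published sensitivity
analyses of this kind often list the excluded units without stating the
detection rule. Change-vs-index analyses reuse the same code path with ΔCHI
as the response. No multiple-testing correction is applied across the three
categories, matching the analysis the package reimplements.

## Synthetic world

The generator produces the full input bundle on an abstract equal-area plane
(declared CRS "synthetic, unit = km"): no reprojection is ever needed, since
the contracts, not Earth's shape, are under test.

* **Geometry.** The top `land_fraction` (default 0.25) of the map is land,
  split into vertical country strips; each strip's marine extension is the
  country's EEZ, so EEZs tile the marine area exactly and the map's seaward
  edge is the 200-nm limit. Each BCU occupies its own horizontal band and
  spans 1–3 adjacent countries with probabilities 0.76/0.16/0.08 — the
  observed share of 1-, 2- and 3-country units in the real portfolio. The
  topmost BCU deliberately spills onto land so the clipping stage always has
  work to do. Bands thinner than two raster cells abort generation with an
  error naming the constraint.
* **Stressors.** 19 layers by default (4 climate, 5 land, 10 marine),
  smoothed seeded Gaussian noise min-max-mapped to [0, 1]
  (kernel width `smooth_sigma`, default 3 cells). Land-sourced stressors
  decay exponentially with distance from the coast (e-folding distance a
  quarter of the map height). Period-2 fields add a per-category mean trend
  plus smoothed noise (sd `temporal_noise_sd` = 0.02), clipped to [0, 1].
  Default trends follow the observed directions of change — climate +0.12,
  marine −0.04, land +0.002 on the intensity scale — chosen so the injected
  signs are recoverable through the full change analysis at the default noise
  level. Change-ineligible stressors are copied unchanged between periods.
* **Habitats and vulnerability.** Binary habitat rasters from thresholded
  random fields, with a "reef" habitat forced present inside BCUs; μ weights
  drawn uniformly from [0.2, 1.0]. These exercise habitat-weighted impact
  without claiming ecological realism.
* **Metrics.** Each country carries a latent per-category commitment in
  [0, 1]; raw metric values are affine transforms of commitment-plus-noise on
  heterogeneous scales (lower-is-better metrics decrease with commitment),
  with entries dropped at `metric_missing_rate` (default 0.15) and region
  labels cycling over four synthetic regions. With zero noise and no
  missingness the recomputed index reproduces the latent rank order exactly.

Every stage draws from its own seeded stream (derived from the world seed),
so operations are reproducible individually and identical configurations
reproduce byte-identical output files.

**What the synthetic world does and does not show.** Passing tests establish
the correctness of the contracts — conservation of CHI across categories,
exclusion rules, zonal statistics, normalization/imputation algebra,
regression and quadrant semantics, determinism — on inputs whose truth is
known. The synthetic fields are smoothed noise on a toy coastline: category
contribution shares, absolute CHI magnitudes and regression strengths in a
synthetic run are properties of the generator's defaults (e.g. marine
stressors dominate simply because 10 of 19 layers are marine), and are not
calibrated to, and should not be compared against, values estimated from the
real global pressure layers, which are not redistributable inputs.

## Problem sizes and numerics

Tests run on grids from 3×3 (hand-checkable oracles) to 64×64 (end-to-end
demo); the acceptance script uses a 96×96 world with 12 BCUs across 8
countries. Floating-point conservation (category sums vs. total CHI) is
asserted at 1e-9 relative; rasters are serialized as float64 TIFFs so the
identity survives a disk round-trip. Monte-Carlo checks use 500 replicates
for slope-CI coverage (expected ≥ 93% at a nominal 95%) and 1000 replicates
for the collinearity false-positive rate (expected ≈ 5%).

## Known limitations

* Real EEZ/BCU polygons and stressor rasters are accepted as inputs but no
  geodesic buffering or reprojection is performed; inputs must already share
  an equal-area plane.
* The management-metric registry carries direction flags as data; the package
  cannot infer whether a novel metric is higher- or lower-better.
* Country aggregation ambiguity (portion-mean-of-means vs. cell-pooled) is
  surfaced, not resolved: both tables are written.
* The change analysis underestimates total change by construction whenever
  ineligible stressors did in fact change.
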