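# Methods

## Problem and data model

The package analyses how public-health resources — institutions, technical
personnel, beds, and large equipment — are distributed across the 31
mainland-Chinese provinces, grouped into western (12), middle (8) and
eastern (11) regions by geography and GDP per capita. The unit of
observation is a province-year with resident population (in 10,000-person
units, the yearbook convention), land area (km²), and one raw count per
resource. Two packaged reference tables ship with the package: the national
totals for 2013–2018 (population plus the four counts) and the 2018
provincial snapshot, which was published as densities at 3-decimal
precision, not as raw counts. The snapshot panel is therefore
density-flagged: operations that need raw counts (density computation, the
Theil statistic) reject it with an explicit message instead of silently
treating printed densities as counts.

A romanization collision exists in the source lists: the spelling "Shanxi"
appears in both the western and the middle group. The packaged partition
uses the standard distinct pinyin names — Shaanxi (western, capital Xi'an)
and Shanxi (middle, capital Taiyuan). The bare spelling "Shanxi" resolves to
the middle province; the western one must be spelled Shaanxi. Province names
are matched case-insensitively with whitespace trimmed, with a small alias
table (e.g. "Xizang" → Tibet); unmatched names are hard errors, never
guesses.

## Density indicators

Density is a count divided by population (per 10,000 persons) or by area
(per km²). National totals aggregate by summing counts and populations
before dividing, so the national density is exactly the population-weighted
mean of provincial densities.

Display rounding is half-away-from-zero (2 decimals for national tables, 3
for provincial), because that is the convention of the printed sources;
Python's built-in banker's rounding loses cells on exact halves.

Percent changes between two years are offered in two modes. `table_rounded`
(default) first rounds both densities to 2 decimals and then differences —
this is the only convention under which the published national growth
figures (+8.72% personnel, +24.68% beds, +50.28% equipment, −43.48%
institutions over 2013–2018) reproduce exactly; `raw` differences the
unrounded densities (giving e.g. −43.56% for institutions). The source does
not state which convention it used; the rounded one is inferred from exact
agreement and kept as the fixture-matching default.

Extremes summaries report the min/max province and their ratio per (year,
resource, perspective). Ratios are computed on the stored printed-precision
values — the widely quoted ~1403× Shanghai/Tibet personnel-per-km² gap is
the quotient of the printed 1.403 and 0.001 and is only meaningful at that
precision. Ties break alphabetically by canonical name; a zero minimum
yields an undefined ratio rather than infinity.

One data inconsistency in the 2018 snapshot is worth recording: the source's
results text names Hainan (6.301) as the per-10,000 personnel maximum and
quotes a 2.3× ratio to Anhui (2.709), but its own table and discussion give
Guangxi 7.333 as the maximum. The extremes operation follows the table
(Guangxi, ratio ≈ 2.71); the 2.3 figure is reproducible only as the
Hainan/Anhui quotient of printed cells.

## The Theil statistic and its decomposition

Inequality is measured by the mean-log-deviation (Theil-L) form over
provinces,

    T = Σ_i p_i · ln(p_i / y_i),

with p_i the province's share of total population and y_i its share of the
resource. The orientation is population-weighted: T is the Kullback–Leibler
divergence of the resource-share distribution from the population-share
distribution, hence non-negative and zero exactly when resources are
proportional to population. The resource-weighted (Theil-T) orientation is
out of scope. Values are in nats (natural log) and unbounded above; the
implementation never clamps to [0, 1], a range sometimes informally claimed
for this index.

Grouping provinces into regions j with population shares P_j = Σ_{i∈j} p_i
and resource shares Y_j decomposes T exactly:

    T = T_within + T_between
      = Σ_j P_j · T_j  +  Σ_j P_j · ln(P_j / Y_j),

where T_j is the same statistic on within-group shares (province shares
renormalized by the group totals, so within-group weights are population
weights — the formula taken literally). The implementation computes both
sides independently and asserts |T − T_within − T_between| below 1e-12;
components that land an epsilon below zero from floating-point cancellation
are clamped to zero (tolerance 1e-9, the same as the share-sum check).

Contribution rates divide each component by the total: group j contributes
P_j·T_j / T and the between term T_between / T; they sum to 1 whenever
T > 0 and are reported as undefined (`None`) at T = 0.

Zero resource shares make the statistic infinite. The default policy is
`error` (naming the offending units); an opt-in `drop` policy excludes such
units, renormalizes, and warns. Silent infinities would corrupt trend
series, which is why `drop` is not the default.

Trend analysis decomposes every year of a multi-year panel, sorted
ascending; years lacking the resource are skipped with a warning. Tidy
exporters produce the three standard series: total/within/between per year,
per-region within-group Theil, and contribution rates.

## Synthetic panel generator

The published province-year panels behind the source's Theil trend figures
were never printed, so those series cannot be reproduced numerically; the
generator exists to exercise every pipeline stage and the statistical
guarantees on data with the same structure: 31 provinces in three regions
observed 2013–2018.

Populations (10,000-person units) are log-normal per region, drawn once per
province and held fixed across years; region medians ≈ 2500 (western),
5000 (middle), 4500 (eastern) with scales 0.65/0.35/0.60, giving realistic
province sizes from a few hundred to ~10,000. Per-10,000 densities are
log-normal per (region, resource) — densities are positive and
right-skewed (the real 2018 table spans ~12× per capita and three orders of
magnitude per km²) — with locations anchored to the 2013 national
densities (institutions 0.23, personnel 4.47, beds 1.58, equipment 3.54)
and region scales 0.45/0.20/0.30, the western region most dispersed in line
with the within-western dominance of observed inequality. Densities evolve
by deterministic per-resource annual factors whose five-year compounds
match the observed national 2013→2018 changes (≈0.893/yr for institutions,
1.017, 1.045, 1.085 for the others). Counts are `round(density ×
population)`; rounded-to-zero counts are bumped to 1 so the default
zero-share policy never trips, with a switch (`allow_zero_counts`) for
testing the `drop` policy.

All draws come from one seeded NumPy generator in a fixed order (per
region: populations, then densities resource by resource), so panels are
bit-reproducible given the seed.

What the generator does not emulate: spatial autocorrelation between
neighboring provinces, within-region mean differences beyond the configured
locations, policy shocks (the real institution-count collapse after 2015
was a merger policy, not smooth drift), and any population growth over
time. Passing tests therefore demonstrate correctness of the statistics and
pipeline on structurally realistic data, not calibration to the real
yearbook panels.

The analytic share factory provides configurations with known Theil values
used as independent oracles: uniform shares (T = 0) and the two-block split
with population (π, 1−π) and resource (ρ, 1−ρ), whose closed form is
T = π·ln(π/ρ) + (1−π)·ln((1−π)/(1−ρ)).

## Reporting

`run_report` chains the stages in a fixed order — densities, percent
changes, extremes, per-year Theil decompositions with contribution rates —
each number produced by exactly one library call, so reports match direct
module calls bit for bit. JSON is the canonical artifact (NaN-free;
re-running on identical input is byte-identical); CSV tables and the three
standard figures are projections. Density-flagged panels keep the
density-level stages and skip the Theil stages with an explicit warning.

## Problem sizes

The statistical guarantees are checked on 1,000 random panels of 4–40 units
with random 3-group labelings; the dispersion-recovery experiment uses 200
seeded simulations of the default 31-province panel with western σ = 0.6
against 0.1 elsewhere at equal means, scoring the fraction of runs in which
the western contribution rate is the largest group rate. Both complete in
seconds on one core.

## Known limitations

- The Theil values of the real 2013–2018 provincial panels cannot be
  checked without the yearbook data; only structure and invariants are.
- Printed-precision ratios (1403×) are artifacts of 3-dp rounding; from raw
  counts the ratio would differ.
- The within-group weighting follows the population-share formula literally;
  alternative weightings (resource-share weights inside groups) are not
  offered.
- No uncertainty quantification (bootstrap CIs for Theil values) and no
  alternative inequality indices (Gini, Atkinson, dissimilarity).
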