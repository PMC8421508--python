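# Methods

This note documents the models and procedures `weekmort` implements, the
assumptions behind them, the parameters that matter, and the limits of
what the synthetic-data tests demonstrate.

## Harmonization model

The pipeline assumes that within a calendar year the age and sex
composition of weekly deaths is well described by the composition of
*annual* deaths. All three adjustments are proportional allocations built
on that assumption:

1. **Unknown-age redistribution.** Unknown-age deaths in a (year, week,
   sex) stratum are allocated proportionally to the stratum's own
   known-age counts. If the week has no known-age deaths the annual age
   distribution of the same year and sex is used instead; if that is also
   empty the stratum is unprocessable and an error is raised. The
   hierarchy (week → year → error) is a package choice: silent dropping or
   uniform allocation would bias age-specific rates invisibly.
2. **Age splitting.** A broad source interval is split over the nested
   standard groups in proportion to annual age-specific death counts
   (observed or forecast). Targets that straddle source boundaries are
   rejected rather than approximated.
3. **Sex splitting.** Combined-sex counts are split per age group by the
   annual male share; female counts are the complement, so the sexes sum
   to the input exactly.

Each step conserves the stratum total exactly (floating point aside — the
tests bound the relative error at 1e−9, measured ~1e−16). Because all
three operators are proportional rescalings, unknown-age redistribution
and age splitting commute as long as the annual fallback is not
triggered; the pipeline nonetheless fixes the order unknown-age → age
split → sex split so that runs are reproducible bit-for-bit.

Counts are never rounded: splitting produces fractional deaths, and
conservation is exact only without rounding. No smoothing and no
undercount adjustment is applied anywhere.

**Known bias.** Applying annual age shares to weeks is exact only when
the weekly age distribution is constant over the year. A shock
concentrated at old ages makes the shock weeks' distribution deviate from
the annual one, and the split then under-allocates the shocked groups in
those weeks (the week total is still conserved). The acceptance tests
quantify this deliberately: a 3× old-age shock in one week produces up to
~93% relative error in that week's 85+ cell while all other weeks stay
within 5%. Broad target groups keep this risk contained, which is exactly
why the standard grouping is broad.

**Flags.** `Split` and `SplitSex` describe the *shape of the source
data*, which is a property of a country-year series: if any week of a
year required the adjustment, the whole year is flagged. `Forecast = 1`
marks years whose exposures (and annual splitting denominators) are model
projections rather than observations.

## Week calendars and the 52-week year

Default labelling is ISO-8601 (Monday weeks; week 1 contains January 4).
Sunday- and Saturday-start schemes anchor week 1 as the scheme-aligned
week containing January 4 — the same anchor as ISO-8601, chosen because
national definitions vary and a single documented convention beats
guessing each office's rule; it reduces to ISO-8601 when the start day is
Monday. The January-1 scheme labels 7-day blocks from January 1, leaving
a 1–2 day week 53.

The statistical year always has 52 weeks. Source week-53 counts are
merged into week 52 (conserving totals) by default; a `drop` mode exists
for users who prefer truncation. Every merge is logged. Registration- vs
occurrence-dating is carried through as a flag and never converted — the
conversion is impossible in principle.

## Lee-Carter forecasting and zero-migration projection

For years lacking observed annual deaths/exposures:

* log m(x,t) = a_x + b_x·k_t, with a_x the row means of log rates and
  (b_x, k_t) the leading singular pair of the centered log-rate matrix,
  normalized to Σb = 1, Σk = 0. No second-stage re-estimation of k
  against observed total deaths is applied — the plain SVD fit is kept
  for transparency.
* Zero rates are floored at half the row's smallest positive rate before
  logging (configurable); every flooring is logged.
* k is extrapolated by a random walk with drift, drift = (k_T − k_1)/(T−1);
  only the central path is used (the pipeline needs point exposures), and
  the innovation standard deviation is retained on the fitted object for
  reference.
* Exposures are projected by cohort bookkeeping under zero migration:
  survivors per year are pop·exp(−m); a fraction 1/width of each group's
  survivors ages into the next group (uniform within-group age
  distribution); the open group accumulates; inflow into the youngest
  group is held at its last observed level. The projected population is
  used directly as the person-years estimate. Forecast deaths are rates ×
  projected exposures by construction.
* Default fit window starts in 2005 — short and recent, so the fit tracks
  current mortality change and is comparable across series; the
  `sensitivity_report` helper quantifies how much the start-year choice
  moves final-year forecast rates. Typical horizons are 1–4 years.

**Identifiability limit.** The rank-1 SVD fit requires the period signal
to dominate sampling noise. With exposure of order 1e5 person-years per
age group, a child-mortality row (~3e−4, i.e. ~30 deaths/yr) has log-rate
noise of ~18%, larger than the coherent signal a realistic 1–2%/yr
decline produces; the leading singular vector then locks onto that row's
noise and the whole fit degrades. This is a property of the model, not of
the implementation. The recovery experiments in the tests and the
acceptance script therefore use adult-and-older schedules (≥ ~200
deaths/row), where the fit recovers forecast rates with ~3% median
relative error at horizon 3. Users fitting small populations should
aggregate ages or use larger exposures.

## Rates, baselines, excess

Weekly rates are deaths per person-week, m = D/(E/52), so a year of
uniform weekly deaths has mean weekly rate equal to the annual rate.

Expected weekly schedules come from a registry of baseline methods:
`week_mean` (default; week-specific average over the reference years,
e.g. 2015–19), `week_median`, `week_mean_trend` (per-week OLS on year,
evaluated at the target year; needs ≥ 3 reference years),
`annual_min_year` (the reference year with the lowest mean rate),
`specific_year`, and `week_mean_excluding_shocks` (trimmed mean dropping
the extreme year at each tail). The registry is a documented stand-in for
the various reference-level conventions in circulation and is trivially
extensible.

Excess = observed − expected, per week, for rates and (via exposure/52)
counts; deficits are negative and preserved; cumulative excess over a
window is the sum of weekly excess. Because recent weeks are incomplete
under registration lag, a completeness cutoff week can exclude them from
excess output; the data themselves are never adjusted.

## Quality checks

All checks are pure functions producing report entries, never exceptions
and never data edits: group sums vs all-ages totals, male+female vs
both-sex, processed vs raw weekly totals, male/female rate-ratio
plausibility band (default [0.5, 5], warn-only), and weekly sums vs
official annual totals (default tolerance 1%, a package choice exposed in
config).

Outlier screening centres each week on its same-week median across
reference years, but estimates the robust scale from the *pooled*
residuals of all weeks (MAD × 1.4826, with two small-sample corrections:
√(n/(n−1)) for the deflation of residuals about an own-sample median, and
√(1 + π/2n) for the median's own estimation variance). A per-week MAD of
4–6 values is too noisy to be usable — it flags several percent of null
weeks at |z| > 4, versus ~0.07% for the pooled estimator — while the
median centre keeps the screen robust to genuine shock weeks, which are
the signal of interest and must not inflate the scale. Flags are
advisory only.

## Synthetic data

The generator emulates what the harmonization model assumes: stable
annual age/sex death rates with a log-linear secular trend (default
−1%/yr), sinusoidal weekly seasonality (default 15% relative amplitude
peaking in week 2, normalized to mean 1 so annual totals are
seasonality-free), Poisson sampling of weekly counts, and optional shocks
(additive deaths or a rate multiplier, by default concentrated at old
ages). Default exposures and rates describe a mid-sized developed
country: ~11.7M people, ~96 000 deaths/year, male rates ~40% above
female. Annual tables are the *sums of the sampled weekly counts* and
official totals equal the annual sums, so generated data are internally
consistent by construction and the internal checks pass exactly.

The coarsening step degrades the fine table the way sources do: broad-
group sums, optional both-sex merge, and extraction of a fixed fraction
of each cell into an unknown-age row. The extraction is deterministic (a
fixed proportion, not a random draw) so that the coarsen→harmonize
round-trip identity is exact and seeds affect only the Poisson sampling.

**What passing tests show — and don't.** Recovery results on this
generator certify the algebra and the implementation (conservation,
proportional-split identities, LC recovery in the identifiable regime,
shock recovery within sampling error). They do not certify behaviour on
real data, where weekly age distributions shift within years (the split
bias above), mortality trends break, registration artifacts distort
weekly counts, and exposures carry census error. The generator has no
within-year age-distribution drift except through explicit shocks, no
migration, and no reporting lag.

## Problem sizes and numerical choices

Test and acceptance runs use 6–9 year series at 52 weeks × 2 sexes × 5
age groups, 100 replicates for the Lee-Carter noise experiment and 200
for shock recovery — sizes at which every Monte-Carlo margin in the tests
is several standard errors wide. Conservation tolerances are 1e−9
relative (measured ~1e−16); LC constraint normalization is exact to
1e−10; ties and degenerate inputs (zero strata, zero denominators,
single-group populations, empty horizons) follow the rules stated in the
docstrings — zero weekly counts split to zeros, zero annual denominators
with positive weekly counts are errors, horizon 0 is an empty forecast.

## Limitations

* Annual-share splitting biases shock weeks' age composition (quantified
  above); only broad target groups mitigate this.
* The LC fit is unweighted; low-count age rows degrade it (documented
  identifiability limit). No jump-off adjustment, no prediction
  intervals, no cohort effects, no migration.
* Sunday/Saturday week-1 anchoring is a package convention, not a
  reproduction of each statistical office's rule.
* Baseline methods are a stand-in registry, not an authoritative
  enumeration of any particular toolkit's options.
* No age standardization, P-scores, or cause-of-death decomposition.
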