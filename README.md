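# weekmort

Weekly all-cause mortality harmonization, Lee-Carter exposure forecasting,
and excess-mortality estimation.

## The problem

National statistical offices publish weekly all-cause death counts on
wildly different age scales — some by 5-year groups, some by bands as
broad as 0–17 / 18–64 / 65+, some for both sexes combined, some with a
residual "unknown age" count — and label weeks by different calendars
(ISO-8601 Monday weeks, Sunday or Saturday weeks, 7-day blocks from
January 1). Comparing short-term mortality fluctuations across countries,
as pandemic surveillance and demographic research require, needs all of
this harmonized onto one scale: death counts and person-week death rates
for five standard age groups (0–14, 15–64, 65–74, 75–84, 85+) by sex,
on a 52-week statistical year.

`weekmort` implements that pipeline for demographers and epidemiologists,
together with a synthetic-data generator with known ground truth so every
stage is testable without any external data.

## The method

Per stratum (year *y*, week *w*), with annual death counts
*D<sub>y</sub>* (observed, or forecast when not yet available):

* **Age splitting** — a broad source interval [*x*, *x*+*b*) is
  disaggregated onto a nested target group [*x*, *x*+*a*) in proportion to
  the annual age distribution:

  *D̂<sub>y</sub><sup>w</sup>(x, x+a) = D<sub>y</sub><sup>w</sup>(x, x+b) ·
  D<sub>y</sub>(x, x+a) / D<sub>y</sub>(x, x+b)*

* **Sex splitting** — combined-sex counts are split by the annual sex
  ratio in the same age group:
  *D̂<sub>y</sub><sup>w,males</sup> = D<sub>y</sub><sup>w,total</sup> ·
  D<sub>y</sub><sup>males</sup> / D<sub>y</sub><sup>total</sup>*

* **Unknown-age redistribution** — proportional to the stratum's own
  known-age counts, falling back to the annual age distribution.

* **Person-week rates** — *m<sub>y</sub><sup>w</sup> =
  D̂<sub>y</sub><sup>w</sup> / (E<sub>y</sub> / 52)*, with *E<sub>y</sub>*
  the annual person-years exposure, so weekly rates are directly
  comparable with annual rates.

* **Lee-Carter forecasting** — for recent years lacking annual data,
  log *m(x,t) = a<sub>x</sub> + b<sub>x</sub>k<sub>t</sub>* is fitted by
  rank-1 SVD (fit window starting 2005 by default), *k<sub>t</sub>* is
  extrapolated by a random walk with drift, and exposures are projected
  by cohort bookkeeping under zero migration. Such years carry
  `Forecast = 1`.

* **Excess mortality** — observed minus expected weekly rates, where the
  expected schedule comes from a configurable baseline registry
  (week-specific mean over a reference window by default, e.g. the
  2015–19 average; also median, per-week linear trend, trimmed mean,
  lowest-mortality year, single reference year).

Every adjustment conserves stratum totals exactly and is visible in the
output `Split` / `SplitSex` / `Forecast` flags; nothing is smoothed and no
undercount adjustment is applied. Consistency checks (group sums vs
totals, sexes vs both-sex, processed vs raw totals, weekly sums vs
official annual figures, robust per-week outlier z-scores) produce a
machine-readable report and never mutate the data.

## Worked example

Generate a synthetic country (2014–2020, ~96 000 deaths/year, 1 %/yr
mortality decline, a 4 000-death shock injected in weeks 12–18 of 2020),
withhold the 2019–20 annual tables, and run the pipeline end to end:

```sh
weekmort simulate --seed 7 --out demo/        # then drop annual years > 2018
weekmort run --config demo/pipeline.yaml
```

with `pipeline.yaml`:

```yaml
raw_path: demo/raw_weekly.csv
annual_path: demo/annual.csv          # observed through 2018 only
official_path: demo/official_totals.csv
lc_fit_start: 2014
reference_years: [2015, 2019]
target_year: 2020
output_path: demo/stmf.csv
excess_path: demo/excess.csv
report_path: demo/validation.jsonl
```

This prints

```
1092 output records; 2191 check(s): 2191 pass, 0 warn, 0 fail
```

and `demo/stmf.csv` begins

```
CountryCode,Year,Week,Sex,D0_14,D15_64,D65_74,D75_84,D85p,DTotal,R0_14,...,RTotal,Split,SplitSex,Forecast
SYN,2014,1,b,9,291,302,573,639,1814,0.000281927...,0.009423376...,0,0,0
```

i.e. 1814 deaths in week 1 of 2014 across both sexes, an all-ages rate of
0.0094 per person-week, and no adjustment flags (the input was fully
detailed; 2019–20 rows carry `Forecast = 1` because their exposures are
Lee-Carter projections). Summing `demo/excess.csv` over the shock window
recovers the injected shock:

```
cumulative excess deaths (both sexes), weeks 12-18: 3921.6   # 4000 injected
cumulative excess deaths (both sexes), full year:   1744.8
```

The full-year figure is smaller because the 1 %/yr secular decline puts
2020's baseline mortality below the 2015–19 average — a deficit that
partially offsets the shock, exactly as week-specific-average baselines
behave on real data.

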