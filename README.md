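# countyrank

Within-state composite health scoring and ranking of counties, implementing
the County Health Rankings methodology as a reusable, testable engine.

Public-health surveillance programs summarize the health of every county in
a state with two composite indices — **health outcomes** (current health:
mortality and morbidity) and **health factors** (modifiable determinants:
health behaviors, clinical care, social & economic factors, physical
environment) — and rank counties within their state from healthiest (#1)
downward. `countyrank` provides that pipeline for analysts who want to run
it on their own data, re-weight it, or study its statistical behavior:
epidemiologists reproducing a state ranking, methodologists probing
sensitivity to weights and data quality, and teaching settings that need a
fully synthetic, self-contained version of the workflow.

## The method

Each measure *m* of county *i* in state *s* is standardized against the
other counties of the same state:

```
z_im = (x_im − mean_s(x_m)) / sd_s(x_m)
```

with the state mean and SD taken over observed counties (sample SD by
default). Data-quality handling:

* **Reliability** — an estimate with relative standard error above 20%
  (se/|x| > 0.20) is treated as missing.
* **Imputation** — missing cells receive the state mean, i.e. z = 0.
* **Direction** — reverse-coded measures (higher value = better health,
  e.g. high-school graduation) are negated so higher z always means poorer
  health.
* **Small-county truncation** — counties with ≤ 20,000 residents have |z|
  clamped to 3.0.

Z-scores are multiplied by their catalog weights and summed into eight
composites — the two family scores and their six components. The default
catalog is the 2014 measure set: 34 measures, outcomes split 50/50 between
premature death (years of potential life lost before 75) and four
morbidity measures, factors split 30/20/40/10 across the four components.
Within each state, composites are sorted ascending and competition-ranked:
the lowest score (best health) is rank 1. Counties without usable
premature-death data are flagged unrankable under three rules. Quartiles,
direction-aware national best-10% benchmarks, and a least-healthy vs
healthiest extremes comparison round out the outputs.

A synthetic-panel generator draws counties whose measures all load on one
latent health score per county, with log-normal populations,
population-dependent standard errors and the banded missingness profile of
the real 2014 panel — so the whole pipeline can be exercised and validated
offline against known ground truth.

## Worked example

```python
from countyrank import CountyHealthRankings, SimulationConfig, generate_counties

table, truth = generate_counties(
    SimulationConfig(seed=7, n_states=3, counties_per_state=12))
res = CountyHealthRankings(table).fit()
print(res.summary())
```

```
County Health Rankings Results
==============================================
Catalog:                    chr-2014 (34 measures)
Counties:                   36
States:                     3
SD flavor:                  sample
----------------------------------------------
Imputed cells:              53
Truncated cells:            0
Unreliable cells:           0
State-measures dropped:     0
Unranked counties:          0 (0.0%)
----------------------------------------------
Composite score distribution (ranked counties):
      outcomes  mortality  morbidity  factors  health_behaviors  clinical_care  social_economic  physical_environment
mean    0.0000     0.0000    -0.0000   0.0000            0.0000         0.0000          -0.0000               -0.0000
std     0.8734     0.4855     0.4143   0.8226            0.2428         0.1732           0.3403                0.0872
...
```

The 53 imputed cells are the synthetic panel's missing values (the default
missingness profile leaves gaps in the survey-based measures), each scored
at the state mean. Per-county results:

```python
res.to_frame()[["state", "score_outcomes", "rank_outcomes",
                "rank_factors", "quartile_outcomes"]].head(6)
```

```
      state  score_outcomes  rank_outcomes  rank_factors  quartile_outcomes
fips
01001    AA       -0.251549              3             5                  1
01002    AA        0.786376             10            11                  4
01003    AA       -0.212379              4             3                  2
01004    AA        0.025851              7             4                  3
01005    AA       -0.028803              6             9                  2
01006    AA       -0.108979              5             8                  2
```

County 01001 scores 0.25 weighted SD units better (lower) than its state's
average on outcomes, placing 3rd of 12 and in the healthiest quartile;
its health-factor profile is slightly weaker (5th). `res.benchmarks()`
gives the national best-10% boundary per measure in raw units, e.g.
`premature_death 5812.6` — the 10th percentile of county premature-death
rates, since lower is better; and `res.compare_extremes()` pools each
state's five best- and worst-ranked counties into the healthy / least
healthy comparison with group means and their ratio.

The same pipeline is available from a shell:

```
countyrank simulate --n-states 50 --seed 1 -o counties.csv
countyrank rank counties.csv -o out/
countyrank validate counties.csv
countyrank export-catalog -o catalog.yaml
```

## Layout

* `countyrank.catalog` — measure hierarchy, 2014 default, validation
* `countyrank.standardize` — within-state z-scores, reliability, imputation,
  truncation
* `countyrank.composite` — weighted composites, ranks, quartiles, unranked
  rules, benchmarks, extremes
* `countyrank.model` — `CountyHealthRankings` / `RankingsResults` facade
* `countyrank.synthetic` — latent-health panel generator
* `countyrank.io`, `countyrank.cli`, `countyrank.config` — CSV formats,
  command line, options

See `docs/methods.md` for the modelling choices, defaults and limitations.
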