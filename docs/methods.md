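# Methods

## The scoring model

The package scores a county panel with two composite indices per county —
health outcomes and health factors — each a weighted sum of within-state
standardized measures. The model's premise is comparative, not absolute:
a county's score is meaningful only relative to the other counties of its
state, which is why every transformation is state-local and the final
product is a within-state rank.

For measure *m* in state *s*, using the observed counties of that state,

    z_im = (x_im − mean_s) / sd_s ,

then reverse-coded measures are negated (so higher z = poorer health
everywhere), and counties with populations ≤ 20,000 have z clamped to
[−3, 3]. Composites are Σ (w_m/100)·z_im with weights expressed as percent
of the composite family; the six component scores (mortality, morbidity;
behaviors, clinical care, social & economic, environment) partition their
family score exactly. Within each state, each of the eight composites is
competition-ranked ascending: lowest score (best health) = rank 1; ties
share the minimal rank.

Assumptions worth stating plainly: measures are exchangeable within the
weighted hierarchy once standardized (no correlation adjustment between
measures); the state's counties are treated as a sample from a wider
process (hence sample SD, n−1, by default); and the weights are normative,
set by the catalog, not estimated from the data.

## Data-quality handling

* **Reliability.** A cell with relative standard error above the threshold
  (default 0.20; a zero estimate with positive SE counts as unreliable) is
  treated as missing for scoring but remembered on a separate flag. The
  published method applies the reliability rule explicitly to premature
  death and low birthweight; this package applies the same rule uniformly
  to every SE-bearing measure, which is the simpler and more defensible
  generalization.
* **Imputation.** Missing (or unreliable) cells are assigned the state
  mean, i.e. exactly z = 0; state means and SDs are computed from observed
  counties only, so observed z-scores still have mean 0 and SD 1 within
  each state-measure.
* **Whole-state missingness.** A state-measure with fewer than two observed
  counties (e.g. a pollution measure unavailable statewide) carries no
  information: the measure is dropped for that state and the remaining
  weights of the same composite family are rescaled proportionally to sum
  to 100, preserving the composite scale across states. Measures absent
  from the input table entirely are treated as dropped in every state.
* **Zero variance.** A constant state-measure yields z = 0 for everyone,
  with no flag: the counties genuinely do not differ. Variance below the
  float round-off of the mean (sd ≤ 1e−12·max(1, |mean|)) counts as zero,
  so a constant column never manufactures spurious scores.
* **Order of transforms.** standardize → impute → direction-flip →
  truncate. The clamp is symmetric, so the direction-flip/truncation order
  is immaterial; it is fixed anyway for reproducibility.

## Unrankable counties

A county is excluded from all ranks when its mortality anchor is unusable:
(1) premature death missing; (2) premature death unreliable and no
morbidity measure present; (3) premature death and low birthweight both
unreliable and no other morbidity measure present. "Present" means a
value exists, reliable or not — rule 3 exists precisely for the case where
low birthweight is present but unreliable, so the three rules are
disjoint and are reported as the first that matches. Catalogs without a
premature-death measure rank every county. Unranked counties keep their
composite scores but carry no ranks or quartiles, and quartiles are
assigned over ranked counties only: q = ceil(4·rank/n_ranked), clamped to
1–4 (a state with a single ranked county puts it in quartile 4, the
documented degenerate case).

## Fixed constants and options

| Option | Default | Meaning |
| --- | --- | --- |
| `sd_flavor` | sample | n−1 denominator for the state SD; `population` (n) available because the original implementation does not document its choice |
| `truncation_threshold_population` | 20,000 residents | inclusive population cut for the z clamp |
| `truncation_z` | 3.0 SD | clamp magnitude |
| `rse_threshold` | 0.20 | relative-standard-error reliability cut |
| `benchmark_percentile` | 10 | national best-X% benchmark |
| `extremes_k` | 5 counties | per-tail pool in the extremes comparison |
| `extremes_min_counties` | 10 | minimum state size for the extremes comparison |

The national benchmark is the 10th percentile of observed county values
for adverse measures and the 90th for reverse-coded ones, with linear
interpolation between order statistics (no percentile method is documented
upstream; linear interpolation is numpy's default and the least surprising
choice). It is computed over all counties with observed values, ranked or
not, and requires at least 10 observations. The extremes comparison uses
unweighted group means across counties (population is reported as its own
row, not used as a weight), restricts to states with at least 10 counties,
orders ranked counties by outcomes rank with FIPS breaking ties, and keeps
the best-k and worst-k pools disjoint when a state has fewer than 2k
ranked counties. Ratios are reported rounded to one decimal.

Tie-breaking is competition ranking (ties share the minimal rank, the next
rank is skipped); output rows are ordered by FIPS so identical inputs give
byte-identical outputs.

## The synthetic panel

The generator exists to make every pipeline path testable against known
ground truth; it emulates the *shape* of a national county panel, not real
US distributions (no geographic structure, no realistic marginals, no
informative missingness).

Each county draws a latent health score L ~ N(0,1) (lower = healthier).
Measure values are `baseline_m ± a_m·L + N(0, s_m)`, with the sign chosen
so healthier counties look better on every measure. Defaults, chosen once:

* **Baselines** are national county means (premature death 7,746 YPLL per
  100,000; adult smoking 21%; …) so raw values have realistic magnitudes.
* **Scale** of each measure is 20% of its baseline (floor 0.5); the latent
  loading is 0.8× scale and the noise SD 0.4× scale — a signal-to-noise
  ratio of 2, which makes the outcomes composite correlate ≈ 0.96 with the
  latent score: informative but clearly noisy measures.
* **Populations** are log-normal (log-mean 10.2, log-sd 1.4): median
  ≈ 27,000 residents with roughly 40% of counties at or below the 20,000
  truncation cut, so the clamp path is exercised, floored at 50 residents.
* **Standard errors** follow `20·scale/√population` for the nine
  survey/vital-statistics measures, giving a median county an RSE of ~2%
  and pushing only very small counties over the 20% reliability cut.
* **Missingness** is independent per cell (MCAR) at the banded 2014
  profile: 12 measures complete, six at 0.5%, nine at 5%, six at 15% and
  excessive drinking at 28%. Band membership is assigned by data-source
  plausibility (survey measures in the high band, vital-statistics and
  census measures complete); only the band counts, not the membership, is
  documented upstream.
* **State layout** defaults to 50 states of 5–120 counties (uniform), a
  national-scale spread in which a few states fall under the 10-county cut
  used by the extremes comparison.

Because the data are MCAR with a single latent factor, passing tests show
the pipeline's arithmetic and data-quality logic are correct; they do not
validate the method against real counties, where missingness is
informative, measures have multiple correlated drivers, and distributions
are skewed.

## Validation design

Two independent oracles back the test suite: a per-cell pure-Python
standardization/aggregation (no numpy) and a sort-and-count competition
ranker. The vectorized pipeline must agree with both to 1e−12 on random
micro-panels. Parameter recovery is checked two ways:

* **Exact**: with zero noise, zero missingness and zero sampling error,
  within-state outcome ranks must equal the latent-health ordering in
  every state. This experiment uses 10 counties per state because the
  maximal within-state sample z-score is (n−1)/√n < 3 for n ≤ 10, so the
  truncation clamp provably cannot fire. At larger state sizes the clamp
  can tie two extreme small counties at exactly ±3.0 (both are censored),
  making the latent order unrecoverable there by design — a documented
  property of the truncation rule, not a defect.
* **Statistical**: under the default noise and missingness at 46 states of
  20–100 counties, the mean within-state Spearman correlation between
  latent health and the outcomes rank is ≈ 0.94.

Monotonicity (worsening one value never improves the county's rank) is
checked over 1,000 random perturbations. It is worth recording that this
is not a strict theorem under within-state standardization: worsening an
extreme county shifts the state SD, which in contrived configurations can
compress its z-gap to a county on the other side of the mean enough to
flip a near-tied composite. No violation occurs under the study
conditions; the property should be read as "holds in practice", not as an
algebraic identity.

Problem sizes in the checked experiments (46×20–100 counties for the
distributional properties, 100 micro-panels for oracle agreement, 1,000
perturbations for monotonicity) were chosen as the smallest scales at
which each property is meaningfully exercised.

## Known limitations

* Upstream preparation is out of scope: no multi-year averaging, no age
  adjustment, no acquisition from the national data sources; the package
  starts from a prepared county × measure table.
* Weights are taken as given; the derivation of the default weights is not
  modelled.
* Ranks are ordinal and state-local: no cross-state county ranking and no
  year-over-year rank-change analysis is offered, since close ranks are
  not statistically distinguishable and rank changes confound a county's
  trend with its neighbors'.
* The RSE reliability rule needs standard errors; measures without SE
  columns are never flagged unreliable, however noisy.
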