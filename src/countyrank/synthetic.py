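"""Synthetic multi-state county tables with a known latent health structure.

The generator emulates the shape of a national county panel: states holding
a handful to a hundred-plus counties, log-normal county populations (so a
sizable share fall at or below the 20,000-resident truncation cut),
survey-style standard errors shrinking with population, and per-measure
missingness matching the banded profile of the real 2014 panel (12 measures
complete, six nearly complete, nine moderately missing, seven heavily
missing with excessive drinking worst at 28%).

Each county draws a single latent health score (standard normal; lower =
healthier) that loads on every measure with a direction-consistent sign, so
the true within-state health ordering is known and rank recovery can be
measured end to end.  Baseline levels are national county means; the
default loading-to-noise ratio of 2 makes the outcomes composite correlate
about 0.96 with the latent score — informative but noisy measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import MeasureCatalog, load_default_catalog, HIGHER_IS_BETTER
from .io import CountyMeasureTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_counties",
    "default_missingness_profile",
    "MEASURE_BASELINES",
]

#: national county-mean baselines per default-catalog measure (raw units)
MEASURE_BASELINES: dict[str, float] = {
    "premature_death": 7746.0,
    "poor_fair_health": 17.0,
    "poor_physical_days": 3.7,
    "poor_mental_days": 3.5,
    "low_birthweight": 8.0,
    "adult_smoking": 21.0,
    "adult_obesity": 31.0,
    "food_environment": 2.4,
    "physical_inactivity": 28.0,
    "access_exercise": 54.0,
    "excessive_drinking": 16.0,
    "alcohol_driving_deaths": 31.0,
    "sexually_transmitted_infections": 271.0,
    "teen_births": 42.4,
    "uninsured": 18.0,
    "primary_care_physicians": 1980.0,
    "dentists": 2730.0,
    "mental_health_providers": 1640.0,
    "preventable_stays": 71.0,
    "diabetic_screening": 85.0,
    "mammography_screening": 61.0,
    "hs_graduation": 83.0,
    "some_college": 55.0,
    "unemployment": 8.0,
    "children_poverty": 24.0,
    "inadequate_social_support": 19.0,
    "single_parent_households": 31.0,
    "violent_crime": 204.5,
    "injury_deaths": 73.0,
    "air_pollution": 11.93,
    "drinking_water_violations": 1.0,
    "severe_housing_problems": 14.0,
    "driving_alone_to_work": 80.0,
    "long_commute_driving_alone": 29.0,
}

# banded missingness profile of the 2014 panel: 12 complete measures, six at
# 0.5%, nine at 5%, seven above 10% (excessive drinking worst at 28%)
_MISSING_ZERO = (
    "premature_death", "adult_obesity", "physical_inactivity", "uninsured",
    "primary_care_physicians", "dentists", "some_college", "unemployment",
    "children_poverty", "single_parent_households", "driving_alone_to_work",
    "long_commute_driving_alone",
)
_MISSING_LOW = (
    "low_birthweight", "teen_births", "hs_graduation", "injury_deaths",
    "mental_health_providers", "severe_housing_problems",
)
_MISSING_MID = (
    "food_environment", "access_exercise", "sexually_transmitted_infections",
    "mammography_screening", "diabetic_screening", "preventable_stays",
    "violent_crime", "drinking_water_violations", "air_pollution",
)
_MISSING_HIGH = (
    "poor_fair_health", "poor_physical_days", "poor_mental_days",
    "adult_smoking", "inadequate_social_support", "alcohol_driving_deaths",
)
_MISSING_DRINKING = "excessive_drinking"


def measure_scale(measure_id: str, baseline: float | None = None) -> float:
    """Characteristic cross-county spread of a measure (raw units)."""
    if baseline is None:
        baseline = MEASURE_BASELINES.get(measure_id, 1.0)
    return max(0.2 * abs(baseline), 0.5)


def default_missingness_profile(
    catalog: MeasureCatalog | None = None,
    uniform_rate: float | None = None,
) -> dict[str, float]:
    """Per-measure missing probabilities reproducing the banded 2014 profile.

    For the default catalog: 12 measures at 0, six at 0.005, nine at 0.05,
    six at 0.15 and excessive drinking at 0.28 (the seven >10% band).  A
    ``uniform_rate`` overrides everything; non-default catalogs fall back to
    a uniform 0.05 unless a rate is given.
    """
    if catalog is None:
        catalog = load_default_catalog()
    ids = catalog.measure_ids
    if uniform_rate is not None:
        return {m: float(uniform_rate) for m in ids}
    banded = set(_MISSING_ZERO) | set(_MISSING_LOW) | set(_MISSING_MID) \
        | set(_MISSING_HIGH) | {_MISSING_DRINKING}
    if not set(ids) <= banded:
        return {m: 0.05 for m in ids}
    rates = {}
    for m in ids:
        if m in _MISSING_ZERO:
            rates[m] = 0.0
        elif m in _MISSING_LOW:
            rates[m] = 0.005
        elif m in _MISSING_MID:
            rates[m] = 0.05
        elif m == _MISSING_DRINKING:
            rates[m] = 0.28
        else:
            rates[m] = 0.15
    return rates


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic county panel.

    Parameters
    ----------
    n_states
        Number of states (default 50).
    counties_per_state
        An int (every state equal), an inclusive ``(lo, hi)`` range drawn
        uniformly per state, or an explicit per-state sequence.  Default
        (5, 120): mean ~62 counties, a realistic national spread in which a
        few states fall under ten counties.
    seed
        Seed for all randomness; identical seeds give identical tables.
    latent_effect, noise_sd
        Per-measure loading of latent health and residual noise SD (raw
        units).  Defaults: 0.8x and 0.4x the measure scale (signal-to-noise
        2).  A float scales the defaults instead.
    missing_rate
        Per-measure missing probability; ``None`` = banded default profile,
        a float = uniform rate.
    se_scale
        Standard errors follow se_scale x scale / sqrt(population)
        (default 20: a median county's RSE is ~2%, tiny counties unreliable).
    population_log_mean, population_log_sd
        Log-normal population parameters (defaults 10.2 / 1.4: median
        ~27,000 residents with ~40% of counties at or below 20,000).
    """

    n_states: int = 50
    counties_per_state: int | tuple[int, int] | Sequence[int] = (5, 120)
    seed: int = 0
    latent_effect: Mapping[str, float] | float | None = None
    noise_sd: Mapping[str, float] | float | None = None
    missing_rate: Mapping[str, float] | float | None = None
    se_scale: float = 20.0
    population_log_mean: float = 10.2
    population_log_sd: float = 1.4

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        cps = self.counties_per_state
        if isinstance(cps, int):
            if cps < 1:
                raise ValueError("counties_per_state must be >= 1")
        elif isinstance(cps, tuple) and len(cps) == 2:
            lo, hi = cps
            if lo < 1 or hi < lo:
                raise ValueError("counties_per_state range must satisfy "
                                 "1 <= lo <= hi")
        else:
            counts = list(cps)
            if len(counts) != self.n_states:
                raise ValueError("per-state counties sequence must have "
                                 "n_states entries")
            if any(c < 1 for c in counts):
                raise ValueError("counties_per_state entries must be >= 1")
        if self.se_scale < 0:
            raise ValueError("se_scale must be >= 0")
        if self.population_log_sd < 0:
            raise ValueError("population_log_sd must be >= 0")
        if isinstance(self.missing_rate, (int, float)):
            if not 0 <= self.missing_rate <= 1:
                raise ValueError("missing_rate must be in [0, 1]")
        elif isinstance(self.missing_rate, Mapping):
            bad = {m: r for m, r in self.missing_rate.items()
                   if not 0 <= r <= 1}
            if bad:
                raise ValueError(f"missing rates outside [0, 1]: {bad}")


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic panel: the latent health per county.

    Lower latent health = healthier county.  ``within_state_order`` gives
    the true competition ranks of latent health inside each state, directly
    comparable to the pipeline's outcomes ranks.
    """

    latent_health: pd.Series      # index fips
    state: pd.Series

    def within_state_order(self) -> pd.Series:
        return (self.latent_health.groupby(self.state.to_numpy())
                .rank(method="min").astype(int))

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "state": self.state,
            "latent_health": self.latent_health,
        })
        out.index.name = "fips"
        return out


def _state_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = [a + b for a in letters for b in letters]
    return codes[:n]


def _per_measure(param, measure_ids, default_fn):
    """Resolve a per-measure parameter: mapping, scalar multiplier, or None."""
    if param is None:
        return {m: default_fn(m) for m in measure_ids}
    if isinstance(param, Mapping):
        return {m: float(param.get(m, default_fn(m))) for m in measure_ids}
    return {m: float(param) * default_fn(m) for m in measure_ids}


def generate_counties(
    config: SimulationConfig | None = None,
    catalog: MeasureCatalog | None = None,
) -> tuple[CountyMeasureTable, SyntheticTruth]:
    """Draw a synthetic county panel plus its latent ground truth.

    For county i with latent health L_i ~ N(0, 1) and measure m:

        value = baseline_m + sign_m * a_m * L_i + noise,
        noise ~ N(0, s_m),  sign_m = -1 for reverse-coded measures,

    so healthier counties (lower L) have lower values on higher-is-worse
    measures and higher values on reverse-coded ones.  Populations are
    log-normal; SE-bearing measures get se = se_scale * scale_m /
    sqrt(population); cells are masked missing independently (MCAR) at the
    per-measure rate.  Fully deterministic given the seed.
    """
    if config is None:
        config = SimulationConfig()
    if catalog is None:
        catalog = load_default_catalog()
    rng = np.random.default_rng(config.seed)

    # per-state county counts
    cps = config.counties_per_state
    if isinstance(cps, int):
        counts = [cps] * config.n_states
    elif isinstance(cps, tuple) and len(cps) == 2:
        counts = rng.integers(cps[0], cps[1] + 1,
                              size=config.n_states).tolist()
    else:
        counts = [int(c) for c in cps]

    states = _state_codes(config.n_states)
    state_col = np.repeat(states, counts)
    fips = [f"{si + 1:02d}{ci + 1:03d}"
            for si, c in enumerate(counts) for ci in range(c)]
    n = len(fips)

    population = np.maximum(
        50, np.rint(rng.lognormal(config.population_log_mean,
                                  config.population_log_sd, n))
    ).astype(np.int64)
    latent = rng.standard_normal(n)

    ids = catalog.measure_ids
    baselines = {m: MEASURE_BASELINES.get(m, 1.0) for m in ids}
    scales = {m: measure_scale(m, baselines[m]) for m in ids}
    effects = _per_measure(config.latent_effect, ids,
                           lambda m: 0.8 * scales[m])
    noises = _per_measure(config.noise_sd, ids, lambda m: 0.4 * scales[m])
    if any(v < 0 for v in noises.values()):
        raise ValueError("noise_sd must be >= 0")
    rates = config.missing_rate
    if rates is None or isinstance(rates, (int, float)):
        rates = default_missingness_profile(
            catalog, None if rates is None else float(rates))

    values = pd.DataFrame(index=pd.Index(fips, name="fips"), columns=ids,
                          dtype=float)
    ses = pd.DataFrame(index=values.index)
    sqrt_pop = np.sqrt(population)
    for m in ids:
        sign = -1.0 if catalog[m].direction == HIGHER_IS_BETTER else 1.0
        col = baselines[m] + sign * effects[m] * latent
        if noises[m] > 0:
            col = col + rng.normal(0.0, noises[m], n)
        if rates.get(m, 0.0) > 0:
            mask = rng.random(n) < rates[m]
            col = np.where(mask, np.nan, col)
        values[m] = col
        if catalog[m].has_standard_error and config.se_scale > 0:
            ses[m] = np.where(np.isnan(col), np.nan,
                              config.se_scale * scales[m] / sqrt_pop)

    counties = pd.DataFrame(
        {"state": state_col, "population": population}, index=values.index)
    table = CountyMeasureTable(counties=counties, values=values,
                               standard_errors=ses)
    truth = SyntheticTruth(
        latent_health=pd.Series(latent, index=values.index,
                                name="latent_health"),
        state=counties["state"],
    )
    return table, truth
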