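"""Weighted composites, within-state ranks, quartiles, benchmarks, extremes.

Standardized scores are multiplied by their catalog weights and summed into
eight composites per county: the two family scores (health outcomes, health
factors) and their six component scores (mortality, morbidity; health
behaviors, clinical care, social & economic, physical environment).  Family
scores are the exact sums of their component scores.  Within each state the
composites are sorted ascending and ranked: rank 1 is the lowest score,
i.e. the best health.  Ties share the minimal rank (competition ranking).

Counties without usable premature-death data cannot be ranked; three rules
flag them.  Quartiles are assigned from the outcomes and factors ranks.
The module also computes direction-aware national best-10% benchmarks per
measure and the least-healthy-vs-healthiest extremes comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (MeasureCatalog, load_default_catalog, OUTCOMES, FACTORS,
                      COMPONENTS, FAMILY_OF_COMPONENT, HIGHER_IS_BETTER)
from .config import RankingOptions
from .io import CountyMeasureTable
from .standardize import StandardizedTable

__all__ = [
    "COMPOSITE_COLUMNS",
    "RankingResult",
    "ExtremesComparison",
    "compute_composites",
    "determine_unranked",
    "rank_within_state",
    "assign_quartiles",
    "national_benchmark",
    "compare_extremes",
    "extremes_ratio",
    "UNRANKED_NONE",
    "MISSING_PREMATURE_DEATH",
    "UNRELIABLE_PD_NO_MORBIDITY",
    "UNRELIABLE_PD_LBW_NO_MORBIDITY",
]

COMPOSITE_COLUMNS = [
    "outcomes", "mortality", "morbidity",
    "factors", "health_behaviors", "clinical_care",
    "social_economic", "physical_environment",
]

UNRANKED_NONE = "none"
MISSING_PREMATURE_DEATH = "missing_premature_death"
UNRELIABLE_PD_NO_MORBIDITY = "unreliable_pd_no_morbidity"
UNRELIABLE_PD_LBW_NO_MORBIDITY = "unreliable_pd_lbw_no_morbidity"

PREMATURE_DEATH_ID = "premature_death"
LOW_BIRTHWEIGHT_ID = "low_birthweight"


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def _state_weights(
    std: StandardizedTable,
    catalog: MeasureCatalog,
) -> pd.DataFrame:
    """Per-state effective weight (percent of family) for each measure.

    A measure dropped for a state (fewer than two observed counties, e.g. a
    measure unavailable statewide) gets weight 0 there and the remaining
    weights of the same composite family are scaled proportionally so they
    still sum to 100, keeping the composite scale comparable across states.
    Measures absent from the table are treated as dropped everywhere.
    """
    cols = std.measure_ids
    states = std.dropped.index
    base = np.array([catalog[m].weight_pct for m in cols])
    families = [catalog[m].composite_family for m in cols]

    w = np.tile(base, (len(states), 1))
    w[std.dropped[cols].to_numpy()] = 0.0

    for family in (OUTCOMES, FACTORS):
        fam = np.array([f == family for f in families])
        # family total is 100 in a valid catalog; measures missing from the
        # table shrink the achievable total, so renormalize to the full 100
        if not fam.any():
            continue
        remaining = w[:, fam].sum(axis=1)
        factor = np.divide(100.0, remaining, out=np.zeros_like(remaining),
                           where=remaining > 0)
        w[:, fam] *= factor[:, None]
    return pd.DataFrame(w, index=states, columns=cols)


def compute_composites(
    std: StandardizedTable,
    catalog: MeasureCatalog | None = None,
) -> pd.DataFrame:
    """Weighted sums of z-scores: eight composite scores per county.

    Each composite is sum over its measures of (weight_pct / 100) x z with
    per-state renormalized weights where a measure is dropped statewide.
    Family columns are computed as the sums of their component columns, so
    ``outcomes == mortality + morbidity`` and ``factors`` equals the sum of
    the four factor components exactly.
    """
    if catalog is None:
        catalog = load_default_catalog()
    unknown = [m for m in std.measure_ids if m not in catalog.measure_ids]
    if unknown:
        raise ValueError(f"standardized measures not in catalog: {unknown}")

    cols = std.measure_ids
    weights = _state_weights(std, catalog)
    state_row = weights.index.get_indexer(std.state.to_numpy())
    per_county_w = weights.to_numpy()[state_row]
    contrib = std.z.to_numpy() * per_county_w / 100.0

    data = np.zeros((len(std.z), len(COMPOSITE_COLUMNS)))
    out = pd.DataFrame(data, index=std.z.index, columns=COMPOSITE_COLUMNS)
    col_pos = {c: i for i, c in enumerate(cols)}
    for comp in COMPONENTS:
        pos = [col_pos[m.measure_id] for m in catalog.component_measures(comp)
               if m.measure_id in col_pos]
        if pos:
            out[comp] = contrib[:, pos].sum(axis=1)
    out["outcomes"] = out["mortality"] + out["morbidity"]
    out["factors"] = (out["health_behaviors"] + out["clinical_care"]
                      + out["social_economic"] + out["physical_environment"])
    return out


# ---------------------------------------------------------------------------
# unranked rules
# ---------------------------------------------------------------------------

def determine_unranked(
    table: CountyMeasureTable,
    std: StandardizedTable,
    catalog: MeasureCatalog | None = None,
) -> pd.DataFrame:
    """Flag counties that cannot be ranked, with the first matching reason.

    A county is unranked iff:

    1. its premature-death value is missing; or
    2. its premature-death value is unreliable and no morbidity measure
       (poor/fair health, poor physical health days, poor mental health
       days, low birthweight) is present; or
    3. its premature-death and low-birthweight values are both unreliable
       and no other morbidity measure is present.

    Catalogs without a premature-death measure rank every county.
    Returns a frame with boolean ``unranked`` and string ``unranked_reason``.
    """
    if catalog is None:
        catalog = load_default_catalog()
    idx = table.fips
    unranked = pd.Series(False, index=idx)
    reason = pd.Series(UNRANKED_NONE, index=idx, dtype=object)

    if PREMATURE_DEATH_ID in table.values.columns:
        morbidity_ids = [m.measure_id
                         for m in catalog.component_measures("morbidity")
                         if m.measure_id in table.values.columns]
        other_morbidity = [m for m in morbidity_ids if m != LOW_BIRTHWEIGHT_ID]

        pd_missing = table.values[PREMATURE_DEATH_ID].isna()
        pd_unrel = std.unreliable.get(
            PREMATURE_DEATH_ID, pd.Series(False, index=idx))

        present = table.values[morbidity_ids].notna() if morbidity_ids \
            else pd.DataFrame(index=idx)
        any_morbidity = present.any(axis=1) if morbidity_ids \
            else pd.Series(False, index=idx)
        any_other = present[other_morbidity].any(axis=1) if other_morbidity \
            else pd.Series(False, index=idx)

        if LOW_BIRTHWEIGHT_ID in table.values.columns:
            lbw_present = table.values[LOW_BIRTHWEIGHT_ID].notna()
            lbw_unrel = std.unreliable.get(
                LOW_BIRTHWEIGHT_ID, pd.Series(False, index=idx))
        else:
            lbw_present = pd.Series(False, index=idx)
            lbw_unrel = pd.Series(False, index=idx)

        rule1 = pd_missing
        rule2 = ~rule1 & pd_unrel & ~any_morbidity
        rule3 = (~rule1 & ~rule2 & pd_unrel
                 & lbw_present & lbw_unrel & ~any_other)

        reason[rule3] = UNRELIABLE_PD_LBW_NO_MORBIDITY
        reason[rule2] = UNRELIABLE_PD_NO_MORBIDITY
        reason[rule1] = MISSING_PREMATURE_DEATH
        unranked = rule1 | rule2 | rule3

    return pd.DataFrame({"unranked": unranked, "unranked_reason": reason})


# ---------------------------------------------------------------------------
# ranking and quartiles
# ---------------------------------------------------------------------------

def rank_within_state(
    scores: pd.DataFrame,
    state: pd.Series,
    unranked: pd.Series | None = None,
) -> pd.DataFrame:
    """Competition-rank each composite ascending within each state.

    The lowest composite score (best health) gets rank 1; ties share the
    minimal rank and the next rank is skipped.  Unranked counties are
    excluded and get missing ranks (nullable integers).
    """
    if unranked is None:
        unranked = pd.Series(False, index=scores.index)
    keep = np.broadcast_to(~unranked.to_numpy()[:, None], scores.shape)
    masked = scores.where(keep)
    ranks = masked.groupby(state.to_numpy()).rank(method="min")
    return ranks.astype("Int64")


def assign_quartiles(
    ranks: pd.Series,
    state: pd.Series,
) -> pd.Series:
    """Quartile q = ceil(4 * rank / n_ranked), clamped to 1..4.

    ``n_ranked`` counts the ranked counties of the county's state; unranked
    counties (missing rank) get a missing quartile.  With n_ranked = 1 the
    single county falls in quartile 4 (ceil(4/1)).
    """
    n_ranked = ranks.notna().groupby(state.to_numpy()).transform("sum")
    q = np.ceil(4.0 * ranks.astype(float) / n_ranked.astype(float))
    q = q.clip(1, 4)
    return pd.Series(q, index=ranks.index).astype("Int64")


@dataclass
class RankingResult:
    """Per-county composite scores, the eight ranks, quartiles and flags."""

    scores: pd.DataFrame              # county x eight composites
    ranks: pd.DataFrame               # county x eight ranks (Int64, NA unranked)
    quartile_outcomes: pd.Series      # Int64 1..4
    quartile_factors: pd.Series       # Int64 1..4
    unranked: pd.Series               # bool
    unranked_reason: pd.Series        # str
    state: pd.Series

    @property
    def fips(self) -> pd.Index:
        return self.scores.index

    @property
    def n_ranked(self) -> int:
        return int((~self.unranked).sum())

    def to_frame(self) -> pd.DataFrame:
        """One row per county: state, scores, ranks, quartiles, flags."""
        out = pd.DataFrame({"state": self.state})
        for c in COMPOSITE_COLUMNS:
            out[f"score_{c}"] = self.scores[c]
        for c in COMPOSITE_COLUMNS:
            out[f"rank_{c}"] = self.ranks[c]
        out["quartile_outcomes"] = self.quartile_outcomes
        out["quartile_factors"] = self.quartile_factors
        out["unranked"] = self.unranked
        out["unranked_reason"] = self.unranked_reason
        out.index.name = "fips"
        return out


def rank_counties(
    table: CountyMeasureTable,
    std: StandardizedTable,
    catalog: MeasureCatalog | None = None,
) -> RankingResult:
    """Composites -> unranked rules -> eight ranks -> quartiles."""
    if catalog is None:
        catalog = load_default_catalog()
    scores = compute_composites(std, catalog)
    flags = determine_unranked(table, std, catalog)
    ranks = rank_within_state(scores, std.state, flags["unranked"])
    return RankingResult(
        scores=scores,
        ranks=ranks,
        quartile_outcomes=assign_quartiles(ranks["outcomes"], std.state),
        quartile_factors=assign_quartiles(ranks["factors"], std.state),
        unranked=flags["unranked"],
        unranked_reason=flags["unranked_reason"],
        state=std.state,
    )


# ---------------------------------------------------------------------------
# national benchmark
# ---------------------------------------------------------------------------

def national_benchmark(
    table: CountyMeasureTable,
    catalog: MeasureCatalog | None = None,
    options: RankingOptions | None = None,
    min_observed: int = 10,
) -> pd.Series:
    """Direction-aware best-10% boundary of each measure across counties.

    The benchmark is the 10th percentile of observed values when higher
    values are worse, the 90th when higher is better (linear interpolation
    between order statistics).  Measures with fewer than ``min_observed``
    observed counties get a missing benchmark.
    """
    if catalog is None:
        catalog = load_default_catalog()
    if options is None:
        options = RankingOptions()
    p = options.benchmark_percentile
    out = {}
    for m in table.values.columns:
        if m not in catalog.measure_ids:
            continue
        obs = table.values[m].dropna().to_numpy()
        if obs.size < min_observed:
            out[m] = np.nan
            continue
        pct = 100.0 - p if catalog[m].direction == HIGHER_IS_BETTER else p
        out[m] = float(np.percentile(obs, pct))
    s = pd.Series(out, name="benchmark")
    s.index.name = "measure_id"
    return s


# ---------------------------------------------------------------------------
# extremes comparison
# ---------------------------------------------------------------------------

def extremes_ratio(lh_mean: float, h_mean: float) -> float:
    """Least-healthy / healthy group-mean ratio, rounded to one decimal."""
    if h_mean == 0 or not math.isfinite(lh_mean) or not math.isfinite(h_mean):
        return float("nan")
    return float(np.round(lh_mean / h_mean, 1))


@dataclass
class ExtremesComparison:
    """Group means for the least-healthy vs healthiest counties per state.

    ``frame`` has one row per measure plus a ``population`` row; columns
    ``all``, ``least_healthy``, ``healthy``, ``others`` (unweighted group
    means) and ``ratio`` (least-healthy / healthy, one decimal).
    ``group`` labels each county LH / H / Others ('' = excluded).
    """

    frame: pd.DataFrame
    group: pd.Series
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_least_healthy(self) -> int:
        return self.counts.get("least_healthy", 0)

    @property
    def n_healthy(self) -> int:
        return self.counts.get("healthy", 0)


def compare_extremes(
    result: RankingResult,
    table: CountyMeasureTable,
    k: int = 5,
    min_counties_per_state: int = 10,
) -> ExtremesComparison:
    """Pool each state's k best- and k worst-outcome counties and compare.

    States with fewer than ``min_counties_per_state`` counties are excluded
    entirely.  Within each remaining state, ranked counties are ordered by
    outcomes rank (FIPS breaking ties); the first k form the healthy (H)
    group, the last k (disjoint from H) the least-healthy (LH) group, the
    rest the others group.  Group means are unweighted across counties over
    observed values; the LH/H ratio is rounded to one decimal.
    """
    state_sizes = table.state.value_counts()
    eligible = set(state_sizes.index[state_sizes >= min_counties_per_state])

    group = pd.Series("", index=table.fips, dtype=object)
    order = pd.DataFrame({
        "state": result.state.to_numpy(),
        "rank": result.ranks["outcomes"].astype(float).to_numpy(),
        "fips": result.fips,
    })
    order = order[order["state"].isin(eligible) & order["rank"].notna()]
    order = order.sort_values(["state", "rank", "fips"])

    for st, grp in order.groupby("state", sort=False):
        ids = grp["fips"].to_numpy()
        n = len(ids)
        h_ids = ids[:min(k, n)]
        lh_ids = ids[max(k, n - k):]
        group.loc[h_ids] = "healthy"
        group.loc[lh_ids] = "least_healthy"
        rest = ids[min(k, n):max(k, n - k)]
        group.loc[rest] = "others"

    included = group != ""
    cols = {"all": included}
    for label in ("least_healthy", "healthy", "others"):
        cols[label] = group == label

    aug = table.values.copy()
    aug["population"] = table.population.astype(float)
    rows = {}
    for label, mask in cols.items():
        rows[label] = aug[mask.to_numpy()].mean()
    frame = pd.DataFrame(rows)
    frame["ratio"] = [
        extremes_ratio(lh, h) for lh, h in
        zip(frame["least_healthy"], frame["healthy"])
    ]
    frame.index.name = "measure_id"

    counts = {label: int(mask.sum()) for label, mask in cols.items()}
    return ExtremesComparison(frame=frame, group=group, counts=counts)
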