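"""Independent brute-force oracles: plain per-cell Python loops.

Deliberately naive re-implementations of standardization, weighted
aggregation and ranking, kept free of numpy vectorization and of the
package's own code paths, so pipeline results can be checked against them.
"""

from __future__ import annotations

import math


def naive_zscores(table, catalog, *, ddof=1, rse_threshold=0.20,
                  truncation_population=20_000, z_max=3.0):
    """Per-cell loop standardization: dict (fips, measure) -> z."""
    cols = [m for m in catalog.measure_ids if m in table.values.columns]
    fips = list(table.fips)
    state_of = dict(zip(fips, table.state))
    pop_of = dict(zip(fips, table.population))
    states = sorted(set(state_of.values()))

    def observed(f, m):
        v = table.values.at[f, m]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return False
        if m in table.standard_errors.columns:
            se = table.standard_errors.at[f, m]
            if se is not None and not math.isnan(se) \
                    and se > rse_threshold * abs(v):
                return False
        return True

    z = {}
    for m in cols:
        for st in states:
            members = [f for f in fips if state_of[f] == st]
            obs = [f for f in members if observed(f, m)]
            n = len(obs)
            if n >= 2:
                mean = sum(table.values.at[f, m] for f in obs) / n
                ss = sum((table.values.at[f, m] - mean) ** 2 for f in obs)
                sd = math.sqrt(ss / (n - ddof)) if n - ddof > 0 else 0.0
            else:
                mean, sd = 0.0, 0.0
            sd_floor = 1e-12 * max(1.0, abs(mean))  # round-off = no variance
            for f in members:
                if n < 2 or sd <= sd_floor or not observed(f, m):
                    val = 0.0
                else:
                    val = (table.values.at[f, m] - mean) / sd
                if catalog[m].direction == "higher_is_better":
                    val = -val
                if pop_of[f] <= truncation_population:
                    val = min(max(val, -z_max), z_max)
                z[(f, m)] = val
    return z


def naive_composites(table, catalog, z):
    """Loop-based weighted sums with per-state family renormalization."""
    cols = [m for m in catalog.measure_ids if m in table.values.columns]
    fips = list(table.fips)
    state_of = dict(zip(fips, table.state))
    states = sorted(set(state_of.values()))

    # state-measure drop: fewer than 2 observed counties
    import math as _m

    def observed(f, m):
        v = table.values.at[f, m]
        if isinstance(v, float) and _m.isnan(v):
            return False
        if m in table.standard_errors.columns:
            se = table.standard_errors.at[f, m]
            if se is not None and not _m.isnan(se) and se > 0.20 * abs(v):
                return False
        return True

    dropped = {}
    for st in states:
        members = [f for f in fips if state_of[f] == st]
        for m in cols:
            n = sum(1 for f in members if observed(f, m))
            dropped[(st, m)] = n < 2
    absent = [m for m in catalog.measure_ids if m not in cols]

    scores = {}
    for f in fips:
        st = state_of[f]
        comp = {c: 0.0 for c in ("mortality", "morbidity", "health_behaviors",
                                 "clinical_care", "social_economic",
                                 "physical_environment")}
        for family in ("outcomes", "factors"):
            fam_measures = [m for m in catalog.family_measures(family)]
            live = [m for m in fam_measures
                    if m.measure_id not in absent
                    and not dropped[(st, m.measure_id)]]
            total_w = sum(m.weight_pct for m in live)
            if total_w <= 0:
                continue
            for m in live:
                w = m.weight_pct * 100.0 / total_w
                comp[m.component] += (w / 100.0) * z[(f, m.measure_id)]
        comp["outcomes"] = comp["mortality"] + comp["morbidity"]
        comp["factors"] = (comp["health_behaviors"] + comp["clinical_care"]
                           + comp["social_economic"]
                           + comp["physical_environment"])
        scores[f] = comp
    return scores


def competition_ranks(values):
    """Sort-and-assign competition ranking: rank = 1 + #strictly smaller."""
    return [1 + sum(1 for w in values if w < v) for v in values]


def quartile_of(rank, n_ranked):
    """Direct evaluation of the quartile rule."""
    q = math.ceil(4 * rank / n_ranked)
    return min(max(q, 1), 4)
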