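import numpy as np
import pandas as pd
import pytest

from countyrank import (CountyMeasureTable, SimulationConfig,
                        compute_composites, compute_zscores,
                        determine_unranked, rank_within_state,
                        assign_quartiles, rank_counties, national_benchmark,
                        compare_extremes, extremes_ratio, generate_counties,
                        COMPOSITE_COLUMNS)
from countyrank.standardize import StandardizedTable
from _oracles import competition_ranks, quartile_of, naive_composites, \
    naive_zscores


def make_std(catalog, z_values, n=4, state="AA"):
    """StandardizedTable with explicit z for some measures, zero elsewhere."""
    fips = pd.Index([f"{i:05d}" for i in range(n)], name="fips")
    z = pd.DataFrame(0.0, index=fips, columns=catalog.measure_ids)
    for m, vals in z_values.items():
        z[m] = vals
    false = pd.DataFrame(False, index=fips, columns=catalog.measure_ids)
    states = pd.Series([state] * n, index=fips)
    dropped = pd.DataFrame(False, index=pd.Index([state], name="state"),
                           columns=catalog.measure_ids)
    return StandardizedTable(
        z=z, imputed=false.copy(), truncated=false.copy(),
        unreliable=false.copy(), dropped=dropped, state=states,
        population=pd.Series(50_000, index=fips), z_untruncated=z.copy())


class TestComputeComposites:
    def test_premature_death_is_half_the_outcomes_score(self, catalog):
        std = make_std(catalog, {"premature_death": 1.0})
        scores = compute_composites(std, catalog)
        np.testing.assert_allclose(scores["outcomes"], 0.5)
        np.testing.assert_allclose(scores["mortality"], 0.5)
        np.testing.assert_allclose(scores["morbidity"], 0.0)

    def test_all_zero_z_gives_zero_composites(self, catalog):
        std = make_std(catalog, {})
        scores = compute_composites(std, catalog)
        assert (scores == 0.0).all().all()

    def test_adult_smoking_weight_in_factors(self, catalog):
        std = make_std(catalog, {"adult_smoking": 2.0})
        scores = compute_composites(std, catalog)
        np.testing.assert_allclose(scores["factors"], 0.2)
        np.testing.assert_allclose(scores["health_behaviors"], 0.2)
        np.testing.assert_allclose(scores["outcomes"], 0.0)

    def test_family_scores_partition_into_components(self, catalog):
        table, _ = generate_counties(
            SimulationConfig(seed=9, n_states=4, counties_per_state=15),
            catalog)
        std = compute_zscores(table, catalog)
        scores = compute_composites(std, catalog)
        np.testing.assert_allclose(
            scores["outcomes"], scores["mortality"] + scores["morbidity"],
            atol=1e-12)
        np.testing.assert_allclose(
            scores["factors"],
            scores[["health_behaviors", "clinical_care", "social_economic",
                    "physical_environment"]].sum(axis=1), atol=1e-12)

    def test_statewide_missing_measure_renormalizes_weights(self, catalog):
        # all factor z = 1 in both states; one state lacks air pollution
        # entirely.  Renormalized weights keep its factors score at 1.0.
        n = 6
        fips = [f"{i:05d}" for i in range(2 * n)]
        df = pd.DataFrame({"fips": fips,
                           "state": ["AA"] * n + ["BB"] * n,
                           "population": 50_000})
        rng = np.random.default_rng(0)
        for m in catalog.measure_ids:
            df[m] = rng.normal(size=2 * n)
        df.loc[df["state"] == "BB", "air_pollution"] = np.nan
        table = CountyMeasureTable.from_dataframe(df)
        std = compute_zscores(table, catalog)
        assert std.dropped.loc["BB", "air_pollution"]

        z_one = std.z.copy()
        z_one.loc[:, :] = 1.0
        z_one.loc[:, "air_pollution"] = [1.0] * n + [0.0] * n
        std_one = StandardizedTable(
            z=z_one, imputed=std.imputed, truncated=std.truncated,
            unreliable=std.unreliable, dropped=std.dropped, state=std.state,
            population=std.population, z_untruncated=z_one)
        scores = compute_composites(std_one, catalog)
        np.testing.assert_allclose(scores["factors"], 1.0, atol=1e-12)
        np.testing.assert_allclose(scores["outcomes"], 1.0, atol=1e-12)

    def test_unknown_measure_rejected(self, catalog):
        std = make_std(catalog, {})
        std.z["mystery"] = 1.0
        with pytest.raises(ValueError, match="mystery"):
            compute_composites(std, catalog)


class TestDetermineUnranked:
    @staticmethod
    def build(catalog, **overrides):
        """Five-county state; county 00000 gets the overridden cells."""
        n = 5
        df = pd.DataFrame({"fips": [f"{i:05d}" for i in range(n)],
                           "state": "AA", "population": 50_000})
        rng = np.random.default_rng(1)
        for m in catalog.measure_ids:
            df[m] = rng.normal(loc=100.0, size=n)
            if catalog[m].has_standard_error:
                df[m + "_se"] = 1.0
        for col, val in overrides.items():
            df.loc[0, col] = val
        table = CountyMeasureTable.from_dataframe(df)
        std = compute_zscores(table, catalog)
        return determine_unranked(table, std, catalog)

    def test_missing_premature_death_unranks(self, catalog):
        flags = self.build(catalog, premature_death=np.nan)
        assert flags.loc["00000", "unranked"]
        assert flags.loc["00000", "unranked_reason"] == \
            "missing_premature_death"
        assert not flags["unranked"].iloc[1:].any()

    def test_unreliable_pd_with_morbidity_still_ranked(self, catalog):
        flags = self.build(catalog, premature_death_se=1e6)
        assert not flags.loc["00000", "unranked"]

    def test_unreliable_pd_no_morbidity_unranks(self, catalog):
        flags = self.build(catalog, premature_death_se=1e6,
                           poor_fair_health=np.nan, poor_physical_days=np.nan,
                           poor_mental_days=np.nan, low_birthweight=np.nan)
        assert flags.loc["00000", "unranked"]
        assert flags.loc["00000", "unranked_reason"] == \
            "unreliable_pd_no_morbidity"

    def test_unreliable_pd_and_lbw_no_other_morbidity_unranks(self, catalog):
        flags = self.build(catalog, premature_death_se=1e6,
                           low_birthweight_se=1e6, poor_fair_health=np.nan,
                           poor_physical_days=np.nan, poor_mental_days=np.nan)
        assert flags.loc["00000", "unranked"]
        assert flags.loc["00000", "unranked_reason"] == \
            "unreliable_pd_lbw_no_morbidity"


class TestRankWithinState:
    def test_competition_ranking_with_tie(self):
        fips = pd.Index(list("abcd"))
        scores = pd.DataFrame({"outcomes": [0.2, -1.0, 0.2, 0.5]}, index=fips)
        state = pd.Series("AA", index=fips)
        ranks = rank_within_state(scores, state)
        assert ranks["outcomes"].tolist() == [2, 1, 2, 4]

    def test_distinct_scores_rank_as_sorting_permutation(self, rng):
        fips = pd.Index([f"{i:03d}" for i in range(9)])
        scores = pd.DataFrame({"outcomes": rng.normal(size=9)}, index=fips)
        state = pd.Series("AA", index=fips)
        ranks = rank_within_state(scores, state)["outcomes"]
        expected = scores["outcomes"].rank().astype(int)
        assert (ranks == expected).all()
        assert sorted(ranks) == list(range(1, 10))

    def test_single_ranked_county_gets_rank_one(self):
        fips = pd.Index(["a", "b"])
        scores = pd.DataFrame({"outcomes": [0.3, 0.1]}, index=fips)
        state = pd.Series("AA", index=fips)
        unranked = pd.Series([False, True], index=fips)
        ranks = rank_within_state(scores, state, unranked)["outcomes"]
        assert ranks.iloc[0] == 1
        assert pd.isna(ranks.iloc[1])

    def test_matches_sort_based_oracle(self, rng):
        fips = pd.Index([f"{i:03d}" for i in range(12)])
        scores = pd.DataFrame(
            {"outcomes": rng.choice([0.1, 0.2, 0.3, 0.4], size=12)},
            index=fips)
        state = pd.Series(["AA"] * 6 + ["BB"] * 6, index=fips)
        ranks = rank_within_state(scores, state)["outcomes"]
        for st in ("AA", "BB"):
            vals = scores.loc[state == st, "outcomes"].tolist()
            assert ranks[state == st].tolist() == competition_ranks(vals)


class TestAssignQuartiles:
    def test_eight_counties_split_evenly(self):
        fips = pd.Index([f"{i}" for i in range(8)])
        ranks = pd.Series(range(1, 9), index=fips, dtype="Int64")
        state = pd.Series("AA", index=fips)
        q = assign_quartiles(ranks, state)
        assert q.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_boundary_at_72_counties(self):
        fips = pd.Index([f"{i:03d}" for i in range(72)])
        ranks = pd.Series(range(1, 73), index=fips, dtype="Int64")
        state = pd.Series("AA", index=fips)
        q = assign_quartiles(ranks, state)
        assert q.iloc[17] == 1   # rank 18
        assert q.iloc[18] == 2   # rank 19

    def test_single_county_lands_in_quartile_four(self):
        fips = pd.Index(["x"])
        q = assign_quartiles(pd.Series([1], index=fips, dtype="Int64"),
                             pd.Series(["AA"], index=fips))
        assert q.iloc[0] == 4

    @pytest.mark.parametrize("n", [3, 7, 25])
    def test_matches_direct_ceiling_rule(self, n):
        fips = pd.Index([f"{i:03d}" for i in range(n)])
        ranks = pd.Series(range(1, n + 1), index=fips, dtype="Int64")
        state = pd.Series("AA", index=fips)
        q = assign_quartiles(ranks, state)
        assert q.tolist() == [quartile_of(r, n) for r in range(1, n + 1)]


class TestNationalBenchmark:
    def test_tenth_percentile_for_adverse_measure(self, tiny_catalog):
        from conftest import make_table
        table = make_table(["AA"], [list(map(float, range(1, 101)))])
        bm = national_benchmark(table, tiny_catalog)
        assert bm["premature_death"] == pytest.approx(10.9)

    def test_ninetieth_percentile_for_reverse_coded(self, tiny_catalog):
        df = pd.DataFrame({
            "fips": [f"{i:05d}" for i in range(100)],
            "state": "AA", "population": 50_000,
            "some_college": list(map(float, range(1, 101)))})
        table = CountyMeasureTable.from_dataframe(df)
        bm = national_benchmark(table, tiny_catalog)
        assert bm["some_college"] == pytest.approx(90.1)

    def test_constant_column_benchmark_is_the_constant(self, tiny_catalog):
        from conftest import make_table
        table = make_table(["AA"], [[7.0] * 12])
        bm = national_benchmark(table, tiny_catalog)
        assert bm["premature_death"] == 7.0

    def test_too_few_observations_unavailable(self, tiny_catalog):
        from conftest import make_table
        table = make_table(["AA"], [[1.0, 2.0, 3.0]])
        bm = national_benchmark(table, tiny_catalog)
        assert np.isnan(bm["premature_death"])


class TestCompareExtremes:
    def test_published_style_ratio_from_group_means(self):
        assert extremes_ratio(10_862, 5_113) == 2.1
        assert extremes_ratio(7.0, 7.0) == 1.0

    def test_small_states_excluded_and_groups_sized(self, catalog):
        counts = [12, 15, 20, 4]  # one state below the 10-county cut
        table, _ = generate_counties(
            SimulationConfig(seed=4, n_states=4, counties_per_state=counts,
                             missing_rate=0.0), catalog)
        std = compute_zscores(table, catalog)
        result = rank_counties(table, std, catalog)
        cmp_ = compare_extremes(result, table, k=5, min_counties_per_state=10)
        assert cmp_.n_least_healthy == 15
        assert cmp_.n_healthy == 15
        assert cmp_.counts["all"] == 47
        assert cmp_.counts["others"] == 47 - 30
        # excluded state's counties belong to no group
        assert (cmp_.group[table.state == "AD"] == "").all()

    def test_groups_disjoint_when_fewer_than_2k_ranked(self, catalog):
        table, _ = generate_counties(
            SimulationConfig(seed=4, n_states=1, counties_per_state=7,
                             missing_rate=0.0), catalog)
        std = compute_zscores(table, catalog)
        result = rank_counties(table, std, catalog)
        cmp_ = compare_extremes(result, table, k=5, min_counties_per_state=7)
        assert cmp_.n_healthy == 5
        assert cmp_.n_least_healthy == 2
        assert cmp_.counts["others"] == 0

    def test_least_healthy_group_has_worse_premature_death(self, catalog):
        table, _ = generate_counties(
            SimulationConfig(seed=6, n_states=6, counties_per_state=25),
            catalog)
        std = compute_zscores(table, catalog)
        result = rank_counties(table, std, catalog)
        cmp_ = compare_extremes(result, table)
        row = cmp_.frame.loc["premature_death"]
        assert row["least_healthy"] > row["healthy"]
        assert row["ratio"] > 1.0


class TestPipelineOracle:
    def test_scores_match_naive_loops_on_small_tables(self, catalog):
        for seed in range(3):
            table, _ = generate_counties(
                SimulationConfig(seed=seed, n_states=3,
                                 counties_per_state=(2, 6)), catalog)
            std = compute_zscores(table, catalog)
            scores = compute_composites(std, catalog)
            z = naive_zscores(table, catalog)
            expected = naive_composites(table, catalog, z)
            for f in table.fips:
                for c in COMPOSITE_COLUMNS:
                    assert scores.at[f, c] == pytest.approx(
                        expected[f][c], abs=1e-10), (f, c)
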