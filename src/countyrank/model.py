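"""Model/results interface over the full scoring-and-ranking pipeline.

:class:`CountyHealthRankings` is built from a county measure table (a
DataFrame, a CSV, or a :class:`~countyrank.io.CountyMeasureTable`) plus a
measure catalog; ``fit()`` runs standardization, composites, the unranked
rules, ranking and quartiles, and returns a :class:`RankingsResults`
carrying the per-county scores, ranks, quartiles and data-quality
diagnostics, with ``summary()``, national benchmarks and the
least-healthy-vs-healthiest comparison hanging off it.

Example
-------
>>> from countyrank import CountyHealthRankings, SimulationConfig
>>> from countyrank.synthetic import generate_counties
>>> table, truth = generate_counties(SimulationConfig(seed=7))
>>> res = CountyHealthRankings(table).fit()
>>> res.ranks["outcomes"].head()
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalog import MeasureCatalog, load_default_catalog, validate_catalog
from .composite import (RankingResult, ExtremesComparison, rank_counties,
                        national_benchmark, compare_extremes,
                        COMPOSITE_COLUMNS)
from .config import RankingOptions
from .io import CountyMeasureTable, read_measure_table, TableValidationError
from .standardize import StandardizedTable, compute_zscores

__all__ = ["CountyHealthRankings", "RankingsResults"]


class CountyHealthRankings:
    """Within-state composite health scoring model for a county panel.

    Parameters
    ----------
    table
        The county x measure data (raw values, SEs, populations, states).
    catalog
        Measure hierarchy and weights; default is the 2014 34-measure set.
    options
        Methodological thresholds (SD flavor, truncation, RSE cut, ...).
    """

    def __init__(
        self,
        table: CountyMeasureTable,
        catalog: MeasureCatalog | None = None,
        options: RankingOptions | None = None,
    ) -> None:
        self.catalog = catalog if catalog is not None else load_default_catalog()
        report = validate_catalog(self.catalog)
        if not report.valid:
            raise ValueError(f"invalid catalog:\n{report}")
        problems = table.validate(self.catalog)
        if problems:
            raise TableValidationError(problems)
        self.table = table
        self.options = options if options is not None else RankingOptions()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        catalog: MeasureCatalog | None = None,
        options: RankingOptions | None = None,
    ) -> "CountyHealthRankings":
        """Build from a flat frame: fips, state, population, measures[, _se]."""
        cat = catalog if catalog is not None else load_default_catalog()
        table = CountyMeasureTable.from_dataframe(df, catalog=cat)
        return cls(table, cat, options)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        catalog: MeasureCatalog | None = None,
        options: RankingOptions | None = None,
    ) -> "CountyHealthRankings":
        cat = catalog if catalog is not None else load_default_catalog()
        table = read_measure_table(path, cat)
        return cls(table, cat, options)

    @property
    def n_counties(self) -> int:
        return self.table.n_counties

    @property
    def n_states(self) -> int:
        return int(self.table.state.nunique())

    def fit(self) -> "RankingsResults":
        """Standardize, aggregate, apply unranked rules, rank, quartile."""
        std = compute_zscores(self.table, self.catalog, self.options)
        ranking = rank_counties(self.table, std, self.catalog)
        return RankingsResults(self, std, ranking)


@dataclass
class RankingsResults:
    """Fitted rankings: scores, ranks, quartiles, flags and diagnostics."""

    model: CountyHealthRankings
    standardized: StandardizedTable
    ranking: RankingResult

    # -- primary outputs ---------------------------------------------------
    @property
    def scores(self) -> pd.DataFrame:
        """County x eight composite scores (weighted SD units)."""
        return self.ranking.scores

    @property
    def ranks(self) -> pd.DataFrame:
        """County x eight within-state ranks (1 = best health)."""
        return self.ranking.ranks

    @property
    def quartile_outcomes(self) -> pd.Series:
        return self.ranking.quartile_outcomes

    @property
    def quartile_factors(self) -> pd.Series:
        return self.ranking.quartile_factors

    @property
    def unranked(self) -> pd.Series:
        return self.ranking.unranked

    @property
    def unranked_reason(self) -> pd.Series:
        return self.ranking.unranked_reason

    def to_frame(self) -> pd.DataFrame:
        """One row per county: state, scores, ranks, quartiles, flags."""
        return self.ranking.to_frame()

    # -- diagnostics -------------------------------------------------------
    def diagnostics(self) -> dict[str, float]:
        """Counts of imputed/truncated/unreliable cells and unranked counties."""
        std = self.standardized
        n = self.model.n_counties
        n_unranked = int(self.unranked.sum())
        return {
            "n_counties": n,
            "n_states": self.model.n_states,
            "n_measures": len(std.measure_ids),
            "cells_imputed": int(std.imputed.to_numpy().sum()),
            "cells_truncated": int(std.truncated.to_numpy().sum()),
            "cells_unreliable": int(std.unreliable.to_numpy().sum()),
            "state_measures_dropped": int(std.dropped.to_numpy().sum()),
            "n_unranked": n_unranked,
            "pct_unranked": 100.0 * n_unranked / n if n else 0.0,
        }

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        d = self.diagnostics()
        cat = self.model.catalog
        lines = [
            "County Health Rankings Results",
            "=" * 46,
            f"{'Catalog:':<28}{cat.name} ({len(cat)} measures)",
            f"{'Counties:':<28}{d['n_counties']}",
            f"{'States:':<28}{d['n_states']}",
            f"{'SD flavor:':<28}{self.model.options.sd_flavor}",
            "-" * 46,
            f"{'Imputed cells:':<28}{d['cells_imputed']}",
            f"{'Truncated cells:':<28}{d['cells_truncated']}",
            f"{'Unreliable cells:':<28}{d['cells_unreliable']}",
            f"{'State-measures dropped:':<28}{d['state_measures_dropped']}",
            f"{'Unranked counties:':<28}{d['n_unranked']} "
            f"({d['pct_unranked']:.1f}%)",
            "-" * 46,
            "Composite score distribution (ranked counties):",
        ]
        ranked = self.scores[~self.unranked]
        desc = ranked[COMPOSITE_COLUMNS].describe().loc[["mean", "std",
                                                         "min", "max"]]
        lines.append(desc.round(4).to_string())
        return "\n".join(lines)

    # -- derived analyses --------------------------------------------------
    def benchmarks(self, min_observed: int = 10) -> pd.Series:
        """National best-10% benchmark per measure (direction-aware)."""
        return national_benchmark(self.model.table, self.model.catalog,
                                  self.model.options, min_observed)

    def compare_extremes(
        self,
        k: int | None = None,
        min_counties_per_state: int | None = None,
    ) -> ExtremesComparison:
        """Pool each state's k healthiest / least-healthy counties and compare."""
        opts = self.model.options
        return compare_extremes(
            self.ranking, self.model.table,
            k=k if k is not None else opts.extremes_k,
            min_counties_per_state=(
                min_counties_per_state if min_counties_per_state is not None
                else opts.extremes_min_counties),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the per-county results table (scores at 6 decimals)."""
        self.to_frame().to_csv(path, float_format="%.6f")
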