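"""County measure table container and CSV readers/writers.

The canonical input is one row per county::

    fips,state,population,<measure_id>[,<measure_id>_se],...

FIPS codes are kept as zero-padded text (a county identifier, never a
number), empty fields are missing values, and ``_se``-suffixed columns hold
the standard errors of the paired measure where the catalog says the measure
carries one.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MeasureCatalog, load_default_catalog

__all__ = [
    "CountyMeasureTable",
    "TableValidationError",
    "read_measure_table",
    "write_measure_table",
]

_SE_SUFFIX = "_se"


class TableValidationError(ValueError):
    """Raised when an input table violates its contract; lists all defects."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid county measure table:\n"
                         + "\n".join(f"- {p}" for p in self.problems))


@dataclass
class CountyMeasureTable:
    """Raw county values, standard errors, populations and state membership.

    Attributes
    ----------
    counties
        DataFrame indexed by FIPS with columns ``state`` (2-character code)
        and ``population`` (positive resident count).
    values
        County x measure matrix of raw values; NaN marks missing.
    standard_errors
        County x measure matrix of standard errors for the SE-bearing
        measures; NaN where absent.
    """

    counties: pd.DataFrame
    values: pd.DataFrame
    standard_errors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.standard_errors.empty:
            self.standard_errors = pd.DataFrame(index=self.values.index)

    # -- convenience -------------------------------------------------------
    @property
    def fips(self) -> pd.Index:
        return self.counties.index

    @property
    def state(self) -> pd.Series:
        return self.counties["state"]

    @property
    def population(self) -> pd.Series:
        return self.counties["population"]

    @property
    def n_counties(self) -> int:
        return len(self.counties)

    @property
    def measure_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self, catalog: MeasureCatalog | None = None) -> list[str]:
        """Return a list of contract violations (empty list = valid)."""
        problems: list[str] = []
        if self.counties.index.has_duplicates:
            dupes = self.counties.index[
                self.counties.index.duplicated()].unique().tolist()
            problems.append(f"duplicate FIPS codes: {dupes}")
        if self.counties["state"].isna().any():
            bad = self.counties.index[self.counties["state"].isna()].tolist()
            problems.append(f"counties without a state: {bad}")
        pop = self.counties["population"]
        if (pop.isna() | (pop <= 0)).any():
            bad = self.counties.index[pop.isna() | (pop <= 0)].tolist()
            problems.append(f"non-positive or missing population: {bad}")
        if not self.values.index.equals(self.counties.index):
            problems.append("values matrix index does not match county index")
        if catalog is not None:
            unknown = [c for c in self.values.columns
                       if c not in catalog.measure_ids]
            if unknown:
                problems.append(f"value columns not in catalog: {unknown}")
        for col in self.standard_errors.columns:
            se = self.standard_errors[col]
            if (se.dropna() < 0).any():
                bad = se.index[se < 0].tolist()
                problems.append(f"negative standard errors in {col}: {bad}")
        return problems

    # -- dataframe round trip ---------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Flatten to the canonical single-frame layout (measure, measure_se)."""
        out = self.counties.copy()
        for m in self.values.columns:
            out[m] = self.values[m]
            if m in self.standard_errors.columns:
                out[m + _SE_SUFFIX] = self.standard_errors[m]
        out.index.name = "fips"
        return out

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        catalog: MeasureCatalog | None = None,
    ) -> "CountyMeasureTable":
        """Build a table from a flat frame with fips/state/population columns.

        ``fips`` may be the index or a column; it is normalised to
        zero-padded 5-character text.
        """
        df = df.copy()
        if "fips" in df.columns:
            df = df.set_index("fips")
        df.index = df.index.astype(str).str.zfill(5)
        df.index.name = "fips"

        missing_cols = [c for c in ("state", "population") if c not in df.columns]
        if missing_cols:
            raise TableValidationError(
                [f"required column missing: {c!r}" for c in missing_cols])

        measure_cols = [c for c in df.columns
                        if c not in ("state", "population")
                        and not c.endswith(_SE_SUFFIX)]
        if catalog is not None:
            measure_cols = [c for c in measure_cols if c in catalog.measure_ids]

        counties = df[["state", "population"]].copy()
        counties["state"] = counties["state"].astype(str)
        counties["population"] = pd.to_numeric(
            counties["population"], errors="coerce")

        problems: list[str] = []
        values = pd.DataFrame(index=df.index)
        ses = pd.DataFrame(index=df.index)
        for c in measure_cols:
            col = pd.to_numeric(df[c], errors="coerce")
            bad = df.index[df[c].notna() & col.isna()
                           & (df[c].astype(str).str.strip() != "")]
            if len(bad):
                problems.append(f"non-numeric value in column {c!r} for "
                                f"counties {bad.tolist()}")
            values[c] = col.astype(float)
            se_col = c + _SE_SUFFIX
            if se_col in df.columns:
                ses[c] = pd.to_numeric(df[se_col], errors="coerce").astype(float)
        if problems:
            raise TableValidationError(problems)

        table = cls(counties=counties, values=values, standard_errors=ses)
        return table


def read_measure_table(
    path: str | Path | _io.TextIOBase,
    catalog: MeasureCatalog | None = None,
    *,
    strict: bool = True,
) -> CountyMeasureTable:
    """Read a county measure CSV, validating against a catalog.

    Unknown columns are reported as warnings (returned table simply omits
    them); structural defects (missing required columns, duplicate FIPS,
    non-positive population, negative SEs) raise
    :class:`TableValidationError` listing every defect at once.
    """
    import warnings

    if catalog is None:
        catalog = load_default_catalog()
    df = pd.read_csv(path, dtype={"fips": str, "state": str})
    if "fips" not in df.columns:
        raise TableValidationError(["required column missing: 'fips'"])

    known = set(catalog.measure_ids)
    unknown = [c for c in df.columns
               if c not in ("fips", "state", "population")
               and c.rstrip() not in known
               and not (c.endswith(_SE_SUFFIX) and c[:-len(_SE_SUFFIX)] in known)]
    if unknown:
        warnings.warn(f"ignoring columns not in catalog: {unknown}",
                      stacklevel=2)

    table = CountyMeasureTable.from_dataframe(df, catalog=catalog)
    problems = table.validate(catalog)
    if problems and strict:
        raise TableValidationError(problems)
    return table


def write_measure_table(table: CountyMeasureTable, path: str | Path) -> None:
    """Write the canonical CSV; full float precision, empty field = missing."""
    df = table.to_dataframe()
    # population as integer text, not float
    df["population"] = df["population"].astype(np.int64)
    df.to_csv(path, na_rep="")
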