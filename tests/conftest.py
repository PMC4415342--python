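import numpy as np
import pandas as pd
import pytest

from countyrank import (CountyMeasureTable, MeasureCatalog, MeasureDefinition,
                        load_default_catalog)


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()


@pytest.fixture
def tiny_catalog():
    """Two-measure catalog: one outcome, one reverse-coded factor."""
    return MeasureCatalog(measures=[
        MeasureDefinition("premature_death", "Premature death", "mortality",
                          "length of life", 100.0, has_standard_error=True),
        MeasureDefinition("some_college", "Some college", "social_economic",
                          "education", 100.0, direction="higher_is_better"),
    ], name="tiny")


def make_table(states, values, populations=None, ses=None,
               measure="premature_death"):
    """One-measure table builder: values/populations keyed by state lists."""
    rows = []
    i = 0
    for st, vals in zip(states, values):
        for j, v in enumerate(vals):
            pop = populations[i] if populations is not None else 50_000
            rows.append({"fips": f"{i:05d}", "state": st,
                         "population": pop, measure: v})
            if ses is not None:
                rows[-1][measure + "_se"] = ses[i]
            i += 1
    return CountyMeasureTable.from_dataframe(pd.DataFrame(rows))


@pytest.fixture
def one_state_table():
    """Three counties in one state, values 1, 2, 3, all above 20k residents."""
    return make_table(["AA"], [[1.0, 2.0, 3.0]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
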