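"""Measure catalog: the weighted hierarchy behind the composite health scores.

A catalog names every measure, assigns it to one of the two composite
families (health *outcomes* — current health — or health *factors* —
modifiable determinants), to a component within that family, and gives it a
weight expressed as percent of its family total.  The default catalog is the
2014 County Health Rankings measure set: 34 measures, outcomes split 50/50
between mortality (length of life) and morbidity (quality of life), factors
split 30/20/40/10 between health behaviors, clinical care, social & economic
factors, and the physical environment.

Catalogs are data, not code: users may load their own from JSON or YAML to
re-weight or swap measures, and :func:`validate_catalog` reports every
violated structural invariant without raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "MeasureDefinition",
    "MeasureCatalog",
    "ValidationReport",
    "load_default_catalog",
    "validate_catalog",
    "read_catalog",
    "write_catalog",
    "OUTCOMES",
    "FACTORS",
    "COMPONENTS",
    "FAMILY_OF_COMPONENT",
]

OUTCOMES = "outcomes"
FACTORS = "factors"

#: component -> composite family membership
FAMILY_OF_COMPONENT = {
    "mortality": OUTCOMES,
    "morbidity": OUTCOMES,
    "health_behaviors": FACTORS,
    "clinical_care": FACTORS,
    "social_economic": FACTORS,
    "physical_environment": FACTORS,
}
COMPONENTS = tuple(FAMILY_OF_COMPONENT)

HIGHER_IS_WORSE = "higher_is_worse"
HIGHER_IS_BETTER = "higher_is_better"

#: weight-sum tolerance used by validation
_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class MeasureDefinition:
    """One measure: identity, placement in the hierarchy, weight and direction.

    ``weight_pct`` is percent of the measure's composite *family* total
    (outcomes or factors), not of a grand total; the two families are never
    mixed into a single score.  ``direction`` says whether higher raw values
    mean poorer health (the common case) or better health (reverse-coded
    measures such as high-school graduation), in which case the z-score is
    negated before aggregation.
    """

    measure_id: str
    display_name: str
    component: str
    subcomponent: str
    weight_pct: float
    direction: str = HIGHER_IS_WORSE
    has_standard_error: bool = False
    source_label: str = ""
    years_label: str = ""

    @property
    def composite_family(self) -> str:
        return FAMILY_OF_COMPONENT[self.component]

    @property
    def reverse_coded(self) -> bool:
        return self.direction == HIGHER_IS_BETTER


@dataclass
class MeasureCatalog:
    """Ordered collection of measures plus the component-level weight split."""

    measures: list[MeasureDefinition]
    component_weight_pct: dict[str, float] = field(default_factory=dict)
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.component_weight_pct:
            # derive component subtotals from the measure weights
            sub: dict[str, float] = {}
            for m in self.measures:
                sub[m.component] = sub.get(m.component, 0.0) + m.weight_pct
            self.component_weight_pct = sub

    # -- lookups -----------------------------------------------------------
    @property
    def measure_ids(self) -> list[str]:
        return [m.measure_id for m in self.measures]

    def __len__(self) -> int:
        return len(self.measures)

    def __iter__(self):
        return iter(self.measures)

    def __getitem__(self, measure_id: str) -> MeasureDefinition:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(measure_id)

    def __contains__(self, measure_id: str) -> bool:
        return any(m.measure_id == measure_id for m in self.measures)

    def family_measures(self, family: str) -> list[MeasureDefinition]:
        return [m for m in self.measures if m.composite_family == family]

    def component_measures(self, component: str) -> list[MeasureDefinition]:
        return [m for m in self.measures if m.component == component]

    def se_measure_ids(self) -> list[str]:
        return [m.measure_id for m in self.measures if m.has_standard_error]


@dataclass
class ValidationReport:
    """Outcome of structural validation; empty problem list <=> valid."""

    problems: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:  # truthy when valid, mirrors "report is clean"
        return self.valid

    def __str__(self) -> str:
        if self.valid:
            return "catalog OK"
        return "\n".join(f"- {p}" for p in self.problems)


# ---------------------------------------------------------------------------
# 2014 default catalog
# ---------------------------------------------------------------------------

_NCHS = "National Center for Health Statistics"
_BRFSS = "Behavioral Risk Factor Surveillance System"
_ACS = "American Community Survey"
_DARTMOUTH = "Medicare/Dartmouth Institute"

# (measure_id, display_name, component, subcomponent, weight_pct, direction,
#  has_se, source, years)
_W, _B = HIGHER_IS_WORSE, HIGHER_IS_BETTER
_DEFAULT_ROWS: list[tuple] = [
    # -- health outcomes (weights sum to 100) ------------------------------
    ("premature_death", "Premature death", "mortality", "length of life",
     50.0, _W, True, _NCHS, "2008-2010"),
    ("poor_fair_health", "Poor or fair health", "morbidity", "quality of life",
     10.0, _W, True, _BRFSS, "2006-2012"),
    ("poor_physical_days", "Poor physical health days", "morbidity",
     "quality of life", 10.0, _W, True, _BRFSS, "2006-2012"),
    ("poor_mental_days", "Poor mental health days", "morbidity",
     "quality of life", 10.0, _W, True, _BRFSS, "2006-2012"),
    ("low_birthweight", "Low birthweight", "morbidity", "quality of life",
     20.0, _W, True, _NCHS, "2005-2011"),
    # -- health behaviors (30) ---------------------------------------------
    ("adult_smoking", "Adult smoking", "health_behaviors", "tobacco use",
     10.0, _W, True, _BRFSS, "2006-2012"),
    ("adult_obesity", "Adult obesity", "health_behaviors", "diet and exercise",
     5.0, _W, False, "NCCDPHP", "2010"),
    ("food_environment", "Food environment index", "health_behaviors",
     "diet and exercise", 2.0, _B, False,
     "USDA Food Environment Atlas, Map the Meal Gap", "2010-2011"),
    ("physical_inactivity", "Physical inactivity", "health_behaviors",
     "diet and exercise", 2.0, _W, False, "NCCDPHP", "2010"),
    ("access_exercise", "Access to exercise opportunities", "health_behaviors",
     "diet and exercise", 1.0, _B, False,
     "OneSource, Delorme, Esri & US Census Tigerline", "2010 & 2012"),
    ("excessive_drinking", "Excessive drinking", "health_behaviors",
     "alcohol and drug use", 2.5, _W, True, _BRFSS, "2006-2012"),
    ("alcohol_driving_deaths", "Alcohol-impaired driving deaths",
     "health_behaviors", "alcohol and drug use", 2.5, _W, False,
     "Fatality Analysis Reporting System", "2008-2012"),
    ("sexually_transmitted_infections", "Sexually transmitted infections",
     "health_behaviors", "sexual activity", 2.5, _W, False,
     "National Center for HIV/AIDS, Viral Hepatitis, STD, and TB prevention",
     "2011"),
    ("teen_births", "Teen births", "health_behaviors", "sexual activity",
     2.5, _W, True, _NCHS, "2005-2011"),
    # -- clinical care (20) ------------------------------------------------
    ("uninsured", "Uninsured", "clinical_care", "access to care",
     5.0, _W, False, "Small Area Health Insurance Estimates", "2011"),
    ("primary_care_physicians", "Primary care physicians", "clinical_care",
     "access to care", 3.0, _W, False, "HRSA Area Resource File", "2011"),
    ("dentists", "Dentists", "clinical_care", "access to care",
     1.0, _W, False, "HRSA Area Resource File", "2012"),
    ("mental_health_providers", "Mental health providers", "clinical_care",
     "access to care", 1.0, _W, False, "CMS, National Provider Identification",
     "2013"),
    ("preventable_stays", "Preventable hospital stays", "clinical_care",
     "quality of care", 5.0, _W, False, _DARTMOUTH, "2011"),
    ("diabetic_screening", "Diabetic screening", "clinical_care",
     "quality of care", 2.5, _B, False, _DARTMOUTH, "2011"),
    ("mammography_screening", "Mammography screening", "clinical_care",
     "quality of care", 2.5, _B, False, _DARTMOUTH, "2011"),
    # -- social and economic factors (40) ----------------------------------
    ("hs_graduation", "High school graduation", "social_economic", "education",
     5.0, _B, False, "data.gov / National Center for Education Statistics",
     "2010-2011"),
    ("some_college", "Some college", "social_economic", "education",
     5.0, _B, False, _ACS, "2008-2012"),
    ("unemployment", "Unemployment", "social_economic", "employment",
     10.0, _W, False, "Bureau of Labor Statistics", "2012"),
    ("children_poverty", "Children in poverty", "social_economic", "income",
     10.0, _W, False, "Small Area Income and Poverty Estimates", "2012"),
    ("inadequate_social_support", "Inadequate social support",
     "social_economic", "family and social support", 2.5, _W, True,
     _BRFSS, "2005-2010"),
    ("single_parent_households", "Children in single-parent households",
     "social_economic", "family and social support", 2.5, _W, False,
     _ACS, "2008-2012"),
    ("violent_crime", "Violent crime", "social_economic", "community safety",
     2.5, _W, False, "Uniform Crime Reporting - FBI", "2009-2011"),
    ("injury_deaths", "Injury deaths", "social_economic", "community safety",
     2.5, _W, False, "CDC WONDER", "2006-2010"),
    # -- physical environment (10) -----------------------------------------
    ("air_pollution", "Air pollution - particulate matter",
     "physical_environment", "air and water quality", 2.5, _W, False,
     "CDC WONDER", "2011"),
    ("drinking_water_violations", "Drinking water violations",
     "physical_environment", "air and water quality", 2.5, _W, False,
     "Safe Drinking Water Information System", "FY 2012-2013"),
    ("severe_housing_problems", "Severe housing problems",
     "physical_environment", "housing and transit", 2.0, _W, False,
     "HUD, Comprehensive Housing Affordability Strategy", "2006-2010"),
    ("driving_alone_to_work", "Driving alone to work", "physical_environment",
     "housing and transit", 2.0, _W, False, _ACS, "2008-2012"),
    ("long_commute_driving_alone", "Long commute - driving alone",
     "physical_environment", "housing and transit", 1.0, _W, False,
     _ACS, "2008-2012"),
]


def load_default_catalog() -> MeasureCatalog:
    """Return the 2014 34-measure default catalog.

    Outcome weights: premature death 50, poor/fair health 10, poor physical
    health days 10, poor mental health days 10, low birthweight 20 (sum 100).
    Factor component subtotals: health behaviors 30, clinical care 20,
    social & economic 40, physical environment 10 (sum 100).  Six measures
    are reverse-coded (higher raw value = better health).
    """
    measures = [MeasureDefinition(*row) for row in _DEFAULT_ROWS]
    return MeasureCatalog(measures=measures, name="chr-2014")


def validate_catalog(catalog: MeasureCatalog) -> ValidationReport:
    """Check the structural invariants; never raises.

    Reported problems: duplicate measure ids, non-positive weights, unknown
    component or direction labels, family weight sums off 100 by more than
    1e-9, and component subtotals inconsistent with ``component_weight_pct``.
    """
    problems: list[str] = []

    seen: set[str] = set()
    for m in catalog.measures:
        if m.measure_id in seen:
            problems.append(f"duplicate measure_id {m.measure_id!r}")
        seen.add(m.measure_id)
        if not m.weight_pct > 0:
            problems.append(
                f"{m.measure_id}: weight_pct must be > 0, got {m.weight_pct}")
        if m.component not in FAMILY_OF_COMPONENT:
            problems.append(
                f"{m.measure_id}: unknown component {m.component!r}")
        if m.direction not in (HIGHER_IS_WORSE, HIGHER_IS_BETTER):
            problems.append(
                f"{m.measure_id}: unknown direction {m.direction!r}")

    for family in (OUTCOMES, FACTORS):
        total = sum(m.weight_pct for m in catalog.measures
                    if m.component in FAMILY_OF_COMPONENT
                    and m.composite_family == family)
        if abs(total - 100.0) > _WEIGHT_TOL:
            problems.append(
                f"{family} measure weights sum to {total:g}, expected 100")

    for component, expected in catalog.component_weight_pct.items():
        if component not in FAMILY_OF_COMPONENT:
            problems.append(f"unknown component {component!r} in weight map")
            continue
        total = sum(m.weight_pct for m in catalog.measures
                    if m.component == component)
        if abs(total - expected) > _WEIGHT_TOL:
            problems.append(
                f"component {component}: measure weights sum to {total:g}, "
                f"component_weight_pct says {expected:g}")

    return ValidationReport(problems=problems)


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def catalog_to_dict(catalog: MeasureCatalog) -> dict:
    return {
        "name": catalog.name,
        "component_weight_pct": dict(catalog.component_weight_pct),
        "measures": [asdict(m) for m in catalog.measures],
    }


def catalog_from_dict(data: dict) -> MeasureCatalog:
    measures = [MeasureDefinition(**row) for row in data["measures"]]
    return MeasureCatalog(
        measures=measures,
        component_weight_pct=dict(data.get("component_weight_pct", {})),
        name=data.get("name", "custom"),
    )


def write_catalog(catalog: MeasureCatalog, path: str | Path) -> None:
    """Write a catalog to JSON or YAML, chosen by file extension."""
    path = Path(path)
    data = catalog_to_dict(catalog)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def read_catalog(path: str | Path) -> MeasureCatalog:
    """Read a catalog from JSON or YAML, chosen by file extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return catalog_from_dict(data)
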