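"""Run-time options and run configuration.

The constants here are the method's fixed thresholds: z-scores of counties
with 20,000 or fewer residents are truncated at |z| = 3.0, estimates with a
relative standard error above 20% are treated as unreliable, the national
benchmark is the best-10% boundary, and the extremes comparison pools the
five best- and five worst-ranked counties from states with at least ten
counties.  All are exposed as options so variants can be explored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RankingOptions", "RunConfig", "read_run_config"]

SAMPLE = "sample"
POPULATION = "population"


@dataclass(frozen=True)
class RankingOptions:
    """Methodological knobs for the scoring pipeline.

    Parameters
    ----------
    sd_flavor
        ``"sample"`` (n-1 denominator, default) or ``"population"`` (n) for
        the within-state standard deviation.
    truncation_threshold_population
        Counties at or below this population have |z| clamped to
        ``truncation_z`` (default 20,000 residents).
    truncation_z
        Clamp magnitude for small-county z-scores (default 3.0 SD).
    rse_threshold
        Relative standard error above which an estimate is unreliable
        (default 0.20).
    tie_rule
        Rank tie rule; only ``"competition"`` (ties share the minimal rank,
        next rank skipped) is supported.
    benchmark_percentile
        Percentile defining the national best-X% benchmark (default 10).
    extremes_k
        Counties pooled from each tail of the within-state outcomes ranking
        in the extremes comparison (default 5).
    extremes_min_counties
        Minimum counties a state needs to enter the extremes comparison
        (default 10).
    """

    sd_flavor: str = SAMPLE
    truncation_threshold_population: int = 20_000
    truncation_z: float = 3.0
    rse_threshold: float = 0.20
    tie_rule: str = "competition"
    benchmark_percentile: float = 10.0
    extremes_k: int = 5
    extremes_min_counties: int = 10

    def __post_init__(self) -> None:
        if self.sd_flavor not in (SAMPLE, POPULATION):
            raise ValueError(f"sd_flavor must be 'sample' or 'population', "
                             f"got {self.sd_flavor!r}")
        if self.tie_rule != "competition":
            raise ValueError(f"unsupported tie_rule {self.tie_rule!r}")
        if self.truncation_threshold_population <= 0:
            raise ValueError("truncation_threshold_population must be > 0")
        if self.truncation_z <= 0:
            raise ValueError("truncation_z must be > 0")
        if self.rse_threshold <= 0:
            raise ValueError("rse_threshold must be > 0")
        if not 0 < self.benchmark_percentile <= 50:
            raise ValueError("benchmark_percentile must be in (0, 50]")
        if self.extremes_k < 1 or self.extremes_min_counties < 1:
            raise ValueError("extremes_k and extremes_min_counties must be >= 1")

    @property
    def sd_ddof(self) -> int:
        return 1 if self.sd_flavor == SAMPLE else 0


@dataclass
class RunConfig:
    """Paths plus options for a full command-line run."""

    input_table: str = ""
    catalog: str | None = None          # None -> default 2014 catalog
    output_dir: str = "countyrank_out"
    seed: int | None = None
    options: RankingOptions = field(default_factory=RankingOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def read_run_config(path: str | Path) -> RunConfig:
    """Read a run configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    opts = RankingOptions(**data.pop("options", {}))
    return RunConfig(options=opts, **data)
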