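"""Within-state standardization of raw county measures.

Counties are compared only to the other counties of their own state: for
each measure and state,

    z = (county value - mean of observed counties in state)
        / (SD of observed counties in state)

so every measure lands on a common scale (mean 0, SD 1 within state)
regardless of its raw units.  Around that core the module applies the
method's data-quality handling, in this order:

1. reliability — estimates whose relative standard error exceeds the
   threshold (default 20%) are treated as missing for scoring;
2. imputation — missing (or unreliable) cells receive z = 0, i.e. the state
   mean, with the state mean/SD computed from observed counties only;
3. direction alignment — reverse-coded measures (higher = better health)
   are negated so that a higher z always means poorer health;
4. small-county truncation — counties with populations at or below 20,000
   have |z| clamped to 3.0 to damp small-area noise.

A state-measure with fewer than two observed counties carries no
information; the measure is dropped for that state (all z = 0) and the
composite module renormalizes the remaining weights for that state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MeasureCatalog, load_default_catalog, HIGHER_IS_BETTER, \
    HIGHER_IS_WORSE
from .config import RankingOptions
from .io import CountyMeasureTable

__all__ = [
    "StandardizedTable",
    "flag_unreliable",
    "apply_direction",
    "truncate_small_county",
    "compute_zscores",
]


def flag_unreliable(value: float, se: float, threshold: float = 0.20) -> bool:
    """True iff the estimate's relative standard error exceeds ``threshold``.

    RSE = se / |value|; a zero value with a positive SE is unreliable (the
    RSE diverges).  A missing SE never flags.

    Raises
    ------
    ValueError
        If ``se`` is negative.
    """
    if se is None or (isinstance(se, float) and np.isnan(se)):
        return False
    if se < 0:
        raise ValueError(f"standard error must be >= 0, got {se}")
    return se > threshold * abs(value)


def apply_direction(z: float, direction: str) -> float:
    """Negate z for reverse-coded measures so higher z = poorer health."""
    if direction == HIGHER_IS_BETTER:
        return -z
    if direction == HIGHER_IS_WORSE:
        return z
    raise ValueError(f"unknown direction {direction!r}")


def truncate_small_county(
    z: float,
    population: int,
    threshold_population: int = 20_000,
    z_max: float = 3.0,
) -> float:
    """Clamp z to [-z_max, z_max] for counties at or below the population cut.

    The population boundary is inclusive: a county of exactly 20,000
    residents is truncated.  Larger counties pass through unchanged.
    """
    if population <= threshold_population:
        return float(min(max(z, -z_max), z_max))
    return float(z)


@dataclass
class StandardizedTable:
    """Per county-measure z-scores plus provenance flags.

    ``z`` holds the final scores (post direction alignment and truncation);
    ``z_untruncated`` the direction-aligned scores before the small-county
    clamp (within each state-measure, its observed cells have mean 0 and
    SD 1 up to sign); ``imputed``/``truncated``/``unreliable`` are per-cell
    boolean flags;
    ``dropped`` is a state x measure boolean frame marking state-measures
    with < 2 observed counties (weights renormalized downstream); ``state``
    maps each county to its state for downstream grouping.
    """

    z: pd.DataFrame
    imputed: pd.DataFrame
    truncated: pd.DataFrame
    unreliable: pd.DataFrame
    dropped: pd.DataFrame
    state: pd.Series
    population: pd.Series = field(default_factory=pd.Series)
    z_untruncated: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def measure_ids(self) -> list[str]:
        return list(self.z.columns)


def _unreliable_mask(
    table: CountyMeasureTable,
    cols: list[str],
    threshold: float,
) -> pd.DataFrame:
    out = np.zeros((len(table.values), len(cols)), dtype=bool)
    se_cols = [c for c in table.standard_errors.columns if c in cols]
    if se_cols:
        se = table.standard_errors[se_cols].to_numpy(dtype=float)
        if np.any(se < 0):
            bad = [c for i, c in enumerate(se_cols) if np.any(se[:, i] < 0)]
            raise ValueError(f"negative standard errors in columns {bad}")
        vals = table.values[se_cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            m = np.isfinite(se) & np.isfinite(vals) \
                & (se > threshold * np.abs(vals))
        pos = [cols.index(c) for c in se_cols]
        out[:, pos] = m
    return pd.DataFrame(out, index=table.values.index, columns=cols)


def compute_zscores(
    table: CountyMeasureTable,
    catalog: MeasureCatalog | None = None,
    options: RankingOptions | None = None,
) -> StandardizedTable:
    """Standardize every measure within every state.

    Observed (non-missing, reliable) counties define the state mean and SD
    (sample SD by default); they receive exact z-scores, so within each
    state-measure the observed z have mean 0 and SD 1 before direction
    alignment and truncation.  Missing and unreliable cells are imputed to
    z = 0.  Zero-variance state-measures yield z = 0 for everyone.
    """
    if catalog is None:
        catalog = load_default_catalog()
    if options is None:
        options = RankingOptions()

    # catalog order, restricted to columns actually present
    cols = [m for m in catalog.measure_ids if m in table.values.columns]
    vals_df = table.values[cols]
    state = table.state
    idx = vals_df.index

    unreliable = _unreliable_mask(table, cols, options.rse_threshold)

    # numpy core: grouped moments per (state, measure)
    vals = vals_df.to_numpy(dtype=float)
    usable = np.isfinite(vals) & ~unreliable.to_numpy()
    filled = np.where(usable, vals, 0.0)

    codes, states = pd.factorize(state.to_numpy())
    n_states = len(states)
    n_obs = np.zeros((n_states, len(cols)))
    total = np.zeros_like(n_obs)
    ss_dev = np.zeros_like(n_obs)
    np.add.at(n_obs, codes, usable.astype(float))
    np.add.at(total, codes, filled)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n_obs
    mean_c = mean[codes]
    dev = np.where(usable, vals - mean_c, 0.0)  # two-pass: no cancellation
    np.add.at(ss_dev, codes, dev * dev)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss_dev / (n_obs - options.sd_ddof))

    sd_c, n_c = sd[codes], n_obs[codes]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean_c) / sd_c
    # zero variance -> 0; whole-state-dropped (< 2 observed) -> 0; imputed -> 0
    # (variance below float round-off of the mean counts as zero)
    sd_floor = 1e-12 * np.maximum(1.0, np.abs(mean_c))
    z = np.where((sd_c > sd_floor) & (n_c >= 2) & usable, z, 0.0)

    imputed = pd.DataFrame(~usable, index=idx, columns=cols)
    dropped = pd.DataFrame(n_obs < 2, index=pd.Index(states, name="state"),
                           columns=cols)

    # direction alignment: reverse-coded measures negated
    rev = np.array([catalog[m].direction == HIGHER_IS_BETTER for m in cols])
    z[:, rev] = -z[:, rev]

    # small-county truncation
    small = (table.population.to_numpy()
             <= options.truncation_threshold_population)
    clipped = np.clip(z, -options.truncation_z, options.truncation_z)
    z_final = np.where(small[:, None], clipped, z)
    truncated = pd.DataFrame(z_final != z, index=idx, columns=cols)

    return StandardizedTable(
        z=pd.DataFrame(z_final, index=idx, columns=cols),
        imputed=imputed,
        truncated=truncated,
        unreliable=unreliable,
        dropped=dropped,
        state=state,
        population=table.population,
        z_untruncated=pd.DataFrame(z, index=idx, columns=cols),
    )
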