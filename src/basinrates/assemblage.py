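"""Join species-level rates and traits to basins.

Basin-level summaries (mean / median / min / max of per-species values,
optionally weighted), species richness and area-corrected species density
SD = SR / A^z, Shannon diversity of soil types, and the filtering /
exclusion machinery used by robustness analyses (minimum-richness basin
filters, taxon and basin drops).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy

__all__ = [
    "summarize_rates_by_basin",
    "range_size_weights",
    "richness_and_density",
    "shannon_soil_diversity",
    "filter_and_exclude",
    "FilterLog",
]

logger = logging.getLogger(__name__)

_STATS = ("mean", "median", "min", "max")


def _check_incidence(incidence: pd.DataFrame) -> None:
    vals = incidence.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")


def summarize_rates_by_basin(
    incidence: pd.DataFrame,
    values: pd.Series,
    stat: str = "mean",
    weights: pd.Series | None = None,
) -> pd.Series:
    """Summarize a per-species value over the species present in each basin.

    ``stat`` is one of mean / median / min / max; a weighted mean is used
    when per-species ``weights`` are supplied (weights must be > 0; only
    ``stat="mean"`` supports them).  Basins with no species are excluded
    with a logged warning.
    """
    if stat not in _STATS:
        raise ValueError(f"stat must be one of {_STATS}")
    _check_incidence(incidence)
    lacking = [sp for sp in incidence.columns if sp not in values.index or pd.isna(values[sp])]
    if lacking:
        raise ValueError(f"species lacking a value: {lacking[:10]}")
    v = values.reindex(incidence.columns).to_numpy(dtype=float)
    inc = incidence.to_numpy(dtype=float)

    occupied = inc.sum(axis=1) > 0
    if not occupied.all():
        empty = list(incidence.index[~occupied])
        logger.warning("excluding %d empty basins: %s", len(empty), empty[:5])

    if weights is not None:
        if stat != "mean":
            raise ValueError("weights are only supported with stat='mean'")
        w = weights.reindex(incidence.columns)
        if w.isna().any() or (w <= 0).any():
            raise ValueError("weights must be positive for every species")
        w = w.to_numpy(dtype=float)
        num = inc @ (w * v)
        den = inc @ w
        out = np.where(occupied, num / np.where(den > 0, den, np.nan), np.nan)
    else:
        with np.errstate(invalid="ignore"):
            M = np.where(inc > 0, v[None, :], np.nan)
            if stat == "mean":
                out = np.nanmean(M, axis=1)
            elif stat == "median":
                out = np.nanmedian(M, axis=1)
            elif stat == "min":
                out = np.nanmin(np.where(np.isnan(M), np.inf, M), axis=1)
                out = np.where(occupied, out, np.nan)
            else:
                out = np.nanmax(np.where(np.isnan(M), -np.inf, M), axis=1)
                out = np.where(occupied, out, np.nan)
    series = pd.Series(out, index=incidence.index, name=f"{stat}_{values.name or 'value'}")
    return series[occupied]


def range_size_weights(incidence: pd.DataFrame) -> pd.Series:
    """Inverse range-size weights w_s = 1 / (number of basins occupied by s).

    Down-weights wide-ranging species in basin summaries.
    """
    _check_incidence(incidence)
    counts = incidence.sum(axis=0)
    if (counts == 0).any():
        bad = list(counts.index[counts == 0][:5])
        raise ValueError(f"species occupying no basin: {bad}")
    return 1.0 / counts


def richness_and_density(
    incidence: pd.DataFrame, areas: pd.Series, z: float = 0.3
) -> pd.DataFrame:
    """Species richness SR and species density SD = SR / A^z per basin.

    ``z`` is the species-area scaling exponent (empirically 0.25-0.50;
    ``z = 0`` reduces SD to SR).
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError("z must lie in [0, 1]")
    _check_incidence(incidence)
    a = areas.reindex(incidence.index)
    if a.isna().any() or (a <= 0).any():
        raise ValueError("every basin needs a positive area")
    sr = incidence.sum(axis=1).astype(float)
    sd = sr / np.power(a.to_numpy(dtype=float), z)
    return pd.DataFrame({"SR": sr, "SD": sd}, index=incidence.index)


def shannon_soil_diversity(soil_counts: pd.DataFrame) -> pd.Series:
    """Shannon diversity H (nats) of soil-type composition per basin."""
    counts = soil_counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("soil counts must be >= 0")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(soil_counts.index[totals <= 0][:5])
        raise ValueError(f"all-zero soil rows for basins {bad}")
    H = entropy(counts, axis=1)  # normalizes rows, ignores zero classes, base e
    return pd.Series(H, index=soil_counts.index, name="soil_shannon")


@dataclass
class FilterLog:
    """Provenance of a filter_and_exclude call."""

    dropped_taxa: list[str] = field(default_factory=list)
    dropped_basins: list[str] = field(default_factory=list)
    dropped_low_richness: list[str] = field(default_factory=list)
    dropped_unrepresented_taxa: list[str] = field(default_factory=list)


def filter_and_exclude(
    incidence: pd.DataFrame,
    min_species: int = 0,
    drop_taxa: tuple[str, ...] | list[str] = (),
    drop_basins: tuple[str, ...] | list[str] = (),
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply taxon/basin exclusions and a minimum-richness basin filter.

    Order of operations: listed taxa and basins are removed first, then
    basins whose richness falls below ``min_species``, then species left
    with no occurrence.  The log records exactly what was dropped at each
    step.  Emptying the matrix is an error.
    """
    if min_species < 0:
        raise ValueError("min_species must be >= 0")
    _check_incidence(incidence)
    log = FilterLog()
    out = incidence
    taxa = [t for t in drop_taxa if t in out.columns]
    if taxa:
        out = out.drop(columns=taxa)
        log.dropped_taxa = taxa
    basins = [b for b in drop_basins if b in out.index]
    if basins:
        out = out.drop(index=basins)
        log.dropped_basins = basins
    sr = out.sum(axis=1)
    low = list(out.index[sr < min_species])
    if low:
        out = out.drop(index=low)
        log.dropped_low_richness = low
    unrep = list(out.columns[out.sum(axis=0) == 0])
    if unrep:
        out = out.drop(columns=unrep)
        log.dropped_unrepresented_taxa = unrep
    if out.shape[0] == 0 or out.shape[1] == 0:
        raise ValueError("filtering emptied the incidence matrix")
    return out, log
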