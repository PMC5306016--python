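"""Plot-level environmental inference from Ellenberg indicator values.

Each plot's environment along an indicator axis (R = soil reaction,
N = nutrients/fertility, F = moisture) is estimated as the cover-weighted
mean of the indicator values of the species present, after excluding
species flagged as indifferent (wide, uninformative occurrence pattern)
or with a missing value.  The estimate is invariant under uniform cover
rescaling and always lies within the range of the contributing species'
values.

Where a measured soil pH is available for a subset of plots, the inferred
soil-reaction value can be validated against it (Pearson and Kendall
correlation of the paired values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import INDICATORS
from .stats_core import kendall_tau

__all__ = ["infer_indicator", "attach_indicators", "validate_inferred_ph", "PhValidation"]


def infer_indicator(
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    indicator: str,
    herb_only: bool = False,
) -> pd.DataFrame:
    """Cover-weighted mean Ellenberg value per plot for one indicator.

    Parameters
    ----------
    cover
        Plots x (species_id, stratum) matrix.
    traits
        Species table with ``ellenberg_<indicator>`` and
        ``indifferent_<indicator>`` columns.
    indicator
        One of ``R``, ``N``, ``F``.
    herb_only
        Restrict the weighted mean to the herbaceous stratum.

    Returns a frame indexed by plot_id with ``value`` (NaN when no species
    is usable), ``n_species_used`` and ``fraction_cover_used``.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"indicator must be one of {INDICATORS}, got {indicator!r}")
    col_species = cover.columns.get_level_values(0)
    col_stratum = cover.columns.get_level_values(1).to_numpy()
    vals = traits[f"ellenberg_{indicator}"].reindex(col_species).to_numpy(float)
    indiff = (
        traits[f"indifferent_{indicator}"].reindex(col_species).fillna(False).to_numpy(bool)
    )
    usable = ~np.isnan(vals) & ~indiff
    if herb_only:
        usable &= col_stratum == "herbaceous"

    c = cover.to_numpy(float)
    c_use = c[:, usable]
    v_use = vals[usable]
    denom = c_use.sum(axis=1)
    num = c_use @ v_use
    total = c.sum(axis=1)
    value = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.DataFrame(
        {
            "value": value,
            "n_species_used": (c_use > 0).sum(axis=1),
            "fraction_cover_used": np.where(total > 0, denom / total, np.nan),
        },
        index=cover.index,
    )


def attach_indicators(
    metrics: pd.DataFrame,
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    herb_only: bool = False,
) -> pd.DataFrame:
    """Add ``e_R``, ``e_N``, ``e_F`` columns to a plot-metrics frame."""
    out = metrics.copy()
    for ind in INDICATORS:
        est = infer_indicator(cover, traits, ind, herb_only=herb_only)
        out[f"e_{ind}"] = est["value"].reindex(out.index)
    return out


@dataclass
class PhValidation:
    """Agreement between inferred soil reaction and measured soil pH."""

    pearson_r: float
    kendall_tau: float
    kendall_p: float
    n: int
    pairs: pd.DataFrame

    def __repr__(self) -> str:  # pairs table elided
        return (
            f"PhValidation(pearson_r={self.pearson_r:.3f}, "
            f"kendall_tau={self.kendall_tau:.3f}, n={self.n})"
        )


def validate_inferred_ph(estimates: pd.DataFrame, meta: pd.DataFrame) -> PhValidation:
    """Compare inferred Ellenberg R values with measured pH where available.

    ``estimates`` is the output of :func:`infer_indicator` for R; ``meta``
    must carry a ``measured_ph`` column.  Requires >= 3 complete pairs.
    """
    inferred = estimates["value"]
    measured = meta["measured_ph"].reindex(inferred.index)
    ok = inferred.notna() & measured.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 plots with both inferred and measured pH, got {n}")
    x = inferred[ok].to_numpy(float)
    y = measured[ok].to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    tau = kendall_tau(x, y)
    pairs = pd.DataFrame(
        {"inferred_R": x, "measured_ph": y}, index=inferred.index[ok]
    )
    return PhValidation(
        pearson_r=r, kendall_tau=tau.estimate, kendall_p=tau.p_value, n=n, pairs=pairs
    )
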