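"""Per-plot mycorrhizal community metrics.

The central quantities are AM-weighted shares of a stratum's community.
Each species carries a weight w in [0, 1] derived from its mycorrhizal
status class: obligately AM species count fully (w=1), species never
reported as AM count zero, species reported both as AM and in another
state (facultative / mixed) count ``w_mixed`` (default 0.5), and species
of unknown status are excluded from numerator *and* denominator.

Relative AM abundance of a stratum is sum(w_i c_i) / sum(c_i) over the
non-excluded species present, with c_i the converted cover score; relative
AM richness replaces covers by presence.  The log response ratio
ln(herb total / woody total) serves as the biotic covariate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import STRATA

__all__ = [
    "EXCLUDED",
    "mycorrhizal_weight",
    "species_weights",
    "relative_am_abundance",
    "relative_am_richness",
    "absolute_am_richness",
    "log_response_ratio",
    "compute_plot_metrics",
    "compare_strata",
    "StrataComparison",
]

#: Sentinel for species dropped from both numerator and denominator.
EXCLUDED = object()

_STATUS_BASE = {"AM_ONLY": 1.0, "NON_AM": 0.0}


def mycorrhizal_weight(status: str, w_mixed: float = 0.5):
    """Map a mycorrhizal status class to a weight, or ``EXCLUDED``.

    AM_ONLY -> 1, NON_AM -> 0, AM_MIXED -> ``w_mixed``, UNKNOWN -> EXCLUDED.
    """
    if not 0.0 <= w_mixed <= 1.0:
        raise ValueError(f"w_mixed must be in [0, 1], got {w_mixed}")
    if status in _STATUS_BASE:
        return _STATUS_BASE[status]
    if status == "AM_MIXED":
        return float(w_mixed)
    if status == "UNKNOWN":
        return EXCLUDED
    raise ValueError(f"unknown mycorrhizal status {status!r}")


def species_weights(traits: pd.DataFrame, w_mixed: float = 0.5) -> pd.Series:
    """Per-species weight vector; NaN marks excluded (unknown-status) species."""
    if not 0.0 <= w_mixed <= 1.0:
        raise ValueError(f"w_mixed must be in [0, 1], got {w_mixed}")
    mapping = {"AM_ONLY": 1.0, "NON_AM": 0.0, "AM_MIXED": float(w_mixed), "UNKNOWN": np.nan}
    return traits["myc_status"].map(mapping).astype(float)


def _weighted_share(covers: np.ndarray, weights: np.ndarray) -> float:
    keep = ~np.isnan(weights)
    covers, weights = covers[keep], weights[keep]
    total = covers.sum()
    if total <= 0:
        return np.nan
    return float((covers * weights).sum() / total)


def relative_am_abundance(covers, weights) -> float:
    """AM-weighted share of total cover; NaN if nothing usable remains."""
    return _weighted_share(np.asarray(covers, float), np.asarray(weights, float))


def relative_am_richness(weights) -> float:
    """AM-weighted share of the species count of present, non-excluded species."""
    w = np.asarray(weights, float)
    w = w[~np.isnan(w)]
    if w.size == 0:
        return np.nan
    return float(w.sum() / w.size)


def absolute_am_richness(weights) -> float:
    """AM-weighted species count (sum of weights over present species)."""
    w = np.asarray(weights, float)
    w = w[~np.isnan(w)]
    if w.size == 0:
        return np.nan
    return float(w.sum())


def log_response_ratio(herb_total: float, woody_total: float) -> float:
    """ln(herb_total / woody_total); NaN when either stratum is empty."""
    if herb_total <= 0 or woody_total <= 0:
        return np.nan
    return float(np.log(herb_total / woody_total))


def compute_plot_metrics(
    cover: pd.DataFrame, traits: pd.DataFrame, w_mixed: float = 0.5
) -> pd.DataFrame:
    """Compute all per-plot community metrics from a cover matrix.

    Parameters
    ----------
    cover
        Plots x (species_id, stratum) matrix from
        :func:`mycomediate.io_model.convert_bb_to_cover`.
    traits
        Species trait table indexed by species_id.
    w_mixed
        Weight for facultatively-AM (mixed status) species.

    Returns a frame indexed by plot_id with columns ``ra_am_woody``,
    ``ra_am_herb``, ``rr_am_woody``, ``rr_am_herb``, ``s_am_herb``,
    ``lrr``; missing strata yield NaN.
    """
    sp_w = species_weights(traits, w_mixed)
    col_species = cover.columns.get_level_values(0)
    col_stratum = cover.columns.get_level_values(1).to_numpy()
    col_weights = sp_w.reindex(col_species).to_numpy()

    vals = cover.to_numpy(float)
    out = pd.DataFrame(index=cover.index)
    totals = {}
    for stratum in STRATA:
        in_s = col_stratum == stratum
        w = col_weights[in_s]
        keep = ~np.isnan(w)
        sub = vals[:, in_s]
        known = sub[:, keep]
        wk = w[keep]
        denom = known.sum(axis=1)
        num = known @ wk
        ra = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        pres = known > 0
        s_tot = pres.sum(axis=1)
        s_am = pres @ wk
        rr = np.where(s_tot > 0, s_am / np.where(s_tot > 0, s_tot, 1.0), np.nan)
        key = "herb" if stratum == "herbaceous" else "woody"
        out[f"ra_am_{key}"] = ra
        out[f"rr_am_{key}"] = rr
        if stratum == "herbaceous":
            out["s_am_herb"] = np.where(s_tot > 0, s_am, np.nan)
        totals[stratum] = sub.sum(axis=1)  # all species incl. unknown status

    herb_t, woody_t = totals["herbaceous"], totals["woody"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["lrr"] = np.where(
            (herb_t > 0) & (woody_t > 0), np.log(herb_t / woody_t), np.nan
        )
    return out


@dataclass
class StrataComparison:
    """Paired comparison of a per-plot metric between understory and canopy."""

    mean_herb: float
    mean_woody: float
    t: float
    p_value: float
    n: int
    paired: bool = True


def compare_strata(
    herb: pd.Series | np.ndarray, woody: pd.Series | np.ndarray, paired: bool = True
) -> StrataComparison:
    """Test whether a metric differs between the two strata.

    Default is a paired (per-plot) t test on the within-plot differences;
    ``paired=False`` gives the two-sample Welch test.  A constant nonzero
    difference with zero variance is reported as t = +/-inf, p = 0.
    """
    a = np.asarray(herb, float)
    b = np.asarray(woody, float)
    if paired:
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if a.size < 3:
            raise ValueError(f"need >= 3 complete pairs, got {a.size}")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = float(np.sign(d.mean()) * np.inf), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
        n = a.size
    else:
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if min(a.size, b.size) < 3:
            raise ValueError("need >= 3 values per stratum")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        n = a.size + b.size
    return StrataComparison(
        mean_herb=float(np.mean(a)),
        mean_woody=float(np.mean(b)),
        t=float(t),
        p_value=float(p),
        n=int(n),
        paired=paired,
    )
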