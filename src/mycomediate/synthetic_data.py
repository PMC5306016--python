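"""Synthetic vegetation-plot bundles with known ground truth.

The generator emulates the structure of a regional ancient-forest survey:
plots clustered in forests, spatially autocorrelated environmental
gradients, a species pool split into woody and herbaceous life forms with
mycorrhizal status classes and Ellenberg-style niche optima, ordinal
Braun-Blanquet cover codes, and a saturating (breakpoint) mediation effect
of the AM woody community on the AM herbaceous community.

Design of the mediation mechanism
---------------------------------
Each plot receives an idiosyncratic target for the (weight-0.5) relative
abundance of AM woody plants, ``p_s``, drawn iid from a low-concentrated
Beta distribution; the environment shapes *which* species occur (so
Ellenberg inference has signal) but not the AM share itself, so that with
the mediation effect switched off the predictor and the responses are
independent by construction and null calibration is exact.  The mediation
signal is ``min(p_s, psi_star)`` -- linear below the breakpoint, flat
above:

* the cover share of obligately AM herbs rises with slope ``beta_med``,
* AM herb occupancy (richness share) rises with slope ``beta_rich``,
* the cover share of facultatively AM (mixed-status) herbs *falls*
  (competitive displacement by obligate specialists) with slope
  ``mixed_suppression * beta_med``.

Because nearly all AM-capable woody cover sits in mixed-status species and
the facultative herb share carries an opposite-signed signal, recomputing
the metrics with extreme mixed weights (0 or 1) degrades the relationship
-- the pattern the weight-sensitivity scan is designed to detect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .io_model import VAN_DER_MAAREL, InputBundle, write_inputs

__all__ = [
    "SyntheticTruth",
    "SyntheticBundle",
    "generate",
    "write_bundle",
    "make_alt_traits",
    "make_confounded_triple",
]

_CODE_BY_VALUE = {int(v): k for k, v in VAN_DER_MAAREL.items()}


@dataclass
class SyntheticTruth:
    """Generator parameters; the defaults are the study conditions."""

    seed: int = 0
    n_plots: int = 415
    n_forests: int = 77
    region_size: float = 40000.0  # metres
    forest_sd: float = 120.0

    # species pool (220 total; unknown status only among herbs)
    n_woody_am_only: int = 2
    n_woody_am_mixed: int = 22
    n_woody_non_am: int = 36
    n_herb_am_only: int = 45
    n_herb_am_mixed: int = 30
    n_herb_non_am: int = 50
    n_herb_unknown: int = 35

    # environment (R, N, F axes)
    env_range: float = 4000.0
    env_nugget: float = 0.2
    env_means: tuple = (6.0, 5.7, 6.0)
    env_sds: tuple = (1.0, 0.85, 0.8)
    optimum_sd: float = 2.0
    niche_sd: float = 0.85
    indifferent_prob: float = 0.08
    missing_prob: float = 0.05

    # mediation mechanism
    psi_star: float = 0.043
    beta_med: float = 1.6
    beta_rich: float = 2.0
    mixed_suppression: float = 1.0  # fraction of beta_med removed from mixed herbs
    woody_share_a: float = 1.2  # Beta parameters of the p_s targets
    woody_share_b: float = 14.0

    # community assembly
    woody_richness: int = 10
    woody_richness_extra: float = 4.0  # Poisson mean on top
    herb_richness: int = 12
    herb_richness_extra: float = 16.0
    base_rich_share: float = 0.18
    rich_noise_sd: float = 0.03
    base_only_share: float = 0.05
    only_noise_sd: float = 0.015
    mixed_share_mean: float = 0.10
    mixed_share_sd: float = 0.05
    herb_mixed_frac: float = 0.16  # occupancy fraction of mixed-status herbs
    herb_unknown_frac: float = 0.12
    woody_only_occ: float = 0.12  # occurrence prob of each obligate-AM woody sp.
    cover_ln_mean_woody: float = 1.2
    cover_ln_mean_herb: float = 1.0
    cover_ln_sd: float = 0.55

    # observation layer
    discretize: bool = True
    n_ph_plots: int = 126
    ph_slope: float = 0.55
    ph_intercept: float = 1.2
    ph_noise_sd: float = 0.05

    def null(self) -> "SyntheticTruth":
        """Copy with the mediation effect switched off."""
        d = asdict(self)
        d.update(beta_med=0.0, beta_rich=0.0)
        return SyntheticTruth(**d)


@dataclass
class SyntheticBundle:
    """Generated bundle plus the retained per-plot ground truth."""

    records: pd.DataFrame  # plot_id, species_id, stratum, bb_code, value
    traits: pd.DataFrame
    meta: pd.DataFrame
    plot_truth: pd.DataFrame
    truth: SyntheticTruth

    def to_input_bundle(self) -> InputBundle:
        if not self.truth.discretize:
            raise ValueError(
                "continuous covers carry no Braun-Blanquet codes; "
                "generate with discretize=True for a readable bundle"
            )
        return InputBundle(
            records=self.records[["plot_id", "species_id", "stratum", "bb_code"]].copy(),
            traits=self.traits,
            meta=self.meta,
        )

    def cover_matrix(self) -> pd.DataFrame:
        """Plots x (species, stratum) matrix of the generated cover values."""
        return (
            self.records.pivot_table(
                index="plot_id",
                columns=["species_id", "stratum"],
                values="value",
                aggfunc="sum",
                fill_value=0.0,
            )
            .astype(float)
        )


def _spatial_field(L: np.ndarray, rng: np.random.Generator, mean, sd) -> np.ndarray:
    return np.clip(mean + sd * (L @ rng.standard_normal(L.shape[0])), 1.0, 9.0)


def _species_pool(truth: SyntheticTruth, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counts = [
        ("woody", "AM_ONLY", truth.n_woody_am_only),
        ("woody", "AM_MIXED", truth.n_woody_am_mixed),
        ("woody", "NON_AM", truth.n_woody_non_am),
        ("herbaceous", "AM_ONLY", truth.n_herb_am_only),
        ("herbaceous", "AM_MIXED", truth.n_herb_am_mixed),
        ("herbaceous", "NON_AM", truth.n_herb_non_am),
        ("herbaceous", "UNKNOWN", truth.n_herb_unknown),
    ]
    w_i = h_i = 0
    for life_form, status, k in counts:
        for _ in range(k):
            if life_form == "woody":
                w_i += 1
                sid = f"W{w_i:03d}"
            else:
                h_i += 1
                sid = f"H{h_i:03d}"
            rows.append({"species_id": sid, "life_form": life_form, "myc_status": status})
    pool = pd.DataFrame(rows)
    n_sp = len(pool)
    for ax, (mean, _) in zip("RNF", zip(truth.env_means, truth.env_sds)):
        opt = rng.normal(mean, truth.optimum_sd, n_sp)
        pool[f"opt_{ax}"] = opt
        val = np.round(np.clip(opt, 1, 9))
        indiff = rng.random(n_sp) < truth.indifferent_prob
        missing = ~indiff & (rng.random(n_sp) < truth.missing_prob)
        pool[f"ellenberg_{ax}"] = np.where(indiff | missing, np.nan, val)
        pool[f"indifferent_{ax}"] = indiff
    return pool


def _weighted_sample(rng, pool_idx, weights, k):
    if k <= 0 or pool_idx.size == 0:
        return np.empty(0, dtype=int)
    k = min(k, pool_idx.size)
    w = weights + 1e-12
    return rng.choice(pool_idx, size=k, replace=False, p=w / w.sum())


def generate(truth: SyntheticTruth | None = None) -> SyntheticBundle:
    """Generate a complete synthetic bundle under ``truth``.

    Raises ValueError before building anything if the breakpoint cannot
    fall inside the support of the woody AM share targets.
    """
    truth = truth or SyntheticTruth()
    if not 0 < truth.psi_star < 1:
        raise ValueError("psi_star must lie in (0, 1)")
    mean_p = truth.woody_share_a / (truth.woody_share_a + truth.woody_share_b)
    if truth.psi_star >= 6 * mean_p:
        raise ValueError(
            "psi_star lies outside the bulk of the woody AM share distribution"
        )
    rng = np.random.default_rng(truth.seed)

    # --- plots and environment -------------------------------------------
    n = truth.n_plots
    centers = rng.uniform(0, truth.region_size, size=(truth.n_forests, 2))
    forest_of = np.sort(np.concatenate([
        np.arange(truth.n_forests),
        rng.integers(0, truth.n_forests, n - truth.n_forests),
    ]))
    coords = centers[forest_of] + rng.normal(0, truth.forest_sd, size=(n, 2))
    dist = squareform(pdist(coords))
    corr = (1 - truth.env_nugget) * np.exp(-dist / truth.env_range)
    np.fill_diagonal(corr, 1.0)
    L = cholesky(corr + 1e-10 * np.eye(n), lower=True)
    env = np.column_stack([
        _spatial_field(L, rng, m, s) for m, s in zip(truth.env_means, truth.env_sds)
    ])

    pool = _species_pool(truth, rng)
    opt = pool[["opt_R", "opt_N", "opt_F"]].to_numpy()
    # plots x species niche suitability
    suit = np.exp(
        -np.sum((env[:, None, :] - opt[None, :, :]) ** 2, axis=2)
        / (2 * truth.niche_sd**2)
    )
    lf = pool["life_form"].to_numpy()
    st = pool["myc_status"].to_numpy()
    idx_w_only = np.flatnonzero((lf == "woody") & (st == "AM_ONLY"))
    idx_w_mix = np.flatnonzero((lf == "woody") & (st == "AM_MIXED"))
    idx_w_non = np.flatnonzero((lf == "woody") & (st == "NON_AM"))
    idx_h = {
        s: np.flatnonzero((lf == "herbaceous") & (st == s))
        for s in ("AM_ONLY", "AM_MIXED", "NON_AM", "UNKNOWN")
    }

    # --- per-plot targets (iid; mediation via min(p, psi)) ----------------
    p_t = rng.beta(truth.woody_share_a, truth.woody_share_b, n)
    signal = np.minimum(p_t, truth.psi_star)
    q_t = np.clip(
        truth.base_rich_share + truth.beta_rich * signal
        + rng.normal(0, truth.rich_noise_sd, n),
        0.02, 0.6,
    )
    h_only_t = np.clip(
        truth.base_only_share + truth.beta_med * signal
        + rng.normal(0, truth.only_noise_sd, n),
        0.005, 0.6,
    )
    h_mix_t = np.clip(
        truth.mixed_share_mean - truth.mixed_suppression * truth.beta_med * signal
        + rng.normal(0, truth.mixed_share_sd, n),
        0.005, 0.6,
    )

    plot_ids = np.array([f"P{i + 1:04d}" for i in range(n)])
    rec_plot, rec_sp, rec_stratum, rec_val = [], [], [], []
    tr_rows = []
    ln_sd = truth.cover_ln_sd

    for s in range(n):
        # ---- woody stratum ----
        n_w = truth.woody_richness + rng.poisson(truth.woody_richness_extra)
        only = idx_w_only[rng.random(idx_w_only.size) < truth.woody_only_occ]
        k_mix = min(3 + rng.poisson(1.0), idx_w_mix.size)
        mix = _weighted_sample(rng, idx_w_mix, suit[s, idx_w_mix], k_mix)
        k_non = max(n_w - only.size - mix.size, 2)
        non = _weighted_sample(rng, idx_w_non, suit[s, idx_w_non], k_non)
        c_only = 0.3 * np.exp(rng.normal(truth.cover_ln_mean_woody, ln_sd, only.size))
        c_mix = np.exp(rng.normal(truth.cover_ln_mean_woody, ln_sd, mix.size))
        c_non = np.exp(rng.normal(truth.cover_ln_mean_woody, ln_sd, non.size))
        co, cm, cn = c_only.sum(), c_mix.sum(), c_non.sum()
        p = p_t[s]
        if cm > 0 and p < 0.5:
            lam = (p * (co + cn) - co * (1 - p)) / (cm * (0.5 - p))
            lam = min(max(lam, 0.0), 9.0 / max(c_mix.max(), 1e-9))
        else:
            lam = 1.0
        c_mix = lam * c_mix
        denom_w = co + c_mix.sum() + cn
        ra_w = (co + 0.5 * c_mix.sum()) / denom_w if denom_w > 0 else np.nan

        # ---- herbaceous stratum ----
        S = truth.herb_richness + rng.poisson(truth.herb_richness_extra)
        pi_only = np.clip(
            q_t[s] * (1 - truth.herb_unknown_frac) - 0.5 * truth.herb_mixed_frac,
            0.01, 0.6,
        )
        probs = np.array([
            pi_only,
            truth.herb_mixed_frac,
            truth.herb_unknown_frac,
            max(1 - pi_only - truth.herb_mixed_frac - truth.herb_unknown_frac, 0.01),
        ])
        k_ho, k_hm, k_hu, k_hn = rng.multinomial(S, probs / probs.sum())
        k_hn = max(k_hn, 2)
        ho = _weighted_sample(rng, idx_h["AM_ONLY"], suit[s, idx_h["AM_ONLY"]], k_ho)
        hm = _weighted_sample(rng, idx_h["AM_MIXED"], suit[s, idx_h["AM_MIXED"]], k_hm)
        hu = _weighted_sample(rng, idx_h["UNKNOWN"], suit[s, idx_h["UNKNOWN"]], k_hu)
        hn = _weighted_sample(rng, idx_h["NON_AM"], suit[s, idx_h["NON_AM"]], k_hn)
        c_ho = np.exp(rng.normal(truth.cover_ln_mean_herb, ln_sd, ho.size))
        c_hm = np.exp(rng.normal(truth.cover_ln_mean_herb, ln_sd, hm.size))
        c_hu = np.exp(rng.normal(truth.cover_ln_mean_herb, ln_sd, hu.size))
        c_hn = np.exp(rng.normal(truth.cover_ln_mean_herb, ln_sd, hn.size))
        cn_h = c_hn.sum()
        rest = max(1.0 - h_only_t[s] - h_mix_t[s], 0.2)
        D = cn_h / rest if cn_h > 0 else 1.0
        if ho.size:
            lam_o = h_only_t[s] * D / c_ho.sum()
            c_ho = np.minimum(lam_o, 9.0 / max(c_ho.max(), 1e-9)) * c_ho
        if hm.size:
            lam_m = h_mix_t[s] * D / c_hm.sum()
            c_hm = np.minimum(lam_m, 9.0 / max(c_hm.max(), 1e-9)) * c_hm
        denom_h = c_ho.sum() + c_hm.sum() + cn_h
        ra_h = (c_ho.sum() + 0.5 * c_hm.sum()) / denom_h if denom_h > 0 else np.nan
        s_known = ho.size + hm.size + hn.size
        rr_h = (ho.size + 0.5 * hm.size) / s_known if s_known else np.nan

        sp_idx = np.concatenate([only, mix, non, ho, hm, hu, hn])
        covers = np.concatenate([c_only, c_mix, c_non, c_ho, c_hm, c_hu, c_hn])
        strata = np.array(
            ["woody"] * (only.size + mix.size + non.size)
            + ["herbaceous"] * (ho.size + hm.size + hu.size + hn.size)
        )
        rec_plot.append(np.repeat(plot_ids[s], sp_idx.size))
        rec_sp.append(sp_idx)
        rec_stratum.append(strata)
        rec_val.append(covers)
        tr_rows.append((ra_w, ra_h, rr_h))

    records = pd.DataFrame(
        {
            "plot_id": np.concatenate(rec_plot),
            "species_id": pool["species_id"].to_numpy()[np.concatenate(rec_sp)],
            "stratum": np.concatenate(rec_stratum),
            "value": np.concatenate(rec_val),
        }
    )
    if truth.discretize:
        # round to the nearest ordinal value; covers below 0.5 fall under the
        # detection limit and the species goes unrecorded in that plot
        ordinal = np.minimum(np.round(records["value"]), 9).astype(int)
        records = records.loc[ordinal >= 1].reset_index(drop=True)
        ordinal = ordinal[ordinal >= 1].reset_index(drop=True)
        records["value"] = ordinal.astype(float)
        records["bb_code"] = ordinal.map(_CODE_BY_VALUE)
    else:
        records["bb_code"] = ""

    traits = pool.drop(columns=["opt_R", "opt_N", "opt_F"]).set_index("species_id")
    for ax in "RNF":
        traits[f"ellenberg_{ax}"] = traits[f"ellenberg_{ax}"].astype(float)

    meta = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "area": rng.choice([100.0, 200.0, 300.0, 400.0], n),
            "forest_id": [f"F{f + 1:02d}" for f in forest_of],
            "measured_ph": np.nan,
        }
    ).set_index("plot_id")
    ph_plots = rng.choice(n, size=min(truth.n_ph_plots, n), replace=False)
    meta.iloc[ph_plots, meta.columns.get_loc("measured_ph")] = (
        truth.ph_intercept
        + truth.ph_slope * env[ph_plots, 0]
        + rng.normal(0, truth.ph_noise_sd, ph_plots.size)
    )

    realized = np.array(tr_rows)
    plot_truth = pd.DataFrame(
        {
            "p_target": p_t,
            "q_target": q_t,
            "h_only_target": h_only_t,
            "h_mixed_target": h_mix_t,
            "ra_am_woody": realized[:, 0],
            "ra_am_herb": realized[:, 1],
            "rr_am_herb": realized[:, 2],
            "env_R": env[:, 0],
            "env_N": env[:, 1],
            "env_F": env[:, 2],
        },
        index=pd.Index(plot_ids, name="plot_id"),
    )
    return SyntheticBundle(
        records=records, traits=traits, meta=meta, plot_truth=plot_truth, truth=truth
    )


def write_bundle(sb: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write plots.tsv / traits.tsv / plots_meta.tsv / truth.json."""
    out = Path(out_dir)
    paths = write_inputs(sb.to_input_bundle(), out)
    truth_path = out / "truth.json"
    payload = {"truth": asdict(sb.truth), "plot_truth": sb.plot_truth.reset_index().to_dict("list")}
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return paths


_ADJACENT = {"AM_ONLY": ["AM_MIXED"], "AM_MIXED": ["AM_ONLY", "NON_AM"], "NON_AM": ["AM_MIXED"]}


def make_alt_traits(traits: pd.DataFrame, flip_fraction: float, seed: int = 0) -> pd.DataFrame:
    """Alternative mycorrhizal-status table with a fraction of species flipped.

    Exactly ``ceil(flip_fraction * n_known)`` known-status species are moved
    to an adjacent status class (AM_ONLY <-> AM_MIXED <-> NON_AM), emulating
    disagreement between trait databases.  Deterministic under ``seed``.
    """
    if not 0.0 <= flip_fraction <= 0.5:
        raise ValueError("flip_fraction must be in [0, 0.5]")
    alt = traits.copy()
    known = alt.index[alt["myc_status"] != "UNKNOWN"]
    n_flip = int(np.ceil(flip_fraction * known.size))
    if n_flip == 0:
        return alt
    rng = np.random.default_rng(seed)
    chosen = rng.choice(known.to_numpy(), size=n_flip, replace=False)
    for sid in chosen:
        options = _ADJACENT[alt.at[sid, "myc_status"]]
        alt.at[sid, "myc_status"] = options[rng.integers(len(options))]
    return alt


def make_confounded_triple(
    n: int,
    alpha: float = 0.6,
    beta: float = 0.4,
    gamma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Plot table where one environmental axis truly confounds the mediation.

    ``e_R`` drives both the woody AM share (strength ``alpha``) and the
    herb AM share (``gamma``) on top of the direct mediation path
    (``beta``); ``e_N``, ``e_F`` and ``lrr`` are decoy covariates only
    weakly tied to the confounder.  Used for path-model recovery checks.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x = alpha * z + np.sqrt(max(1 - alpha**2, 0.05)) * rng.standard_normal(n)
    y = beta * x + gamma * z + rng.standard_normal(n)
    return pd.DataFrame(
        {
            "e_R": z,
            "e_N": 0.35 * z + rng.standard_normal(n),
            "e_F": 0.2 * z + rng.standard_normal(n),
            "lrr": 0.25 * x + rng.standard_normal(n),
            "ra_am_woody": x,
            "ra_am_herb": y,
        }
    )
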