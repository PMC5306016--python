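import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from mycomediate.community_metrics import compute_plot_metrics
from mycomediate.io_model import convert_bb_to_cover
from mycomediate.pipeline import AnalysisConfig, run_abundance_analysis
from mycomediate.synthetic_data import (
    SyntheticTruth,
    generate,
    make_alt_traits,
    make_confounded_triple,
)


def test_default_bundle_matches_survey_structure(small_bundle):
    sb = small_bundle
    assert sb.traits.shape[0] == 220
    assert (sb.traits["myc_status"] == "UNKNOWN").sum() == 35
    woody = sb.traits[sb.traits["life_form"] == "woody"]
    assert (woody["myc_status"] == "UNKNOWN").sum() == 0
    assert sb.meta.shape[0] == sb.truth.n_plots
    assert sb.meta["forest_id"].nunique() == sb.truth.n_forests
    assert sb.meta["measured_ph"].notna().sum() == sb.truth.n_ph_plots
    assert set(sb.meta["area"]).issubset({100.0, 200.0, 300.0, 400.0})


def test_generated_bundle_passes_input_validation(small_bundle, tmp_path):
    from mycomediate.io_model import read_inputs
    from mycomediate.synthetic_data import write_bundle

    paths = write_bundle(small_bundle, tmp_path / "bundle")
    bundle = read_inputs(paths["plots"], paths["traits"], paths["meta"])
    cover = convert_bb_to_cover(bundle.records)
    assert (cover.sum(axis=1) > 0).all()
    assert cover.shape[0] == small_bundle.truth.n_plots


def test_identity_path_without_noise_or_discretization():
    """With noise off and continuous covers, computed metrics equal the
    generator's internal continuous values exactly."""
    truth = SyntheticTruth(
        seed=3, n_plots=60, n_forests=12, n_ph_plots=10, discretize=False,
        rich_noise_sd=0.0, only_noise_sd=0.0, mixed_share_sd=0.0,
    )
    sb = generate(truth)
    m = compute_plot_metrics(sb.cover_matrix(), sb.traits, w_mixed=0.5)
    pt = sb.plot_truth.loc[m.index]
    np.testing.assert_allclose(m["ra_am_woody"], pt["ra_am_woody"], atol=1e-10)
    np.testing.assert_allclose(m["ra_am_herb"], pt["ra_am_herb"], atol=1e-10)
    np.testing.assert_allclose(m["rr_am_herb"], pt["rr_am_herb"], atol=1e-10)
    # and with zero noise the abundance shares equal the target formula
    # wherever the assembly could realize the target (no clamping)
    signal = np.minimum(pt["p_target"], truth.psi_star)
    expect = truth.base_only_share + truth.beta_med * signal \
        + 0.5 * (truth.mixed_share_mean - truth.mixed_suppression * truth.beta_med * signal)
    close = np.isclose(m["ra_am_herb"], expect, atol=5e-3)
    assert close.mean() > 0.9


def test_discretization_roundtrip_bias_is_small(small_bundle):
    """Ordinal coding + detection limit only mildly perturbs the shares."""
    m = compute_plot_metrics(small_bundle.cover_matrix(), small_bundle.traits, 0.5)
    pt = small_bundle.plot_truth.loc[m.index]
    bias = np.nanmean(np.abs(m["ra_am_woody"] - pt["ra_am_woody"]))
    assert bias < 0.02
    assert np.corrcoef(m["ra_am_woody"], pt["ra_am_woody"])[0, 1] > 0.85


def test_alt_traits_flip_counts_and_adjacency(small_bundle):
    traits = small_bundle.traits
    assert make_alt_traits(traits, 0.0).equals(traits)
    alt = make_alt_traits(traits, 0.1, seed=4)
    changed = (alt["myc_status"] != traits["myc_status"]).sum()
    n_known = (traits["myc_status"] != "UNKNOWN").sum()
    assert changed == int(np.ceil(0.1 * n_known))
    moved = traits.loc[alt["myc_status"] != traits["myc_status"], "myc_status"]
    pairs = set(zip(moved, alt.loc[moved.index, "myc_status"]))
    allowed = {("AM_ONLY", "AM_MIXED"), ("AM_MIXED", "AM_ONLY"),
               ("AM_MIXED", "NON_AM"), ("NON_AM", "AM_MIXED")}
    assert pairs.issubset(allowed)
    # deterministic under the seed
    assert make_alt_traits(traits, 0.1, seed=4).equals(alt)


def test_mediation_dose_response_is_monotone():
    """Expected below-breakpoint slope rises with the mediation effect."""
    cfg = AnalysisConfig(spatial=False)
    means = []
    for beta in (0.4, 1.6, 2.8):
        slopes = []
        for rep in range(15):
            truth = dataclasses.replace(
                SyntheticTruth(seed=900 + rep), n_plots=200, n_forests=40,
                beta_med=beta, n_ph_plots=30,
            )
            sb = generate(truth)
            m = compute_plot_metrics(sb.cover_matrix(), sb.traits, 0.5)
            res = run_abundance_analysis(m, sb.meta, cfg, n_boot=0)
            slopes.append(res.slope)
        means.append(np.mean(slopes))
    assert means[0] < means[1] < means[2]


def test_environment_field_decays_with_distance(small_bundle):
    """Pair correlation of the gradient field falls off with distance."""
    env = small_bundle.plot_truth["env_R"].to_numpy()
    xy = small_bundle.meta[["x", "y"]].to_numpy()
    z = (env - env.mean()) / env.std()
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    prod = np.outer(z, z)
    iu = np.triu_indices(len(z), 1)
    d, prod = d[iu], prod[iu]
    bins = [0, 2000, 8000, 60000]
    cors = [prod[(d >= lo) & (d < hi)].mean() for lo, hi in zip(bins, bins[1:])]
    assert cors[0] > cors[-1]
    expected = [np.exp(-np.median(d[(d >= lo) & (d < hi)]) / small_bundle.truth.env_range)
                for lo, hi in zip(bins, bins[1:])]
    assert st.spearmanr(cors, expected).statistic > 0


def test_infeasible_breakpoint_rejected():
    with pytest.raises(ValueError, match="psi_star"):
        generate(SyntheticTruth(psi_star=0.9, n_plots=30, n_forests=6))


def test_confounded_triple_has_designed_structure():
    df = make_confounded_triple(5000, alpha=0.6, beta=0.4, gamma=0.5, seed=0)
    assert np.corrcoef(df["e_R"], df["ra_am_woody"])[0, 1] == pytest.approx(0.6, abs=0.05)
    # confounder correlates with response more than the decoys do
    r_true = abs(np.corrcoef(df["e_R"], df["ra_am_herb"])[0, 1])
    r_decoy = abs(np.corrcoef(df["e_F"], df["ra_am_herb"])[0, 1])
    assert r_true > r_decoy
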