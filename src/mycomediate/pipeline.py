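"""Orchestration of the full mediation analysis.

Stage order mirrors the analysis chain: per-plot metrics -> strata
comparisons -> Ellenberg inference and pH validation -> richness test
(Kendall tau, full plot set, no spatial correction) -> segmented
regression on the abundance response, restriction to plots below the
breakpoint, and plain + spatial GLS fits on the restricted subset ->
path models and marginal residual tests on the subset -> mixed-weight
sensitivity scan (optionally with an alternative trait source).

Every stage writes a result record into :class:`AnalysisReport`; a global
seed deterministically derives per-stage seeds so stages can be re-run in
isolation and a re-run of the whole report is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from . import __version__
from .community_metrics import StrataComparison, compare_strata, compute_plot_metrics
from .ellenberg import PhValidation, attach_indicators, infer_indicator, validate_inferred_ph
from .io_model import INDICATORS, InputBundle, convert_bb_to_cover
from .path_analysis import (
    combined_structure,
    fit_path_model,
    marginal_residual_test,
    select_model,
    three_variable_structure,
)
from .stats_core import AssociationTest, SegmentedFit, SpatialGLSFit, fit_segmented, fit_spatial_gls

__all__ = [
    "AnalysisConfig",
    "AbundanceResult",
    "AnalysisReport",
    "load_config",
    "run_richness_analysis",
    "run_abundance_analysis",
    "run_path_models",
    "run_sensitivity",
    "run_all",
]

_ALL_STAGES = ("strata", "ellenberg", "richness", "abundance", "paths", "sensitivity")


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + 7919 * (k + 1)) % (2**31)


@dataclass
class AnalysisConfig:
    """Tunable switches of the pipeline; defaults follow the main analysis."""

    w_mixed: float = 0.5
    herb_only_indicators: bool = False
    seg_grid: int = 200
    bootstrap_reps: int = 500
    material_delta_aic: float = 6.0
    spatial: bool = True
    sensitivity_spatial: bool = True
    sensitivity_weights: tuple = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    reestimate_breakpoint: bool = True
    bh_correction: bool = False
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _ALL_STAGES})

    def stage_on(self, name: str) -> bool:
        return bool(self.stages.get(name, True))


def load_config(path: str | Path) -> tuple[AnalysisConfig, dict]:
    """Read config.yaml; returns (AnalysisConfig, extras incl. conversion table)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    extras = {"conversion": raw.pop("conversion", None), "bb_dialect": raw.pop("bb_dialect", None)}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    if "sensitivity_weights" in cfg_kwargs:
        cfg_kwargs["sensitivity_weights"] = tuple(cfg_kwargs["sensitivity_weights"])
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return AnalysisConfig(**cfg_kwargs), extras


def run_richness_analysis(metrics: pd.DataFrame) -> dict:
    """Kendall tau of AM herb relative (and absolute) richness vs AM woody share.

    Full plot set, no breakpoint restriction and no spatial correction:
    the rank-based test over the whole gradient is the designed analysis
    for the richness response.
    """
    from .stats_core import kendall_tau

    df = metrics[["ra_am_woody", "rr_am_herb", "s_am_herb"]].dropna(
        subset=["ra_am_woody", "rr_am_herb"]
    )
    if len(df) < 10:
        raise ValueError(f"need >= 10 plots with both metrics, got {len(df)}")
    rel = kendall_tau(df["ra_am_woody"].to_numpy(), df["rr_am_herb"].to_numpy())
    out = {"relative": rel, "absolute": None}
    abs_df = df.dropna(subset=["s_am_herb"])
    if len(abs_df) >= 10:
        out["absolute"] = kendall_tau(
            abs_df["ra_am_woody"].to_numpy(), abs_df["s_am_herb"].to_numpy()
        )
    return out


@dataclass
class AbundanceResult:
    """Segmented fit plus the breakpoint-restricted (or fallback) tests."""

    seg: SegmentedFit
    restricted: bool
    n_used: int
    slope: float
    t_plain: float
    p_plain: float
    gls: SpatialGLSFit | None
    subset_index: pd.Index


def run_abundance_analysis(
    metrics: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    n_boot: int | None = None,
) -> AbundanceResult:
    """Breakpoint search and restricted-subset fits for the abundance response.

    When the segmented model is not materially better than a single line
    (grid-selection-aware AIC margin), the restriction is skipped and the
    tests run on the full plot set, flagged accordingly.
    """
    config = config or AnalysisConfig()
    df = metrics[["ra_am_woody", "ra_am_herb"]].dropna()
    x = df["ra_am_woody"].to_numpy()
    y = df["ra_am_herb"].to_numpy()
    seg = fit_segmented(
        x,
        y,
        n_grid=config.seg_grid,
        n_boot=config.bootstrap_reps if n_boot is None else n_boot,
        seed=_derive_seed(config.seed, 2),
        material_delta_aic=config.material_delta_aic,
    )
    if seg.material:
        sub = df[df["ra_am_woody"] < seg.psi]
        restricted = True
        if len(sub) < 10:
            raise ValueError(f"restricted subset too small ({len(sub)} plots)")
    else:
        sub = df
        restricted = False
    xs = sub["ra_am_woody"].to_numpy()
    ys = sub["ra_am_herb"].to_numpy()
    ols = sm.OLS(ys, sm.add_constant(xs)).fit()
    gls = None
    if config.spatial:
        coords = meta.loc[sub.index, ["x", "y"]].to_numpy(float)
        gls = fit_spatial_gls(
            sm.add_constant(xs),
            ys,
            coords,
            correlation="exp_nugget",
            seed=_derive_seed(config.seed, 3),
            names=["intercept", "ra_am_woody"],
        )
    return AbundanceResult(
        seg=seg,
        restricted=restricted,
        n_used=len(sub),
        slope=float(ols.params[1]),
        t_plain=float(ols.tvalues[1]),
        p_plain=float(ols.pvalues[1]),
        gls=gls,
        subset_index=sub.index,
    )


_SEM_IDS = {"e_R": "SEM1_R", "e_N": "SEM2_N", "e_F": "SEM3_F", "lrr": "SEM4_biotic"}


def run_path_models(metrics: pd.DataFrame, subset_index=None) -> dict:
    """Fit the five path models and both marginal residual tests.

    Uses complete cases across all six variables so the model AICs are
    comparable; spatial dependencies are deliberately not modelled here.
    """
    cols = ["ra_am_woody", "ra_am_herb", "e_R", "e_N", "e_F", "lrr"]
    df = metrics.loc[subset_index] if subset_index is not None else metrics
    df = df[cols].dropna()
    fits = []
    for cov, model_id in _SEM_IDS.items():
        fits.append(
            fit_path_model(
                df,
                three_variable_structure(cov, "ra_am_woody", "ra_am_herb"),
                model_id=model_id,
            )
        )
    abiotic = [f for f in fits if f.model_id.startswith("SEM1")
               or f.model_id.startswith("SEM2") or f.model_id.startswith("SEM3")]
    best_abiotic = min(abiotic, key=lambda f: (f.aic, f.model_id))
    best_cov = {"SEM1_R": "e_R", "SEM2_N": "e_N", "SEM3_F": "e_F"}[best_abiotic.model_id]
    fits.append(
        fit_path_model(
            df,
            combined_structure(best_cov, "lrr", "ra_am_woody", "ra_am_herb"),
            model_id="SEM5_combined",
        )
    )
    ranking = select_model(fits)
    marginal_abiotic = marginal_residual_test(
        df, "ra_am_herb", ["e_R", "e_N", "e_F"], "ra_am_woody", branch="parametric"
    )
    marginal_combined = marginal_residual_test(
        df, "ra_am_herb", ["e_R", "e_N", "e_F", "lrr"], "ra_am_woody",
        branch="nonparametric",
    )
    return {
        "fits": fits,
        "ranking": ranking,
        "marginal_abiotic": marginal_abiotic,
        "marginal_combined": marginal_combined,
        "n": int(len(df)),
    }


def run_sensitivity(
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    meta: pd.DataFrame,
    config: AnalysisConfig | None = None,
    base_psi: float | None = None,
) -> pd.DataFrame:
    """Mixed-weight sensitivity scan of the abundance relationship.

    For every weight on the grid the per-plot metrics are recomputed, the
    breakpoint re-estimated (or reused when
    ``config.reestimate_breakpoint`` is False and ``base_psi`` given) and
    the restricted-subset tests repeated with and (optionally) without the
    spatial correlation structure.  Failures at a single weight are
    recorded in-row and the scan continues.
    """
    config = config or AnalysisConfig()
    rows = []
    for w in config.sensitivity_weights:
        row = {
            "w_mixed": float(w), "psi": np.nan, "restricted": False, "n": 0,
            "slope": np.nan, "t_plain": np.nan, "p_plain": np.nan,
            "t_spatial": np.nan, "p_spatial": np.nan, "error": "",
        }
        try:
            m = compute_plot_metrics(cover, traits, w_mixed=float(w))
            scan_cfg = dataclasses.replace(
                config, w_mixed=float(w), spatial=config.sensitivity_spatial
            )
            if not config.reestimate_breakpoint and base_psi is not None:
                df = m[["ra_am_woody", "ra_am_herb"]].dropna()
                sub = df[df["ra_am_woody"] < base_psi]
                if len(sub) < 10:
                    raise ValueError("restricted subset too small")
                ols = sm.OLS(
                    sub["ra_am_herb"].to_numpy(),
                    sm.add_constant(sub["ra_am_woody"].to_numpy()),
                ).fit()
                row.update(
                    psi=base_psi, restricted=True, n=len(sub),
                    slope=float(ols.params[1]), t_plain=float(ols.tvalues[1]),
                    p_plain=float(ols.pvalues[1]),
                )
                if config.sensitivity_spatial:
                    gls = fit_spatial_gls(
                        sm.add_constant(sub["ra_am_woody"].to_numpy()),
                        sub["ra_am_herb"].to_numpy(),
                        meta.loc[sub.index, ["x", "y"]].to_numpy(float),
                        seed=_derive_seed(config.seed, 11),
                    )
                    row.update(t_spatial=float(gls.t[1]), p_spatial=float(gls.p[1]))
            else:
                res = run_abundance_analysis(m, meta, scan_cfg, n_boot=0)
                row.update(
                    psi=res.seg.psi if res.seg.material else np.nan,
                    restricted=res.restricted, n=res.n_used, slope=res.slope,
                    t_plain=res.t_plain, p_plain=res.p_plain,
                )
                if res.gls is not None:
                    row.update(t_spatial=float(res.gls.t[1]), p_spatial=float(res.gls.p[1]))
        except (ValueError, RuntimeError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if config.bh_correction:
        from statsmodels.stats.multitest import multipletests

        ok = table["p_plain"].notna()
        if ok.any():
            table.loc[ok, "p_plain_bh"] = multipletests(
                table.loc[ok, "p_plain"], method="fdr_bh"
            )[1]
    return table


@dataclass
class AnalysisReport:
    """Container of all stage records plus run metadata."""

    summary: dict
    metrics: pd.DataFrame
    strata_abundance: StrataComparison | None = None
    strata_richness: StrataComparison | None = None
    indicator_summary: dict | None = None
    ph_validation: PhValidation | None = None
    lrr_herb_am_r: float | None = None
    richness: dict | None = None
    abundance: AbundanceResult | None = None
    paths: dict | None = None
    sensitivity: pd.DataFrame | None = None
    alt_abundance: AbundanceResult | None = None
    alt_richness: dict | None = None
    config: AnalysisConfig | None = None

    def to_dict(self) -> dict:
        def conv(obj):
            if obj is None or isinstance(obj, (int, float, str, bool)):
                return obj
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return [conv(v) for v in obj.tolist()]
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, pd.DataFrame):
                return json.loads(obj.to_json(orient="split", double_precision=10))
            if isinstance(obj, pd.Index):
                return [str(v) for v in obj]
            if dataclasses.is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                        if f.name != "pairs"}
            return str(obj)

        d = {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)
             if f.name != "metrics"}
        d["version"] = __version__
        return d

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.tsv", sep="\t", float_format="%.10g")
        if self.sensitivity is not None:
            self.sensitivity.to_csv(
                out / "sensitivity.tsv", sep="\t", index=False, float_format="%.10g"
            )
        report_path = out / "report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return report_path


def run_all(
    bundle: InputBundle,
    config: AnalysisConfig | None = None,
    alt_traits: pd.DataFrame | None = None,
) -> AnalysisReport:
    """Execute every enabled stage in order and assemble the report."""
    config = config or AnalysisConfig()
    cover = convert_bb_to_cover(bundle.records, bundle.conversion)
    metrics = compute_plot_metrics(cover, bundle.traits, w_mixed=config.w_mixed)
    metrics = attach_indicators(
        metrics, cover, bundle.traits, herb_only=config.herb_only_indicators
    )
    report = AnalysisReport(summary=bundle.summary(), metrics=metrics, config=config)

    if config.stage_on("strata"):
        report.strata_abundance = compare_strata(metrics["ra_am_herb"], metrics["ra_am_woody"])
        report.strata_richness = compare_strata(metrics["rr_am_herb"], metrics["rr_am_woody"])

    if config.stage_on("ellenberg"):
        report.indicator_summary = {
            ind: {
                "min": float(np.nanmin(metrics[f"e_{ind}"])),
                "max": float(np.nanmax(metrics[f"e_{ind}"])),
                "median": float(np.nanmedian(metrics[f"e_{ind}"])),
            }
            for ind in INDICATORS
        }
        if bundle.meta["measured_ph"].notna().sum() >= 3:
            est = infer_indicator(cover, bundle.traits, "R",
                                  herb_only=config.herb_only_indicators)
            report.ph_validation = validate_inferred_ph(est, bundle.meta)
        ok = metrics[["lrr", "ra_am_herb"]].dropna()
        if len(ok) >= 3:
            report.lrr_herb_am_r = float(
                np.corrcoef(ok["lrr"], ok["ra_am_herb"])[0, 1]
            )

    if config.stage_on("richness"):
        report.richness = run_richness_analysis(metrics)

    if config.stage_on("abundance"):
        report.abundance = run_abundance_analysis(metrics, bundle.meta, config)

    if config.stage_on("paths") and report.abundance is not None:
        report.paths = run_path_models(metrics, report.abundance.subset_index)

    if config.stage_on("sensitivity"):
        base_psi = (
            report.abundance.seg.psi
            if report.abundance is not None and report.abundance.seg.material
            else None
        )
        report.sensitivity = run_sensitivity(
            cover, bundle.traits, bundle.meta, config, base_psi=base_psi
        )
        if alt_traits is not None:
            alt_metrics = compute_plot_metrics(cover, alt_traits, w_mixed=0.5)
            report.alt_abundance = run_abundance_analysis(alt_metrics, bundle.meta, config)
            report.alt_richness = run_richness_analysis(alt_metrics)

    return report
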