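"""Data model and IO for Braun-Blanquet vegetation-plot bundles.

A bundle consists of three tab-separated tables:

``plots.tsv``
    Long-format plot x species observations: ``plot_id``, ``species_id``,
    ``stratum`` (``woody`` or ``herbaceous``) and ``bb_code``, an ordinal
    cover-abundance code on the extended Braun-Blanquet scale.
``traits.tsv``
    One row per species: life form, mycorrhizal status class
    (``AM_ONLY`` / ``NON_AM`` / ``AM_MIXED`` / ``UNKNOWN``) and Ellenberg
    indicator values for soil reaction (R), nutrients (N) and moisture (F),
    with ``x`` marking indifferent species and empty cells missing values.
``plots_meta.tsv``
    Per-plot projected coordinates in metres, plot area (m^2), a forest
    cluster identifier and an optional measured soil pH.

Braun-Blanquet codes are converted to numeric abundance with a configurable
code -> value table; the default is the van der Maarel (1979) ordinal
transform for the extended scale (r=1, +=2, 1=3, 2m=4, 2a=5, 2b=6, 3=7,
4=8, 5=9).  Because every downstream metric is a ratio of such values, the
analysis is invariant to rescaling the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VAN_DER_MAAREL",
    "STRATA",
    "MYC_STATUSES",
    "LIFE_FORMS",
    "INDICATORS",
    "InputBundle",
    "read_inputs",
    "write_inputs",
    "read_plot_records",
    "read_traits",
    "read_plot_meta",
    "convert_bb_to_cover",
]

#: Default extended-scale ordinal transform values (van der Maarel 1979).
VAN_DER_MAAREL: dict[str, float] = {
    "r": 1.0,
    "+": 2.0,
    "1": 3.0,
    "2m": 4.0,
    "2a": 5.0,
    "2b": 6.0,
    "3": 7.0,
    "4": 8.0,
    "5": 9.0,
}

STRATA = ("woody", "herbaceous")
LIFE_FORMS = ("woody", "herbaceous")
MYC_STATUSES = ("AM_ONLY", "NON_AM", "AM_MIXED", "UNKNOWN")
INDICATORS = ("R", "N", "F")

_RECORD_COLS = ["plot_id", "species_id", "stratum", "bb_code"]
_TRAIT_COLS = [
    "species_id",
    "life_form",
    "myc_status",
    "ellenberg_R",
    "ellenberg_N",
    "ellenberg_F",
]
_META_COLS = ["plot_id", "x", "y", "area", "forest_id"]


class InputValidationError(ValueError):
    """Raised when an input table violates the bundle contract."""


@dataclass
class InputBundle:
    """Validated in-memory bundle of the three input tables.

    ``records`` is the long-format observation table, ``traits`` is indexed
    by ``species_id`` and carries ``indifferent_*`` boolean columns derived
    from the ``x`` markers, ``meta`` is indexed by ``plot_id``.
    """

    records: pd.DataFrame
    traits: pd.DataFrame
    meta: pd.DataFrame
    conversion: dict[str, float] = field(default_factory=lambda: dict(VAN_DER_MAAREL))

    def summary(self) -> dict:
        n_unknown = int((self.traits["myc_status"] == "UNKNOWN").sum())
        return {
            "n_plots": int(self.records["plot_id"].nunique()),
            "n_species": int(self.records["species_id"].nunique()),
            "n_records": int(len(self.records)),
            "n_unknown_status": n_unknown,
        }


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputValidationError(f"{name}: missing column(s) {missing}")


def read_plot_records(
    path: str | Path, conversion: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Read and validate the long-format plot x species table."""
    conversion = dict(conversion or VAN_DER_MAAREL)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, _RECORD_COLS, "plots")
    df = df[_RECORD_COLS].copy()
    bad_stratum = sorted(set(df["stratum"]) - set(STRATA))
    if bad_stratum:
        raise InputValidationError(f"plots: invalid stratum value(s) {bad_stratum}")
    bad = df.loc[~df["bb_code"].isin(conversion)]
    if len(bad):
        offenders = bad[_RECORD_COLS].head(10).to_dict("records")
        raise InputValidationError(
            f"plots: {len(bad)} record(s) with bb_code not in the active "
            f"conversion table, first offenders: {offenders}"
        )
    dup = df.duplicated(subset=["plot_id", "species_id", "stratum"])
    if dup.any():
        offenders = df.loc[dup, _RECORD_COLS].head(10).to_dict("records")
        raise InputValidationError(f"plots: duplicate keys, first offenders: {offenders}")
    return df.reset_index(drop=True)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read and validate the species trait table.

    Returns a frame indexed by ``species_id`` with float ``ellenberg_*``
    columns (NaN for indifferent or missing) and boolean ``indifferent_*``
    flag columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _TRAIT_COLS, "traits")
    if df["species_id"].duplicated().any():
        dups = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
        raise InputValidationError(f"traits: duplicate species_id(s) {dups[:10]}")
    bad_lf = sorted(set(df["life_form"]) - set(LIFE_FORMS))
    if bad_lf:
        raise InputValidationError(f"traits: invalid life_form value(s) {bad_lf}")
    bad_st = sorted(set(df["myc_status"]) - set(MYC_STATUSES))
    if bad_st:
        raise InputValidationError(f"traits: invalid myc_status value(s) {bad_st}")
    out = df[["species_id", "life_form", "myc_status"]].copy()
    for ind in INDICATORS:
        col = f"ellenberg_{ind}"
        raw = df[col].fillna("").str.strip()
        vals = pd.to_numeric(raw.where(~raw.str.lower().eq("x"), ""), errors="coerce")
        outside = vals.dropna().loc[lambda s: (s < 1) | (s > 9)]
        if len(outside):
            raise InputValidationError(
                f"traits: {col} value(s) outside [1, 9] for species "
                f"{sorted(df.loc[outside.index, 'species_id'])[:10]}"
            )
        out[col] = vals
        out[f"indifferent_{ind}"] = raw.str.lower().eq("x")
    return out.set_index("species_id")


def read_plot_meta(path: str | Path) -> pd.DataFrame:
    """Read and validate the plot metadata table (indexed by plot_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"plot_id": str, "forest_id": str})
    _require_columns(df, _META_COLS, "plots_meta")
    if df["plot_id"].duplicated().any():
        raise InputValidationError("plots_meta: duplicate plot_id")
    for col in ("x", "y", "area"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.isfinite(vals).all():
            raise InputValidationError(f"plots_meta: non-finite values in {col}")
        df[col] = vals
    if (df["area"] <= 0).any():
        raise InputValidationError("plots_meta: area must be > 0")
    if "measured_ph" in df.columns:
        df["measured_ph"] = pd.to_numeric(df["measured_ph"], errors="coerce")
    else:
        df["measured_ph"] = np.nan
    return df.set_index("plot_id")


def read_inputs(
    plots_path: str | Path,
    traits_path: str | Path,
    meta_path: str | Path,
    conversion: Mapping[str, float] | None = None,
) -> InputBundle:
    """Read the three tables and verify cross-referential integrity.

    Every species observed in a plot must have exactly one trait row and
    every plot must have a metadata row; violations raise
    :class:`InputValidationError` naming the offenders.
    """
    conversion = dict(conversion or VAN_DER_MAAREL)
    records = read_plot_records(plots_path, conversion)
    traits = read_traits(traits_path)
    meta = read_plot_meta(meta_path)
    missing_sp = sorted(set(records["species_id"]) - set(traits.index))
    if missing_sp:
        raise InputValidationError(
            f"{len(missing_sp)} species without a trait row: {missing_sp[:20]}"
        )
    missing_plots = sorted(set(records["plot_id"]) - set(meta.index))
    if missing_plots:
        raise InputValidationError(
            f"{len(missing_plots)} plot(s) without metadata: {missing_plots[:20]}"
        )
    return InputBundle(records=records, traits=traits, meta=meta, conversion=conversion)


def write_inputs(bundle: InputBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to ``plots.tsv`` / ``traits.tsv`` / ``plots_meta.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "plots": out / "plots.tsv",
        "traits": out / "traits.tsv",
        "meta": out / "plots_meta.tsv",
    }
    bundle.records[_RECORD_COLS].to_csv(paths["plots"], sep="\t", index=False)

    tr = bundle.traits.reset_index()
    for ind in INDICATORS:
        col, flag = f"ellenberg_{ind}", f"indifferent_{ind}"
        txt = tr[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
        tr[col] = np.where(tr[flag], "x", txt)
    tr[_TRAIT_COLS].to_csv(paths["traits"], sep="\t", index=False)

    meta = bundle.meta.reset_index()
    cols = _META_COLS + (["measured_ph"] if meta["measured_ph"].notna().any() else [])
    meta[cols].to_csv(paths["meta"], sep="\t", index=False)
    return paths


def convert_bb_to_cover(
    records: pd.DataFrame, conversion: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Convert Braun-Blanquet codes to a plots x (species, stratum) matrix.

    Missing plot/species pairs are absences (0).  Species recorded in both
    strata (e.g. tree seedlings in the herb layer) keep separate columns,
    so the column MultiIndex is (species_id, stratum).
    """
    conversion = dict(conversion or VAN_DER_MAAREL)
    unmapped = records.loc[~records["bb_code"].isin(conversion)]
    if len(unmapped):
        first = unmapped.iloc[0]
        raise InputValidationError(
            f"unmapped bb_code {first['bb_code']!r} at plot {first['plot_id']!r}, "
            f"species {first['species_id']!r} ({len(unmapped)} record(s) total)"
        )
    values = records["bb_code"].map(conversion).astype(float)
    cover = (
        pd.DataFrame(
            {
                "plot_id": records["plot_id"],
                "species_id": records["species_id"],
                "stratum": records["stratum"],
                "value": values,
            }
        )
        .pivot_table(
            index="plot_id",
            columns=["species_id", "stratum"],
            values="value",
            aggfunc="sum",
            fill_value=0.0,
        )
        .astype(float)
    )
    if (cover.sum(axis=1) <= 0).any():
        empty = list(cover.index[cover.sum(axis=1) <= 0])[:10]
        raise InputValidationError(f"plots with zero total abundance: {empty}")
    return cover
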