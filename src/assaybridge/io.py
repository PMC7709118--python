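"""Delimited-text readers and writers for every pipeline table.

All tables are header-named delimited text (comma or tab, sniffed);
column order is never significant, and common export-dialect variants of
the column names (e.g. ``Total Area`` vs ``total_area``, ``Sample`` vs
``sample_id``) are normalised on read.  Malformed input raises a
:class:`TableFormatError` naming the file and the offending column before
any computation happens.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class TableFormatError(ValueError):
    pass


#: canonical name -> accepted aliases (lower-cased, stripped)
_TRANSITION_ALIASES: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "sample", "replicate name", "replicate"),
    "well_role": ("well_role", "role"),
    "protein": ("protein", "protein name"),
    "peptide": ("peptide", "peptide sequence", "peptide modified sequence"),
    "label": ("label", "isotope label type", "isotope label"),
    "total_area": ("total_area", "total area"),
    "total_background": ("total_background", "total background"),
}

_PLATE_ALIASES: dict[str, tuple[str, ...]] = {
    "plate_id": ("plate_id", "plate"),
    "well_id": ("well_id", "well"),
    "role": ("role", "well_role"),
    "analyte": ("analyte", "protein"),
    "dilution_factor": ("dilution_factor", "dilution"),
    "od450": ("od450", "od", "absorbance"),
    "nominal_conc": ("nominal_conc", "nominal", "nominal concentration"),
}

_MANIFEST_REQUIRED = ("subject_id", "age", "hdl", "egfr")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def _normalise(
    df: pd.DataFrame, aliases: Mapping[str, tuple[str, ...]], path: str | Path,
    optional: Iterable[str] = (),
) -> pd.DataFrame:
    lookup = {}
    for canonical, names in aliases.items():
        for col in df.columns:
            if col.strip().lower() in names:
                lookup[col] = canonical
                break
    out = df.rename(columns=lookup)
    missing = set(aliases) - set(out.columns) - set(optional)
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    return out


def read_transition_report(path: str | Path) -> pd.DataFrame:
    """Read a transition-level MRM report into canonical columns."""
    df = _normalise(_read_delimited(path), _TRANSITION_ALIASES, path)
    df["label"] = df["label"].str.strip().str.lower()
    for col in ("total_area", "total_background"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    return df


def write_transition_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read an ELISA plate table into canonical columns."""
    df = _normalise(_read_delimited(path), _PLATE_ALIASES, path, optional=("nominal_conc",))
    if "nominal_conc" not in df.columns:
        df["nominal_conc"] = float("nan")
    for col in ("od450", "nominal_conc", "dilution_factor"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: column {col!r} is not numeric: {exc}") from exc
    return df


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the subject manifest (covariates for the risk score).

    Requires columns subject_id, age, hdl, egfr; validation happens up
    front so a missing covariate fails before any quantitation runs.
    """
    df = _read_delimited(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(_MANIFEST_REQUIRED) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: manifest missing column(s) {sorted(missing)}")
    return df.set_index("subject_id")


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=True)


def read_concentration_table(path: str | Path) -> pd.DataFrame:
    df = _read_delimited(path)
    required = {"sample_id", "protein", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: concentration table missing {sorted(missing)}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    return df


def write_concentration_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def concentrations_wide(table: pd.DataFrame, roles: Iterable[str] = ("sample",)) -> pd.DataFrame:
    """Pivot a tidy concentration table to subjects × analytes."""
    sub = table
    if "well_role" in table.columns:
        sub = table[table["well_role"].isin(list(roles))]
    return sub.pivot(index="sample_id", columns="protein", values="concentration")
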