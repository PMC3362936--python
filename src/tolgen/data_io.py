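"""Phenotype-table I/O, validation and the data-edit rules.

The phenotype file is delimited text (comma or tab) with one row per bird:

    animal_id, sire_id, dam_id, gender, batch, stable, person,
    age_bw2, age_bw7, age_ratio, bw2, bw7, ratio

Missing trait cells (mortality before week 7, unusable hearts) may be
blank or "NA". Heart ratio is a percentage and must lie strictly inside
(0, 100). A column-mapping dict allows files with other headers.

The one data edit applied before analysis removes the offspring of sires
with small families (default: fewer than 20 recorded offspring), because
small sire families bias the tolerance-slope variance and the
intercept-slope correlation; the sires themselves stay in the pedigree.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import MISSING_TOKENS, Pedigree

REQUIRED_COLUMNS = [
    "animal_id",
    "sire_id",
    "dam_id",
    "gender",
    "batch",
    "stable",
    "person",
    "age_bw2",
    "age_bw7",
    "age_ratio",
    "bw2",
    "bw7",
    "ratio",
]

TRAIT_COLUMNS = ["bw2", "bw7", "ratio"]


class PhenotypeError(ValueError):
    """Raised for malformed or out-of-range phenotype records."""


def load_phenotypes(
    path,
    pedigree: Pedigree | None = None,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read and validate a phenotype table.

    Checks: required columns present (after renaming via `column_map`),
    every sire/dam known to the pedigree (when one is given), ratio within
    (0, 100), ages positive. Missing trait cells are allowed and become NaN.
    """
    sep = None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PhenotypeError(f"missing columns: {', '.join(missing_cols)}")
    df = df[REQUIRED_COLUMNS].copy()
    for c in TRAIT_COLUMNS + ["age_bw2", "age_bw7", "age_ratio"]:
        df[c] = pd.to_numeric(
            df[c].map(lambda v: np.nan if v is None or str(v).strip() in MISSING_TOKENS else v),
            errors="raise",
        )
    bad = df.index[(df["ratio"] <= 0) | (df["ratio"] >= 100)].tolist()
    bad = [i for i in bad if not np.isnan(df.loc[i, "ratio"])]
    if bad:
        raise PhenotypeError(
            f"heart ratio outside (0, 100) in row(s): {bad[:5]}"
        )
    for c in ("age_bw2", "age_bw7", "age_ratio"):
        neg = df.index[df[c] <= 0].tolist()
        if neg:
            raise PhenotypeError(f"non-positive {c} in row(s): {neg[:5]}")
    dup = df["animal_id"][df["animal_id"].duplicated()].tolist()
    if dup:
        raise PhenotypeError(f"duplicate animal id(s): {dup[:5]}")
    if pedigree is not None:
        for col in ("animal_id", "sire_id", "dam_id"):
            unknown = [
                v
                for v in df[col].dropna().unique()
                if str(v) not in MISSING_TOKENS and str(v) not in pedigree
            ]
            if unknown:
                raise PhenotypeError(
                    f"{col} value(s) not in pedigree: {unknown[:5]}"
                )
    return df


def write_phenotypes(table: pd.DataFrame, path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False, na_rep="")


def trait_counts(table: pd.DataFrame) -> dict:
    """Non-missing record count per trait."""
    return {c: int(table[c].notna().sum()) for c in TRAIT_COLUMNS}


def filter_small_sire_families(
    table: pd.DataFrame, min_offspring: int = 20
) -> pd.DataFrame:
    """Drop all offspring of sires with fewer than `min_offspring` recorded
    offspring. Retained rows are returned unchanged (same dtypes, order)."""
    counts = table.groupby("sire_id")["animal_id"].count()
    keep_sires = set(counts.index[counts >= min_offspring])
    return table[table["sire_id"].isin(keep_sires)].copy()


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------


def write_report(report, path) -> None:
    """Serialise a VarianceReport: components as CSV, scalars and solutions
    as JSON next to it (``<path>.json``)."""
    path = Path(path)
    report.to_frame().to_csv(path, index=False, float_format="%.12g")
    payload = {
        "logl": report.logl,
        "aic": report.aic,
        "bic": report.bic,
        "n_records": report.n_records,
        "n_fixed": report.n_fixed,
        "n_parameters": report.n_parameters,
        "converged": bool(report.converged),
        "n_iter": report.n_iter,
        "meta": {
            k: v
            for k, v in report.meta.items()
            if isinstance(v, (str, int, float, bool, type(None)))
        },
        "fixed_effects": {
            k: float(v) for k, v in report.solutions.get("fixed", {}).items()
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(payload, indent=1))


def read_report(path):
    """Round-trip companion of :func:`write_report`: returns (component
    DataFrame, scalar dict)."""
    path = Path(path)
    frame = pd.read_csv(path)
    payload = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return frame, payload


def write_solutions(report, path) -> None:
    """Random-effect solutions (EBVs etc.) as long-format CSV."""
    rows = []
    for term, df in report.solutions.items():
        if term == "fixed":
            continue
        for col in df.columns:
            for lev, val in df[col].items():
                rows.append({"term": term, "level": lev, "column": col, "value": val})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
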