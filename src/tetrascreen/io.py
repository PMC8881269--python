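"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8 with headers: plate maps as CSV, everything else as
TSV.  Schemas are shared between the synthetic generator and the image
quantifier so image mode and table mode are interchangeable downstream.
"""

from __future__ import annotations

import pandas as pd

from .design import PLATE_MAP_COLUMNS
from .simulate import CELL_TABLE_COLUMNS

CELL_DTYPES = {"plate_id": str, "well": str}


def read_plate_map(path) -> pd.DataFrame:
    t = pd.read_csv(path, dtype={"plate_id": str, "well": str, "gene_id": str}, keep_default_na=False)
    missing = set(PLATE_MAP_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return t[PLATE_MAP_COLUMNS]


def write_plate_map(table: pd.DataFrame, path) -> None:
    table[PLATE_MAP_COLUMNS].to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=CELL_DTYPES)
    required = [c for c in CELL_TABLE_COLUMNS if c != "true_class"]
    missing = set(required) - set(t.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return t


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_profiles(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=CELL_DTYPES)
    t["qc_flag"] = t.get("qc_flag", "").fillna("") if "qc_flag" in t else ""
    return t


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_zscores(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype=CELL_DTYPES)
    t["flag"] = t["flag"].fillna("") if "flag" in t else ""
    return t


def write_zscores(zscores: pd.DataFrame, path) -> None:
    zscores.to_csv(path, sep="\t", index=False)
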