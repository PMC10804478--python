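"""Readers and writers for the plain-text pipeline formats.

All interchange files are CSV/TSV/JSON so every number is diffable:

* ``ihc_fields.csv``  — tumor_id, region, marker, field_index,
  positive_count, cells_assessed (one row per high-power field);
* ``tls.csv``         — tumor_id, region, tls_count;
* ``expression.tsv``  — featureCounts-style gene x sample integer counts
  (first column the gene id; optional annotation columns skipped by name);
* ``clinicopath.csv`` — case_id, age, sex, max_diameter,
  pathological_type, diagnosis, multiplicity;
* ``regional_samples.tsv`` — quantified sections (one row per
  tumor x region);
* ``abundance.tsv``   — feature x sample abundances.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

IHC_FIELD_COLUMNS = [
    "tumor_id",
    "region",
    "marker",
    "field_index",
    "positive_count",
    "cells_assessed",
]
TLS_COLUMNS = ["tumor_id", "region", "tls_count"]
CLINICOPATH_COLUMNS = [
    "case_id",
    "age",
    "sex",
    "max_diameter",
    "pathological_type",
    "diagnosis",
    "multiplicity",
]
#: featureCounts annotation columns dropped on read when present.
FEATURECOUNTS_ANNOTATION = ["Chr", "Start", "End", "Strand", "Length"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def read_ihc_fields(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, IHC_FIELD_COLUMNS, f"IHC field sheet {path}")
    return df


def read_tls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TLS_COLUMNS, f"TLS sheet {path}")
    return df


def read_clinicopath(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CLINICOPATH_COLUMNS, f"clinicopathological table {path}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a featureCounts-style TSV: gene id in the first column,
    integer counts in the remaining (annotation columns dropped)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    drop = [c for c in FEATURECOUNTS_ANNOTATION if c in df.columns]
    df = df.drop(columns=drop)
    try:
        return df.astype(int)
    except ValueError as exc:
        raise ValueError(f"non-integer counts in expression matrix {path}: {exc}") from exc


def write_regional_samples(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_regional_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["tumor_id", "region", "tls_count"], f"regional-sample table {path}")
    return df


def write_abundance(data: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    data.to_csv(path, sep="\t", index_label="feature")
    return path


def read_abundance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0]).rename_axis("feature")


def load_reference_clinical() -> pd.DataFrame:
    """Clinicopathological table of the ten-patient DDRPLS reference
    cohort (age, sex, maximum diameter in cm, complete/partial
    dedifferentiation, primary/recurrent, single/multiple)."""
    with resources.files("timehom.data").joinpath("ddrpls_clinical.csv").open() as fh:
        return pd.read_csv(fh)
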