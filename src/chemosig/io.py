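"""Readers and writers for the pipeline's TSV/CSV dialects.

Expression matrices: genes in rows by default, first column = gene id,
header = sample ids. Drug-response tables: long format with columns
``sample_id, drug, ic50_um``. Clinical tables: one row per patient with
mandatory ``sample_id, time_years, event`` and any further columns kept as
covariates. All numeric output is written with >= 10 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CohortTable, DrugResponseTable, ExpressionMatrix

_SEPS = {"tsv": "\t", "csv": ","}
FLOAT_FMT = "%.12g"


def _sep_for(path, format):
    if format is not None:
        return _SEPS[format]
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(path, format=None, orientation="genes_in_rows",
                           normalization="raw_counts") -> ExpressionMatrix:
    """Read a delimited expression matrix into genes x samples orientation.

    ``orientation`` names what the file's rows hold; the returned matrix is
    always genes x samples. Duplicate identifiers and non-numeric cells are
    reported with names/coordinates.
    """
    df = pd.read_csv(path, sep=_sep_for(path, format), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for i, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            r = df.index[np.argmax(bad.values)]
            raise ValueError(
                f"non-numeric cell at row {r!r}, column {col!r}: "
                f"{df.loc[r, col]!r}"
            )
        df[col] = coerced
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(list(df.index), list(df.columns),
                            df.to_numpy(dtype=float), normalization)


def write_expression_matrix(expr: ExpressionMatrix, path, format=None) -> None:
    expr.to_frame().to_csv(path, sep=_sep_for(path, format), float_format=FLOAT_FMT,
                           index_label="gene_id")


def read_drug_response(path, format=None) -> DrugResponseTable:
    """Read a long-format ``sample_id, drug, ic50_um`` table."""
    df = pd.read_csv(path, sep=_sep_for(path, format))
    required = {"sample_id", "drug", "ic50_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"drug-response table must have columns {sorted(required)}")
    wide = df.pivot_table(index="sample_id", columns="drug", values="ic50_um",
                          aggfunc="first", sort=False)
    return DrugResponseTable(list(wide.index.astype(str)),
                             list(wide.columns.astype(str)),
                             wide.to_numpy(dtype=float))


def write_drug_response(table: DrugResponseTable, path, format=None) -> None:
    long = (table.to_frame()
            .rename_axis("sample_id")
            .reset_index()
            .melt(id_vars="sample_id", var_name="drug", value_name="ic50_um")
            .dropna(subset=["ic50_um"]))
    long.to_csv(path, sep=_sep_for(path, format), index=False, float_format=FLOAT_FMT)


def read_clinical(path, format=None) -> CohortTable:
    """Read a clinical table; extra columns become covariates."""
    df = pd.read_csv(path, sep=_sep_for(path, format))
    required = {"sample_id", "time_years", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    status = None
    if "prognostic_status" in df.columns:
        status = df["prognostic_status"].to_numpy(dtype=object)
    cov_cols = [c for c in df.columns
                if c not in ("sample_id", "time_years", "event", "prognostic_status")]
    covariates = df[cov_cols].copy() if cov_cols else None
    return CohortTable(list(df["sample_id"].astype(str)),
                       df["time_years"].to_numpy(dtype=float),
                       df["event"].to_numpy(),
                       covariates=covariates,
                       prognostic_status=status)


def write_clinical(cohort: CohortTable, path, format=None) -> None:
    cohort.to_frame().rename_axis("sample_id").reset_index().to_csv(
        path, sep=_sep_for(path, format), index=False, float_format=FLOAT_FMT)
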