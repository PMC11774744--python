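"""Core in-memory containers for the screening/classification pipeline.

Three containers flow through the pipeline: a genes-by-samples expression
matrix tagged with its normalization state, a samples-by-drugs IC50 table
(missing entries allowed per drug), and a per-patient clinical table with
right-censored survival and an optional 5-year prognostic status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NORMALIZATIONS = ("raw_counts", "log_size_factor", "tmm_logcpm", "external_normalized")

FAVORABLE = "favorable"
UNFAVORABLE = "unfavorable"
UNCERTAIN = "uncertain"
STATUS_LEVELS = (FAVORABLE, UNFAVORABLE, UNCERTAIN)


def _check_unique(ids: Sequence[str], axis: str) -> list:
    ids = list(ids)
    seen, dups = set(), []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {axis} identifiers: {', '.join(map(str, dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a normalization tag.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in
    ``sample_ids[j]``. Raw counts must be non-negative; any normalized
    matrix must be finite everywhere.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    normalization: str = "raw_counts"

    def __post_init__(self):
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "raw_counts":
            if np.any(np.isnan(self.values)) or np.any(self.values < 0):
                raise ValueError("raw counts must be non-negative and complete")
        else:
            if not np.all(np.isfinite(self.values)):
                raise ValueError("normalized expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index(genes)
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[idx], self.normalization)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {', '.join(missing)}")
        idx = np.array([pos[s] for s in samples], dtype=int)
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, idx], self.normalization)


@dataclass
class DrugResponseTable:
    """Samples x drugs IC50 table in micromolar; NaN marks missing entries."""

    sample_ids: list
    drug_names: list
    ic50: np.ndarray

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.drug_names = _check_unique(self.drug_names, "drug")
        self.ic50 = np.asarray(self.ic50, dtype=float)
        if self.ic50.shape != (len(self.sample_ids), len(self.drug_names)):
            raise ValueError("ic50 shape does not match (samples, drugs)")
        present = ~np.isnan(self.ic50)
        if np.any(self.ic50[present] <= 0):
            raise ValueError("IC50 values must be positive where present")

    def ic50_series(self, drug: str) -> pd.Series:
        """IC50 for one drug indexed by sample, missing samples dropped."""
        j = self.drug_names.index(drug)
        s = pd.Series(self.ic50[:, j], index=self.sample_ids, name=drug)
        return s.dropna()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ic50, index=self.sample_ids, columns=self.drug_names)


@dataclass
class CohortTable:
    """Per-patient survival and covariates.

    ``time_years`` is follow-up in years, ``event`` is 1 for the endpoint
    event (death for OS, relapse for RFS), 0 for censoring.
    ``prognostic_status`` holds the 5-year dichotomization once assigned by
    :func:`chemosig.survival.define_prognostic_status`.
    """

    sample_ids: list
    time_years: np.ndarray
    event: np.ndarray
    covariates: Optional[pd.DataFrame] = None
    prognostic_status: Optional[np.ndarray] = None

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.time_years = np.asarray(self.time_years, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time_years.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample_ids")
        if np.any(self.time_years < 0):
            raise ValueError("survival times must be non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = self.event.astype(int)
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != n:
                raise ValueError("covariate rows do not match sample_ids")
            self.covariates.index = self.sample_ids
        if self.prognostic_status is not None:
            self.prognostic_status = np.asarray(self.prognostic_status, dtype=object)
            bad = set(self.prognostic_status) - set(STATUS_LEVELS)
            if bad:
                raise ValueError(f"unknown prognostic status levels: {bad}")

    @property
    def n_patients(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_years": self.time_years, "event": self.event},
                          index=self.sample_ids)
        if self.prognostic_status is not None:
            df["prognostic_status"] = self.prognostic_status
        if self.covariates is not None:
            df = pd.concat([df, self.covariates], axis=1)
        return df
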