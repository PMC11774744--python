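"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators, each a pure function of its spec (seed included):

* ``simulate_invitro_panel`` — several small expression/IC50 panels that
  share a set of genes truly rank-correlated with log-IC50. Correlated
  genes are built by the Gaussian-copula construction: a bivariate-normal
  latent pair at Pearson ``r = 2 sin(pi * rho_s / 6)`` (the exact
  normal-copula relation) is mapped through a monotone log-normal count
  transform, which preserves Spearman's rho up to integer-rounding ties.
  Per-dataset noise is independent, so cross-dataset reproducibility
  carries the planted signal only.
* ``simulate_cohort`` — a patient cohort whose binary 5-year outcome
  follows a logistic model on a planted gene subset, with right-censored
  survival times drawn consistently with the binary outcome (the
  dichotomized outcome is primary; times are generated conditionally).
* ``simulate_dose_response`` — LL.4 viability plates with Gaussian noise
  and replicate wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import (CohortTable, DrugResponseTable, ExpressionMatrix,
                        FAVORABLE, UNCERTAIN, UNFAVORABLE)
from .doseresponse import loglogistic4


def _spearman_to_pearson(rho_s: float) -> float:
    """Exact bivariate-normal conversion from target Spearman to Pearson."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class PanelSpec:
    n_datasets: int = 3
    n_samples: int = 30
    n_genes: int = 510                     # total, planted included
    planted_genes: Optional[List[Tuple[str, str, float]]] = None
    # (name, direction "+"/"-", target |rho|); default: 10 genes at 0.7
    count_mu_log: float = np.log(500.0)
    count_sigma_between: float = 1.0       # gene-to-gene spread of mean log count
    count_sigma_within: float = 0.5        # sample-to-sample log-count sd
    drug: str = "drugX"
    seed: int = 0

    def __post_init__(self):
        if self.planted_genes is None:
            self.planted_genes = [
                (f"PLT{i + 1:02d}", "+" if i < 5 else "-", 0.7)
                for i in range(10)
            ]
        if len(self.planted_genes) > self.n_genes:
            raise ValueError("more planted genes than genes")
        for name, direction, rho in self.planted_genes:
            if not 0 < rho < 1:
                raise ValueError(f"target |rho| for {name} must lie in (0,1)")
            if direction not in ("+", "-"):
                raise ValueError(f"direction for {name} must be '+' or '-'")


def simulate_invitro_panel(spec: PanelSpec
                           ) -> List[Tuple[ExpressionMatrix, DrugResponseTable]]:
    """One (expression, drug-response) pair per dataset."""
    rng = np.random.default_rng([int(spec.seed) % (2 ** 31), 101])
    n_planted = len(spec.planted_genes)
    gene_ids = [g for g, _, _ in spec.planted_genes] + \
        [f"G{i + 1:04d}" for i in range(spec.n_genes - n_planted)]
    # per-gene baseline abundance shared across datasets
    mu = spec.count_mu_log + spec.count_sigma_between * rng.standard_normal(spec.n_genes)
    for _, _, rho in spec.planted_genes:
        if _spearman_to_pearson(rho) > 0.999 or spec.n_samples < 5:
            warnings.warn("target rho may be unreachable at this sample size")
    out = []
    for d in range(spec.n_datasets):
        n = spec.n_samples
        z = rng.standard_normal(n)                       # latent log-IC50
        ic50 = np.exp(z)                                 # uM, log-normal
        vals = np.empty((spec.n_genes, n))
        for i, (name, direction, rho) in enumerate(spec.planted_genes):
            r = _spearman_to_pearson(rho) * (1.0 if direction == "+" else -1.0)
            g = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
            vals[i] = g
        vals[n_planted:] = rng.standard_normal((spec.n_genes - n_planted, n))
        counts = np.round(np.exp(mu[:, None] + spec.count_sigma_within * vals))
        expr = ExpressionMatrix(gene_ids,
                                [f"D{d + 1}S{j + 1:03d}" for j in range(n)],
                                counts, "raw_counts")
        resp = DrugResponseTable(list(expr.sample_ids), [spec.drug], ic50[:, None])
        out.append((expr, resp))
    return out


@dataclass
class CohortSpec:
    n_patients: int = 160
    n_genes: int = 60                      # candidate pool size, planted included
    signature: Optional[List[Tuple[str, float]]] = None
    # (gene, log-odds per SD of expression); default 5 genes at 1.0
    target_unfavorable: float = 0.45       # 5-year unfavorable fraction
    censoring_rate: float = 0.2            # P(censored before horizon | survivor)
    horizon_years: float = 5.0
    baseline_hazard: float = 0.139         # per-year; median ~5 y at eta = 0
    expr_mu_log: float = 5.0
    expr_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.signature is None:
            self.signature = [(f"SIG{i + 1}", 1.0) for i in range(5)]
        if len(self.signature) > self.n_genes:
            raise ValueError("signature larger than gene pool")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring rate must lie in [0, 1)")
        if not 0 < self.target_unfavorable < 1:
            raise ValueError("target unfavorable fraction must lie in (0, 1)")


def simulate_cohort(spec: CohortSpec) -> Tuple[ExpressionMatrix, CohortTable]:
    """Expression matrix plus clinical table with planted prognostic signal.

    The binary 5-year outcome is primary: unfavorable patients receive an
    event time inside the horizon (truncated exponential with log-hazard
    proportional to the same linear predictor), survivors either reach the
    horizon (favorable) or are censored early (uncertain) at the requested
    censoring rate.
    """
    rng = np.random.default_rng([int(spec.seed) % (2 ** 31), 202])
    n, G = spec.n_patients, spec.n_genes
    sig_genes = [g for g, _ in spec.signature]
    gene_ids = sig_genes + [f"N{i + 1:03d}" for i in range(G - len(sig_genes))]
    z = rng.standard_normal((G, n))
    values = spec.expr_mu_log + spec.expr_sigma * z
    effects = np.array([b for _, b in spec.signature])
    eta = effects @ z[:len(sig_genes)]

    def prevalence(alpha):
        return np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))) - spec.target_unfavorable

    alpha = brentq(prevalence, -30, 30)
    p_unfav = 1.0 / (1.0 + np.exp(-(alpha + eta)))
    unfav = rng.random(n) < p_unfav
    if unfav.all() or not unfav.any():
        raise ValueError("infeasible target prevalence: degenerate outcome draw")

    time = np.empty(n)
    event = np.zeros(n, dtype=int)
    status = np.empty(n, dtype=object)
    H = spec.horizon_years
    rate = spec.baseline_hazard * np.exp(eta - eta.mean())
    # unfavorable: event inside the horizon, truncated-exponential draw
    u = rng.random(n)
    f_h = 1.0 - np.exp(-rate * H)
    time[unfav] = -np.log(1.0 - u[unfav] * f_h[unfav]) / rate[unfav]
    event[unfav] = 1
    status[unfav] = UNFAVORABLE
    # survivors: censored early (uncertain) or followed past the horizon
    surv = ~unfav
    early = surv & (rng.random(n) < spec.censoring_rate)
    late = surv & ~early
    time[early] = rng.uniform(0.25, H - 1e-9, early.sum())
    status[early] = UNCERTAIN
    time[late] = H + rng.exponential(2.0, late.sum())
    status[late] = FAVORABLE

    covariates = pd.DataFrame({
        "age": np.round(rng.normal(65, 10, n), 1),
        "sex_male": rng.integers(0, 2, n).astype(float),
    })
    sample_ids = [f"P{i + 1:04d}" for i in range(n)]
    expr = ExpressionMatrix(gene_ids, sample_ids, values, "external_normalized")
    cohort = CohortTable(sample_ids, time, event, covariates=covariates,
                         prognostic_status=status)
    return expr, cohort


def simulate_dose_response(lower: float = 0.0, upper: float = 1.0,
                           slope: float = 1.5, e_param: float = 10.0,
                           doses: Optional[Sequence[float]] = None,
                           sigma: float = 0.05, replicates: int = 3,
                           seed: int = 0, sample_id: str = "S1",
                           drug: str = "drugX") -> pd.DataFrame:
    """LL.4 viability plate with Gaussian noise, ``replicates`` rows/dose."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if doses is None:
        doses = e_param * np.logspace(-2, 2, 7)
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng([int(seed) % (2 ** 31), 303])
    rows = []
    for d in doses:
        f = loglogistic4(d, lower, upper, slope, e_param)
        for _ in range(replicates):
            rows.append({"sample_id": sample_id, "drug": drug, "dose_um": d,
                         "viability": f + sigma * rng.standard_normal()})
    return pd.DataFrame(rows)
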