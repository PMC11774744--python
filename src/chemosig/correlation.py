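"""Spearman screening of expression against IC50 and cross-dataset logic.

Per dataset and drug, every gene's expression is rank-correlated with the
per-sample IC50; a gene is called significant when ``|rho|`` strictly
exceeds the rho threshold (default 0.3) AND the p-value is strictly below
alpha (default 0.05). No multiple-testing correction is applied:
reproducibility is enforced instead by the co-directional intersection,
which keeps only genes significant with the same sign in every dataset.
Screening hits across drugs are compared by pairwise/overall overlap plus
an explicit list of sign contradictions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DrugResponseTable, ExpressionMatrix


@dataclass
class ScreenConfig:
    rho_threshold: float = 0.3
    alpha: float = 0.05
    p_method: str = "t_approx"  # or "exact_permutation" (n <= 10)

    def __post_init__(self):
        if not 0 < self.rho_threshold < 1:
            raise ValueError("rho_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.p_method not in ("t_approx", "exact_permutation"):
            raise ValueError(f"unknown p_method {self.p_method!r}")


@dataclass
class CorrelationScreenResult:
    dataset_id: str
    drug: str
    table: pd.DataFrame  # columns: gene, rho, p, n, significant, direction


@dataclass
class IntersectionResult:
    drug: str
    positive_genes: set
    negative_genes: set
    contributing_datasets: list


@dataclass
class CrossDrugOverlap:
    pairwise: dict          # (drug_a, drug_b) -> {"positive": set, "negative": set}
    overall: dict           # {"positive": set, "negative": set} across all drugs
    contradictions: set     # genes significant + for one drug, - for another
    drugs: list


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df."""
    rho = np.asarray(rho, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho)
    r = np.clip(rho[ok], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p[ok] = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[ok] = np.where(np.abs(r) >= 1.0, 0.0, p[ok])
    return p


_PERM_CACHE: dict = {}


def _permutation_matrix(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 (cached); exact p-values, n <= 10."""
    if n not in _PERM_CACHE:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int16)
        _PERM_CACHE[n] = perms
    return _PERM_CACHE[n]


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """P(|rho_perm| >= |rho_obs|) by full enumeration of pairings."""
    n = rx.size
    if n > 10:
        raise ValueError("exact permutation p-values are limited to n <= 10")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    if denom == 0:
        return np.nan
    obs = abs(float(rxc @ ryc) / denom)
    perms = _permutation_matrix(n)
    dots = rxc[perms] @ ryc
    rho = np.abs(dots / denom)
    return float(np.mean(rho >= obs - 1e-12))


def spearman_screen(expr: ExpressionMatrix, ic50: pd.Series,
                    config: ScreenConfig = ScreenConfig(),
                    dataset_id: str = "dataset", drug: str = "drug"
                    ) -> CorrelationScreenResult:
    """Spearman rho/p of every gene against IC50 over the shared samples.

    Samples missing from either side are dropped pairwise; at least 4
    shared samples are required. Constant genes yield ``rho = NaN`` and are
    flagged non-significant. Ties are handled by mid-ranks.
    """
    ic50 = ic50.dropna()
    shared = [s for s in expr.sample_ids if s in set(ic50.index)]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples between "
                         "expression and IC50; need >= 4")
    sub = expr.subset_samples(shared)
    y = ic50.loc[shared].to_numpy(dtype=float)
    n = len(shared)

    ry = stats.rankdata(y)
    rx = stats.rankdata(sub.values, axis=1)
    rxc = rx - rx.mean(axis=1, keepdims=True)
    ryc = ry - ry.mean()
    sx = np.sqrt((rxc ** 2).sum(axis=1))
    sy = np.sqrt((ryc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rxc @ ryc) / (sx * sy)
    rho[sx == 0] = np.nan
    if sy == 0:
        rho[:] = np.nan

    if config.p_method == "t_approx":
        p = _t_approx_p(rho, n)
    else:
        p = np.array([
            np.nan if not np.isfinite(rho[i])
            else _exact_permutation_p(rx[i], ry)
            for i in range(rho.size)
        ])

    with np.errstate(invalid="ignore"):
        significant = (np.abs(rho) > config.rho_threshold) & (p < config.alpha)
    significant = np.where(np.isfinite(rho), significant, False).astype(bool)
    direction = np.where(~significant, "none", np.where(rho > 0, "+", "-"))

    table = pd.DataFrame({
        "gene": sub.gene_ids,
        "rho": rho,
        "p": p,
        "n": n,
        "significant": significant,
        "direction": direction,
    })
    return CorrelationScreenResult(dataset_id=dataset_id, drug=drug, table=table)


def filter_significant(result: CorrelationScreenResult,
                       config: ScreenConfig = ScreenConfig()
                       ) -> Tuple[set, set]:
    """(positive, negative) gene sets under strict |rho| and p thresholds."""
    t = result.table
    with np.errstate(invalid="ignore"):
        sig = (np.abs(t["rho"].to_numpy()) > config.rho_threshold) & \
              (t["p"].to_numpy() < config.alpha)
    sig = np.where(np.isfinite(t["rho"].to_numpy()), sig, False)
    pos = set(t.loc[sig & (t["rho"] > 0), "gene"])
    neg = set(t.loc[sig & (t["rho"] < 0), "gene"])
    return pos, neg


def codirectional_intersection(per_dataset: Sequence[Tuple[set, set]],
                               drug: str = "drug",
                               dataset_ids: Sequence[str] | None = None
                               ) -> IntersectionResult:
    """Genes significant with the same sign in every dataset.

    A gene significant positively in one dataset and negatively in another
    appears in neither output set.
    """
    if len(per_dataset) < 2:
        raise ValueError("co-directional intersection needs >= 2 datasets")
    pos = set.intersection(*(set(p) for p, _ in per_dataset))
    neg = set.intersection(*(set(n) for _, n in per_dataset))
    # sign conflicts cannot survive both intersections, but guard anyway
    conflict = pos & neg
    if dataset_ids is None:
        dataset_ids = [f"dataset_{i + 1}" for i in range(len(per_dataset))]
    return IntersectionResult(drug=drug, positive_genes=pos - conflict,
                              negative_genes=neg - conflict,
                              contributing_datasets=list(dataset_ids))


def cross_drug_overlap(per_drug: Dict[str, IntersectionResult]) -> CrossDrugOverlap:
    """Pairwise/overall overlaps of per-drug hits plus sign contradictions."""
    drugs = list(per_drug)
    if len(drugs) < 2:
        raise ValueError("cross-drug overlap needs >= 2 drugs")
    pairwise = {}
    contradictions: set = set()
    for a, b in itertools.combinations(drugs, 2):
        ra, rb = per_drug[a], per_drug[b]
        pairwise[(a, b)] = {
            "positive": ra.positive_genes & rb.positive_genes,
            "negative": ra.negative_genes & rb.negative_genes,
        }
        contradictions |= (ra.positive_genes & rb.negative_genes)
        contradictions |= (ra.negative_genes & rb.positive_genes)
    overall = {
        "positive": set.intersection(*(per_drug[d].positive_genes for d in drugs)),
        "negative": set.intersection(*(per_drug[d].negative_genes for d in drugs)),
    }
    return CrossDrugOverlap(pairwise=pairwise, overall=overall,
                            contradictions=contradictions, drugs=drugs)


def effective_rho_threshold(n: int, config: ScreenConfig = ScreenConfig()) -> float:
    """|rho| above which a gene passes both screen gates (t-approx)."""
    tcrit = stats.t.ppf(1.0 - config.alpha / 2.0, n - 2)
    rho_crit = tcrit / np.sqrt(n - 2 + tcrit ** 2)
    return float(max(config.rho_threshold, rho_crit))


def null_pass_probability(n: int, config: ScreenConfig = ScreenConfig()) -> float:
    """Analytic probability that an independent gene passes the filter.

    Computed under the large-sample t null of Spearman's rho: the pass
    region is ``|rho| > max(rho_threshold, rho_crit(alpha))``. When the
    p-gate binds (small n) this equals alpha exactly under that null; the
    finite-n permutation null is very slightly heavier-tailed.
    """
    c = effective_rho_threshold(n, config)
    t = c * np.sqrt((n - 2) / (1.0 - c * c))
    return float(2.0 * stats.t.sf(t, n - 2))


def collapse_replicates(expr: ExpressionMatrix, groups: Dict[str, str]
                        ) -> ExpressionMatrix:
    """Average replicate samples to one profile per culture.

    ``groups`` maps sample id -> culture id. IC50 is a per-culture quantity,
    so replicate RNA-seq profiles are collapsed (mean of normalized values)
    before screening.
    """
    cultures: List[str] = []
    cols: List[np.ndarray] = []
    order: Dict[str, list] = {}
    for s in expr.sample_ids:
        order.setdefault(groups.get(s, s), []).append(s)
    for culture, members in order.items():
        idx = [expr.sample_ids.index(s) for s in members]
        cultures.append(culture)
        cols.append(expr.values[:, idx].mean(axis=1))
    return ExpressionMatrix(list(expr.gene_ids), cultures,
                            np.column_stack(cols), expr.normalization)
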