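"""Gated forward beam search over logistic-regression gene signatures.

The search grows signatures one gene at a time, up to ``max_size`` genes.
A candidate survives a step only if (i) the newly added gene is at least
marginally significant (Wald p < ``p_new``, default 0.15) and every other
gene remains significant (p < ``p_retained``, default 0.05), and (ii) it
ranks in the top ``keep_fraction`` (default 50%) of gated candidates by
mean AUC under repeated stratified k-fold cross-validation. The final
classifier is the model with the highest CV AUC among those whose train
AND test ROC-AUC strictly exceed a selection threshold (0.85, lowered to
0.75 when unattained).

Logistic fits use a dedicated Newton (IRLS) solver with Wald p-values from
the observed information; the search refits on the order of 1e5 small
models per run, so per-fit overhead matters. Separated or non-converged
fits are treated as gate failures, never as errors, so the beam continues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import ExpressionMatrix, FAVORABLE, UNFAVORABLE


@dataclass
class SearchConfig:
    max_size: int = 12
    p_new: float = 0.15
    p_retained: float = 0.05
    cv_folds: int = 3
    cv_repeats: int = 5
    keep_fraction: float = 0.5
    auc_select_threshold: float = 0.85
    classification_threshold: float = 0.5
    seed: int = 0
    beam_width: Optional[int] = 50  # None = unbounded (spec-literal exhaustive)

    def __post_init__(self):
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.p_retained > self.p_new:
            raise ValueError("p_retained must be <= p_new")


@dataclass
class GeneSignatureModel:
    """Ordered gene set with logistic coefficients (unfavorable = 1)."""

    genes: tuple
    intercept: float
    coefficients: np.ndarray
    p_values: np.ndarray
    train_auc: float
    cv_auc: float = float("nan")
    test_auc: float = float("nan")
    converged: bool = True
    separation: bool = False
    outcome_coding: str = "unfavorable=1"

    def __post_init__(self):
        self.genes = tuple(self.genes)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.genes) != self.coefficients.size or \
                len(self.genes) != self.p_values.size:
            raise ValueError("genes/coefficients/p_values lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = self.coefficients.tolist()
        d["p_values"] = self.p_values.tolist()
        d["genes"] = list(self.genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneSignatureModel":
        return cls(**d)


@dataclass
class LabeledCohort:
    """Expression restricted to candidate genes plus a binary outcome.

    ``y`` is 1 for unfavorable prognosis. Uncertain-status patients must
    be excluded before construction.
    """

    expr: ExpressionMatrix
    y: np.ndarray
    split: str = "train"

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.shape != (self.expr.n_samples,):
            raise ValueError("outcome length does not match samples")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("outcomes must be 0/1")
        self.y = self.y.astype(float)
        # samples x genes design cache for fast column gathering
        self._X = np.ascontiguousarray(self.expr.values.T)
        self._gene_pos = {g: i for i, g in enumerate(self.expr.gene_ids)}

    def design(self, genes: Sequence[str]) -> np.ndarray:
        idx = [self._gene_pos[g] for g in genes]
        return self._X[:, idx]


# ---------------------------------------------------------------------------
# logistic core

_SEP_LP = 30.0       # |linear predictor| beyond which fitted probs are 0/1
_SEP_COEF = 1e4


def _newton_logistic(X: np.ndarray, y: np.ndarray, beta0=None,
                     tol: float = 1e-10, max_iter: int = 40):
    """ML logistic fit; returns (beta, cov, converged, separated, singular).

    ``X`` must already contain the intercept column. ``cov`` is the inverse
    observed information.
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.array(beta0, dtype=float)
    converged = False
    singular = False
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        g = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(k), g)
        except np.linalg.LinAlgError:
            singular = True
            break
        # step-halving on the log-likelihood
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        new = beta + step
        for _h in range(20):
            eta_n = np.clip(X @ new, -500, 500)
            ll_new = np.sum(y * eta_n - np.logaddexp(0.0, eta_n))
            if ll_new >= ll - 1e-12:
                break
            new = beta + (new - beta) * 0.5
        beta = new
        if np.max(np.abs(step)) < tol or abs(ll_new - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            break
        ll_old = ll_new
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    separated = bool(np.max(np.abs(beta)) > _SEP_COEF or
                     (np.max(np.abs(eta)) > _SEP_LP and
                      np.all((p > 0.5) == (y > 0.5))))
    try:
        cov = np.linalg.inv(H)
        if np.any(~np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            singular = True
            cov = np.full((k, k), np.nan)
    except np.linalg.LinAlgError:
        singular = True
        cov = np.full((k, k), np.nan)
    return beta, cov, converged, separated, singular


def _wald_p(beta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    return 2.0 * stats.norm.sf(np.abs(z))


def fit_logistic(genes: Sequence[str], cohort: LabeledCohort,
                 beta0=None) -> GeneSignatureModel:
    """Maximum-likelihood logistic fit of ``y ~ genes``.

    Non-convergence, separation, and singular designs are reported via
    flags on the returned model, never silently.
    """
    y = cohort.y
    if y.min() == y.max():
        raise ValueError("cohort must contain both outcome classes")
    G = cohort.design(genes)
    X = np.column_stack([np.ones(len(y)), G])
    beta, cov, converged, separated, singular = _newton_logistic(X, y, beta0)
    pvals = _wald_p(beta, cov)[1:] if not singular else np.full(len(genes), np.nan)
    scores = X @ beta
    model = GeneSignatureModel(
        genes=tuple(genes), intercept=float(beta[0]), coefficients=beta[1:],
        p_values=pvals, train_auc=roc_auc(scores, y),
        converged=converged and not singular, separation=separated)
    return model


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute ROC-AUC")
    r = stats.rankdata(scores)
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# cross-validation

def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample; class proportions preserved per fold."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} samples; cannot "
                             f"stratify into {k} folds")
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _cv_fold_sets(n: int, y: np.ndarray, config: SearchConfig
                  ) -> List[np.ndarray]:
    """One fold-assignment vector per repeat, deterministic in the seed."""
    out = []
    for rep in range(config.cv_repeats):
        rng = np.random.default_rng([config.seed % (2 ** 31), rep, 2077])
        out.append(_stratified_folds(y, config.cv_folds, rng))
    return out

def _cv_mean_auc(genes: Sequence[str], cohort: LabeledCohort,
                 fold_sets: List[np.ndarray], config: SearchConfig,
                 beta0=None) -> float:
    """Mean held-out AUC over repeats x folds for one gene set."""
    y = cohort.y
    G = cohort.design(genes)
    X = np.column_stack([np.ones(len(y)), G])
    aucs = []
    for folds in fold_sets:
        for f in range(config.cv_folds):
            test = folds == f
            train = ~test
            beta, _, _, _, singular = _newton_logistic(X[train], y[train], beta0)
            if singular:
                return float("nan")
            aucs.append(roc_auc(X[test] @ beta, y[test]))
    return float(np.mean(aucs))


def cv_auc(genes: Sequence[str], cohort: LabeledCohort,
           config: SearchConfig = SearchConfig()) -> float:
    """Repeated stratified k-fold CV mean AUC (deterministic in seed)."""
    fold_sets = _cv_fold_sets(cohort.expr.n_samples, cohort.y, config)
    return _cv_mean_auc(genes, cohort, fold_sets, config)


# ---------------------------------------------------------------------------
# beam search

def _sort_key(m: GeneSignatureModel):
    # higher CV AUC first, then higher train AUC, then lexicographic genes
    return (-m.cv_auc, -m.train_auc, tuple(sorted(m.genes)))


def _gate(model: GeneSignatureModel, new_gene_candidates: set,
          config: SearchConfig) -> bool:
    """Significance gate for a candidate gene set.

    The most weakly significant gene must either pass ``p_retained`` or be
    one of the genes this set was reached through (the "new" gene), which
    only needs ``p_new``.
    """
    if not model.converged or model.separation:
        return False
    p = model.p_values
    if np.any(~np.isfinite(p)):
        return False
    order = {g: i for i, g in enumerate(model.genes)}
    worst = max(model.genes, key=lambda g: p[order[g]])
    for g in model.genes:
        pv = p[order[g]]
        if g == worst:
            continue
        if not pv < config.p_retained:
            # two genes above p_retained can never pass
            return False
    p_worst = p[order[worst]]
    if p_worst < config.p_retained:
        return True
    return (worst in new_gene_candidates) and (p_worst < config.p_new)


def _prune(gated: List[GeneSignatureModel], config: SearchConfig
           ) -> List[GeneSignatureModel]:
    gated = sorted(gated, key=_sort_key)
    keep = math.ceil(config.keep_fraction * len(gated))
    kept = gated[:keep]
    if config.beam_width is not None:
        kept = kept[:config.beam_width]
    return kept


def beam_step(survivors: List[GeneSignatureModel], gene_pool: Sequence[str],
              train: LabeledCohort, config: SearchConfig,
              _fold_sets: Optional[List[np.ndarray]] = None,
              _counts: Optional[dict] = None) -> List[GeneSignatureModel]:
    """Extend every survivor by every unused pool gene, gate, CV-prune.

    Gene sets reached via different orders are collapsed to one candidate;
    the significance gate may be satisfied through any of the orders. Empty
    output means no candidate survived gating and the search stops here.
    """
    if not survivors:
        return []
    sizes = {len(m.genes) for m in survivors}
    if len(sizes) != 1:
        raise ValueError("survivors must all have the same size")
    (s,) = sizes
    if s >= config.max_size:
        return []
    if _fold_sets is None:
        _fold_sets = _cv_fold_sets(train.expr.n_samples, train.y, config)

    candidates: Dict[frozenset, Tuple[tuple, set, np.ndarray]] = {}
    raw = 0
    for parent in survivors:
        parent_set = set(parent.genes)
        warm = np.concatenate([[parent.intercept], parent.coefficients, [0.0]])
        for g in gene_pool:
            if g in parent_set:
                continue
            raw += 1
            key = frozenset(parent.genes) | {g}
            if key in candidates:
                candidates[key][1].add(g)
            else:
                candidates[key] = (parent.genes + (g,), {g}, warm)
    if _counts is not None:
        _counts["raw_candidates"] = raw
        _counts["unique_candidates"] = len(candidates)

    gated: List[GeneSignatureModel] = []
    for key, (genes, new_genes, warm) in candidates.items():
        model = fit_logistic(genes, train, beta0=warm)
        if _gate(model, new_genes, config):
            gated.append(model)
    if _counts is not None:
        _counts["gated"] = len(gated)
    for m in gated:
        m.cv_auc = _cv_mean_auc(
            m.genes, train, _fold_sets, config,
            beta0=np.concatenate([[m.intercept], m.coefficients]))
    gated = [m for m in gated if np.isfinite(m.cv_auc)]
    return _prune(gated, config)


@dataclass
class SearchRegistry:
    """All retained models by size, with per-step candidate counts."""

    models_by_size: Dict[int, List[GeneSignatureModel]] = field(default_factory=dict)
    step_counts: Dict[int, dict] = field(default_factory=dict)

    @property
    def models(self) -> List[GeneSignatureModel]:
        return [m for s in sorted(self.models_by_size)
                for m in self.models_by_size[s]]

    def summary(self) -> "pd.DataFrame":
        import pandas as pd
        rows = []
        for s in sorted(self.models_by_size):
            c = self.step_counts.get(s, {})
            rows.append({"size": s, "retained": len(self.models_by_size[s]), **c})
        return pd.DataFrame(rows)


def search_signatures(train: LabeledCohort, gene_pool: Sequence[str],
                      config: SearchConfig = SearchConfig()) -> SearchRegistry:
    """Run the full gated beam search from size 1 to ``max_size``.

    Size-1 models must themselves be significant (p < ``p_retained``),
    consistent with the "all other genes significant" rule at later steps.
    """
    gene_pool = list(dict.fromkeys(gene_pool))
    if not gene_pool:
        raise ValueError("empty gene pool")
    missing = [g for g in gene_pool if g not in train._gene_pos]
    if missing:
        raise KeyError(f"pool genes absent from cohort: {', '.join(missing)}")

    fold_sets = _cv_fold_sets(train.expr.n_samples, train.y, config)
    registry = SearchRegistry()

    gated = []
    for g in gene_pool:
        m = fit_logistic((g,), train)
        if m.converged and not m.separation and np.isfinite(m.p_values[0]) \
                and m.p_values[0] < config.p_retained:
            gated.append(m)
    for m in gated:
        m.cv_auc = _cv_mean_auc(m.genes, train, fold_sets, config)
    gated = [m for m in gated if np.isfinite(m.cv_auc)]
    survivors = _prune(gated, config)
    registry.models_by_size[1] = survivors
    registry.step_counts[1] = {"raw_candidates": len(gene_pool),
                               "unique_candidates": len(gene_pool),
                               "gated": len(gated)}

    size = 1
    while survivors and size < config.max_size:
        counts: dict = {}
        survivors = beam_step(survivors, gene_pool, train, config,
                              _fold_sets=fold_sets, _counts=counts)
        size += 1
        if survivors:
            registry.models_by_size[size] = survivors
        registry.step_counts[size] = counts
    return registry


@dataclass
class SelectionResult:
    model: Optional[GeneSignatureModel]
    threshold: float
    n_passing: int

    @property
    def threshold_attained(self) -> bool:
        return self.model is not None


def select_best(registry: SearchRegistry, train: LabeledCohort,
                test: LabeledCohort, config: SearchConfig = SearchConfig()
                ) -> SelectionResult:
    """Pick the highest-CV-AUC model among those beating the AUC threshold
    on BOTH train and test; explicit no-model result when none passes."""
    thr = config.auc_select_threshold
    passing = []
    for m in registry.models:
        Xte = np.column_stack([np.ones(test.expr.n_samples), test.design(m.genes)])
        m.test_auc = roc_auc(Xte @ np.concatenate([[m.intercept], m.coefficients]),
                             test.y)
        if m.train_auc > thr and m.test_auc > thr:
            passing.append(m)
    if not passing:
        return SelectionResult(model=None, threshold=thr, n_passing=0)
    best = min(passing, key=_sort_key)
    return SelectionResult(model=best, threshold=thr, n_passing=len(passing))


def classify(model: GeneSignatureModel, expr: ExpressionMatrix,
             threshold: float = 0.5):
    """Per-sample predicted status and probability of unfavorable outcome.

    Probability strictly above the threshold maps to "unfavorable"; a
    linear predictor of exactly 0 (probability 0.5 at the default
    threshold) therefore maps to "favorable".
    """
    idx = expr.gene_index(model.genes)  # raises listing missing genes
    X = expr.values[idx].T
    eta = model.intercept + X @ model.coefficients
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    labels = np.where(prob > threshold, UNFAVORABLE, FAVORABLE)
    return labels, prob


def split_cohort(expr: ExpressionMatrix, y: np.ndarray, train_fraction: float = 0.70,
                 seed: int = 0) -> Tuple[LabeledCohort, LabeledCohort]:
    """Seeded stratified train/test split of a labelled cohort."""
    y = np.asarray(y)
    rng = np.random.default_rng([int(seed) % (2 ** 31), 4242])
    train_idx = []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        k = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:k])
    train_mask = np.zeros(len(y), dtype=bool)
    train_mask[train_idx] = True
    samples = np.array(expr.sample_ids)
    tr = LabeledCohort(expr.subset_samples(list(samples[train_mask])),
                       y[train_mask], split="train")
    te = LabeledCohort(expr.subset_samples(list(samples[~train_mask])),
                       y[~train_mask], split="test")
    return tr, te


def save_model(model: GeneSignatureModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_model(path) -> GeneSignatureModel:
    with open(path) as fh:
        return GeneSignatureModel.from_dict(json.load(fh))
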