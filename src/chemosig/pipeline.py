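"""Convenience orchestration of the full discovery chain.

These helpers wire the stages together the way the analyses are meant to
be run: label a cohort by the 5-year rule, drop uncertain patients, split
stratified 70/30, beam-search the pool, and select at the AUC threshold —
falling back from 0.85 to 0.75 when no model attains the stricter bar,
mirroring how the selection is applied to noisier cohorts.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .datamodel import CohortTable, ExpressionMatrix, UNCERTAIN, UNFAVORABLE
from .signature import (LabeledCohort, SearchConfig, SearchRegistry,
                        SelectionResult, search_signatures, select_best,
                        split_cohort)
from .survival import define_prognostic_status


def cohort_to_labeled(expr: ExpressionMatrix, cohort: CohortTable,
                      horizon: float = 5.0) -> Tuple[ExpressionMatrix, np.ndarray]:
    """Expression and 0/1 outcome restricted to definite-status patients."""
    status = cohort.prognostic_status
    if status is None:
        status = define_prognostic_status(cohort, horizon=horizon)
    keep = status != UNCERTAIN
    samples = [s for s, k in zip(cohort.sample_ids, keep) if k]
    y = (status[keep] == UNFAVORABLE).astype(int)
    return expr.subset_samples(samples), y


def discover_signature(expr: ExpressionMatrix, cohort: CohortTable,
                       gene_pool: Optional[Sequence[str]] = None,
                       config: SearchConfig = SearchConfig(),
                       train_fraction: float = 0.70,
                       fallback_threshold: float = 0.75
                       ) -> Tuple[SearchRegistry, SelectionResult,
                                  LabeledCohort, LabeledCohort]:
    """Label, split, search, and select; returns everything for inspection."""
    sub, y = cohort_to_labeled(expr, cohort)
    train, test = split_cohort(sub, y, train_fraction=train_fraction,
                               seed=config.seed)
    pool = list(gene_pool) if gene_pool is not None else list(sub.gene_ids)
    registry = search_signatures(train, pool, config)
    selection = select_best(registry, train, test, config)
    if selection.model is None and fallback_threshold is not None \
            and fallback_threshold < config.auc_select_threshold:
        import dataclasses
        relaxed = dataclasses.replace(config,
                                      auc_select_threshold=fallback_threshold)
        selection = select_best(registry, train, test, relaxed)
    return registry, selection, train, test
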