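"""Count normalization ahead of correlation screening and classification.

Two transforms are provided:

* ``size_factor_log_transform`` — median-of-ratios size factors (the
  DESeq-family library-size estimator) followed by ``log2(count/sf +
  pseudocount)``. This preserves the rank structure that Spearman screening
  depends on.
* ``tmm_logcpm`` — trimmed mean of M-values scaling factors followed by
  log2 counts-per-million with a library-size-scaled prior count, matching
  the published edgeR definitions (doubly trimmed, precision-weighted mean
  of log-ratios against a reference sample; factors rescaled to geometric
  mean 1).
"""

from __future__ import annotations

import numpy as np

from .datamodel import ExpressionMatrix


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per sample (column).

    The reference profile is the per-gene geometric mean across samples;
    genes containing any zero are excluded from the reference.
    """
    counts = np.asarray(counts, dtype=float)
    ok = np.all(counts > 0, axis=1)
    if not ok.any():
        raise ValueError("no reference genes for size factors "
                         "(every gene has a zero count)")
    geo_mean = np.exp(np.mean(np.log(counts[ok]), axis=1))
    ratios = counts[ok] / geo_mean[:, None]
    return np.median(ratios, axis=0)


def size_factor_log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0
                              ) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount) per entry."""
    if expr.normalization != "raw_counts":
        raise ValueError("size_factor_log_transform expects raw counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sf = size_factors(expr.values)
    vals = np.log2(expr.values / sf[None, :] + pseudocount)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            vals, "log_size_factor")


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float,
                     lib_ref: float, trim_m: float, trim_a: float) -> float:
    """log2 TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic variance of M per gene; weights are its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    # rank with average ties, 1-based, as the reference implementation does
    from scipy.stats import rankdata
    rm = rankdata(m)
    ra = rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any() or not np.any(v[keep2] > 0):
        return 0.0
    return float(np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2]))


def tmm_factors(counts: np.ndarray, reference: int | str = "auto",
                trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """TMM scaling factors, rescaled to geometric mean 1.

    ``reference`` is a column index or ``"auto"`` (sample whose
    upper-quartile fraction is closest to the mean upper-quartile).
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size at column(s) "
                         f"{np.where(lib == 0)[0].tolist()}")
    if not (0 <= trim_m < 0.5 and 0 <= trim_a < 0.5):
        raise ValueError("trim fractions must lie in [0, 0.5)")
    if reference == "auto":
        f75 = np.quantile(counts / lib[None, :], 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = int(reference)
    logf = np.array([
        _tmm_pair_factor(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                         trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def tmm_logcpm(expr: ExpressionMatrix, reference: int | str = "auto",
               trim_m: float = 0.30, trim_a: float = 0.05,
               prior_count: float = 0.5) -> ExpressionMatrix:
    """TMM-normalized log2 counts per million.

    The prior count is scaled per sample in proportion to effective library
    size, which makes the transform exactly invariant to pure sequencing
    depth differences.
    """
    if expr.normalization != "raw_counts":
        raise ValueError("tmm_logcpm expects raw counts")
    counts = expr.values
    lib = counts.sum(axis=0)
    factors = tmm_factors(counts, reference=reference, trim_m=trim_m, trim_a=trim_a)
    eff_lib = lib * factors
    pc = prior_count * eff_lib / eff_lib.mean()
    vals = np.log2((counts + pc[None, :]) / (eff_lib + 2 * pc)[None, :] * 1e6)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            vals, "tmm_logcpm")
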