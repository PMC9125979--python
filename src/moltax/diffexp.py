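"""Differential expression: median-of-ratios size factors, a negative-binomial
Wald test for endotype-versus-control contrasts, and Benjamini-Hochberg FDR.

The DE stage here is a deliberately simplified NB Wald model: per-gene
method-of-moments dispersion, no dispersion shrinkage, no outlier filtering
and no independent filtering.  Downstream stages only need calibrated
p-values and signed log2 fold changes, not a numerical replica of any
particular DE package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import check_probabilities

__all__ = ["size_factors", "de_test", "bh_adjust"]

#: adjusted-p threshold used everywhere a "significant DEG" is needed
ALPHA_PADJ = 0.05


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving.

    padj(i) = min over j with p(j) >= p(i) of p(j) * m / rank(j), capped at 1.
    """
    p = check_probabilities(pvals)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts : DataFrame
        Gene-by-sample non-negative integer counts.

    Genes with a zero count in any sample are excluded from the reference
    geometric mean (their log geomean is -inf).  If no gene is expressed in
    every sample, falls back to total-count ratios with a warning.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a gene x sample matrix")
    with np.errstate(divide="ignore"):
        loggeo = np.mean(np.log(mat), axis=1)
    eligible = np.isfinite(loggeo)
    if eligible.any():
        ratios = mat[eligible] / np.exp(loggeo[eligible])[:, None]
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no gene has nonzero counts in all samples; "
            "falling back to total-count size factors",
            stacklevel=2,
        )
        totals = mat.sum(axis=0)
        factors = np.where(totals > 0, totals, 1.0)
    factors = np.where(factors > 0, factors, 1.0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def de_test(
    counts: pd.DataFrame,
    group_a,
    group_b,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of group A versus group B, per gene.

    The model: normalized counts c/s have mean mu and variance
    mu/s + alpha * mu^2 with a gene-wise dispersion alpha estimated by the
    method of moments (pooled across the two groups, floored at 1e-8).  The
    reported effect is log2((mu_a + 0.5) / (mu_b + 0.5)) with a delta-method
    standard error, a two-sided normal p-value, and BH-adjusted p across all
    tested genes.

    Genes with zero counts in both groups are excluded from testing and
    returned with ``tested = False``.

    Returns
    -------
    DataFrame indexed by gene with columns
    base_mean, log2fc, se, wald, pvalue, padj, tested.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if factors is None:
        factors = size_factors(counts[group_a + group_b])
    sf = factors.reindex(group_a + group_b)
    if sf.isna().any():
        raise ValueError("size factors missing for some samples")

    norm = counts[group_a + group_b].to_numpy(dtype=float) / sf.to_numpy()
    na, nb = len(group_a), len(group_b)
    qa, qb = norm[:, :na], norm[:, na:]

    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    tested = (mu_a > 0) | (mu_b > 0)

    # pooled method-of-moments dispersion: alpha = (s2 - mu) / mu^2
    def _mom(q, mu):
        s2 = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        return np.where(np.isfinite(a), a, 0.0)

    alpha = ((na - 1) * _mom(qa, mu_a) + (nb - 1) * _mom(qb, mu_b)) / (na + nb - 2)
    alpha = np.maximum(alpha, 1e-8)

    inv_sa = np.mean(1.0 / sf.to_numpy()[:na])
    inv_sb = np.mean(1.0 / sf.to_numpy()[na:])
    var_mu_a = (mu_a * inv_sa + alpha * mu_a**2) / na
    var_mu_b = (mu_b * inv_sb + alpha * mu_b**2) / nb

    pa, pb = mu_a + 0.5, mu_b + 0.5
    log2fc = np.log2(pa / pb)
    se = np.sqrt(var_mu_a / pa**2 + var_mu_b / pb**2) / np.log(2)
    se = np.maximum(se, 1e-12)
    wald = log2fc / se
    pval = 2.0 * stats.norm.sf(np.abs(wald))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame(
        {
            "base_mean": (mu_a * na + mu_b * nb) / (na + nb),
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "pvalue": pval,
            "padj": np.nan,
            "tested": tested,
        },
        index=counts.index,
    )
    out.loc[~tested, ["log2fc", "se", "wald", "pvalue"]] = np.nan
    out.loc[tested, "padj"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    return out
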