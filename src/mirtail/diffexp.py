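"""Simplified negative-binomial differential expression.

A documented surrogate for a DESeq2-style analysis: median-of-ratios size
factors, a strict baseMean > 10 expression filter, a per-miRNA NB Wald test
with a moment dispersion estimate, Benjamini-Hochberg adjustment, and the
cross-experiment log2FC signature regression.  Dispersion shrinkage, Cook's
filtering and independent filtering are deliberately not reproduced; all
claims are about this surrogate, not about DESeq2 equivalence.

Model
-----
For miRNA *i* with normalized counts, group means ``m_A``/``m_B`` and pooled
within-group variance ``s^2``:

* dispersion  ``alpha = max((s^2 - mu) / mu^2, 1e-8)`` with ``mu`` the grand
  mean of normalized counts,
* ``log2FC = log2((m_B + 0.5) / (m_A + 0.5))`` (pseudocount keeps FC finite),
* NB variance ``v_g = m_g + alpha m_g^2`` per group, delta-method standard
  error ``SE^2 = v_A / (n_A (m_A+0.5)^2 ln^2 2) + v_B / (n_B (m_B+0.5)^2
  ln^2 2)``,
* Wald ``z = log2FC / SE`` with a two-sided standard-normal p-value.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, the median over all-nonzero miRNAs of the ratio of its
    count to the per-miRNA geometric mean.  Errors if no miRNA is nonzero in
    every sample (callers may then fall back to a pseudo-reference).
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no miRNA has nonzero counts in all samples; median-of-ratios "
            "normalization needs at least one (consider a pseudo-reference fallback)"
        )
    sub = mat[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def base_mean(counts: pd.DataFrame, factors: pd.Series) -> pd.Series:
    """Mean of size-factor-normalized counts across all samples."""
    return (counts / factors).mean(axis=1).rename("baseMean")


def filter_base_mean(counts: pd.DataFrame, factors: pd.Series, cutoff: float = 10.0) -> pd.Index:
    """Rows retained for testing: baseMean strictly greater than the cutoff."""
    bm = base_mean(counts, factors)
    return counts.index[bm > cutoff]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    cm: CountMatrix,
    groups: Mapping[str, str],
    base_mean_cutoff: float = 10.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-miRNA NB Wald test of condition B vs A on normalized counts.

    ``groups`` maps sample_id to "A" (control) or "B" (treatment); the sign
    convention is log2FC > 0 for miRNAs higher in B.  Rows with baseMean <=
    ``base_mean_cutoff`` are excluded before testing and adjustment.
    """
    counts = cm.counts
    a_cols = [s for s in counts.columns if groups[s] == "A"]
    b_cols = [s for s in counts.columns if groups[s] == "B"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    factors = size_factors(counts)
    norm = counts / factors
    bm = base_mean(counts, factors)
    keep = bm.index[bm > base_mean_cutoff]
    norm = norm.loc[keep]

    na, nb = len(a_cols), len(b_cols)
    m_a = norm[a_cols].mean(axis=1).to_numpy()
    m_b = norm[b_cols].mean(axis=1).to_numpy()
    var_a = norm[a_cols].var(axis=1, ddof=1).to_numpy()
    var_b = norm[b_cols].var(axis=1, ddof=1).to_numpy()
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    mu = norm.mean(axis=1).to_numpy()
    alpha = np.maximum((s2 - mu) / np.maximum(mu, 1e-300) ** 2, 1e-8)

    log2fc = np.log2((m_b + pseudocount) / (m_a + pseudocount))
    v_a = m_a + alpha * m_a**2
    v_b = m_b + alpha * m_b**2
    se2 = v_a / (na * (m_a + pseudocount) ** 2 * LN2**2) + v_b / (
        nb * (m_b + pseudocount) ** 2 * LN2**2
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))

    result = pd.DataFrame(
        {
            "baseMean": bm.loc[keep].to_numpy(),
            "log2FC": log2fc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
        },
        index=keep,
    ).rename_axis("mirna_id")
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    result["direction"] = np.sign(result["log2FC"]).astype(int)
    return result


def signature_regression(
    results_x: pd.DataFrame, results_y: pd.DataFrame, alpha: float = 0.05
) -> dict[str, float]:
    """OLS of Y log2FC on X log2FC over miRNAs significant in both results.

    Returns slope, intercept, r-squared, the number of joined miRNAs and the
    concordant/discordant direction counts.  An inverse relationship between
    two perturbations shows up as a negative slope.
    """
    sig_x = results_x[results_x["padj"] < alpha]
    sig_y = results_y[results_y["padj"] < alpha]
    joined = sig_x[["log2FC"]].join(sig_y[["log2FC"]], how="inner", lsuffix="_x", rsuffix="_y")
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} miRNAs significant in both result sets (need >= 3)")
    fit = stats.linregress(joined["log2FC_x"], joined["log2FC_y"])
    concordant = int((np.sign(joined["log2FC_x"]) == np.sign(joined["log2FC_y"])).sum())
    return {
        "n": len(joined),
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue**2,
        "pvalue": fit.pvalue,
        "concordant": concordant,
        "discordant": len(joined) - concordant,
    }
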