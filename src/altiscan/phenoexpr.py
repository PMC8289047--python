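"""Phenotype PCA and expression-phenotype correlation ranking.

Muscle phenotypes are summarized by their leading principal component
(traits standardized first, since units differ by orders of magnitude);
differentially expressed genes are then ranked by the correlation of their
log-transformed TPM with the per-individual PC scores, and selected at a raw
p-value cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["phenotype_pca", "correlate_expression"]


def phenotype_pca(pheno: pd.DataFrame, trait_cols=None, standardize: bool = True):
    """PCA of a phenotype table.

    ``pheno`` holds one row per individual; ``trait_cols`` defaults to all
    numeric columns.  Constant traits are dropped with a warning.  Returns
    ``(scores, variance_fractions)``; the sign convention makes the
    largest-magnitude score of each component positive, so results are
    reproducible.
    """
    if trait_cols is None:
        trait_cols = [c for c in pheno.columns
                      if pd.api.types.is_numeric_dtype(pheno[c])]
    X = pheno[list(trait_cols)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 individuals")
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 traits")
    if np.isnan(X).any():
        raise ValueError("phenotype table has missing trait values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(trait_cols, keep) if not k]
        warnings.warn(f"dropping constant traits: {dropped}")
        X = X[:, keep]
        sd = sd[keep]
    X = X - X.mean(axis=0)
    if standardize:
        X = X / sd
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    scores = U * s
    for k in range(scores.shape[1]):
        if scores[np.argmax(np.abs(scores[:, k])), k] < 0:
            scores[:, k] = -scores[:, k]
    return scores, frac


def correlate_expression(pc_scores, expr: pd.DataFrame, alpha: float = 0.05,
                         pseudocount: float = 1.0, method: str = "pearson",
                         bh_correct: bool = False) -> pd.DataFrame:
    """Rank genes by correlation of log(TPM + pseudocount) with PC scores.

    ``expr`` is genes x samples (columns aligned with ``pc_scores``).  The
    two-sided p comes from the t transform of r on n-2 degrees of freedom;
    genes are ranked by |r| descending and ``selected`` marks p < alpha
    (optionally after Benjamini-Hochberg adjustment).  Zero-variance genes
    are excluded with a warning.
    """
    scores = np.asarray(pc_scores, dtype=float)
    n = len(scores)
    if expr.shape[1] != n:
        raise ValueError("expression columns and PC scores misaligned")
    if n < 3:
        raise ValueError("need at least 3 individuals")
    X = np.log(expr.to_numpy(dtype=float) + pseudocount)
    if method == "spearman":
        X = sps.rankdata(X, axis=1)
        scores = sps.rankdata(scores)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance genes")
    Xc = X[keep] - X[keep].mean(axis=1, keepdims=True)
    z = scores - scores.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (z ** 2).sum())
    r = (Xc @ z) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2 * sps.t.sf(np.abs(t), df=n - 2))
    out = pd.DataFrame({
        "gene": expr.index[keep],
        "r": r,
        "p": p,
    })
    if bh_correct:
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        ranked = out["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        adj[order] = np.minimum(adj_sorted, 1.0)
        out["p_adj"] = adj
        out["selected"] = out["p_adj"] < alpha
    else:
        out["selected"] = out["p"] < alpha
    out = out.reindex(out["r"].abs().sort_values(ascending=False).index)
    return out.reset_index(drop=True)
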