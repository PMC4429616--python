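"""Per-gene and per-CpG methylation-expression correlations.

Correlations (Pearson or Spearman) are computed within the tumor and the
normal group separately, then mapped through Fisher's variance-stabilizing
transformation z = atanh(r) so that group differences can be tested on an
approximately normal scale with variance 1/(n-3).

Row-wise correlations are vectorized: Spearman is Pearson on ranks
(average ranks for ties), so both methods reduce to standardized row
products against the matched expression rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "CLAMP_DEFAULT",
    "correlate",
    "fisher_z",
    "gene_correlations",
    "cpg_correlations",
]

#: |rho| clamp applied before atanh so perfect correlations stay finite
CLAMP_DEFAULT = 0.999999


def correlate(x, y, method: str = "spearman") -> float:
    """Correlation between two vectors.

    ``method`` is ``"pearson"`` (product-moment) or ``"spearman"`` (rank
    correlation with average ranks for ties).  Vectors must have equal
    length >= 4; a constant vector yields NaN (flagged for exclusion
    downstream rather than raising).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    return float(_rowwise_corr(x[None, :], y[None, :], method)[0])


def fisher_z(rho, clamp: float = CLAMP_DEFAULT):
    """Fisher transformation atanh(rho), with |rho| clamped below 1."""
    r = np.clip(np.asarray(rho, dtype=float), -clamp, clamp)
    out = np.arctanh(r)
    if np.ndim(rho) == 0:
        return float(out)
    return out


def _rowwise_corr(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Correlation of each row of ``a`` with the matching row of ``b``.

    Rows with zero variance in either matrix give NaN.
    """
    if method == "spearman":
        a = rankdata(a, axis=1)
        b = rankdata(b, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _split_groups(groups: pd.Series, samples) -> tuple[list, list]:
    normal = [s for s in samples if groups[s] == "normal"]
    tumor = [s for s in samples if groups[s] == "tumor"]
    if len(normal) < 4 or len(tumor) < 4:
        raise ValueError(
            f"each group needs >= 4 samples (normal={len(normal)}, tumor={len(tumor)})"
        )
    return normal, tumor


def gene_correlations(
    expr: pd.DataFrame,
    meth_gene: pd.DataFrame,
    groups: pd.Series,
    method: str = "spearman",
    clamp: float = CLAMP_DEFAULT,
) -> pd.DataFrame:
    """Per-gene correlation of gene-averaged methylation with expression.

    Returns one row per gene common to both matrices with columns
    gene_id, rho_normal, rho_tumor, n_normal, n_tumor, z_normal, z_tumor,
    method.  Genes constant in either group (undefined correlation) are
    excluded with a logged count.
    """
    genes = expr.index.intersection(meth_gene.index)
    samples = [s for s in expr.columns if s in meth_gene.columns]
    normal, tumor = _split_groups(groups, samples)
    e = expr.loc[genes]
    m = meth_gene.loc[genes]
    rec = pd.DataFrame({"gene_id": genes})
    for label, cols in (("normal", normal), ("tumor", tumor)):
        rho = _rowwise_corr(
            m[cols].to_numpy(dtype=float), e[cols].to_numpy(dtype=float), method
        )
        rec[f"rho_{label}"] = rho
        rec[f"n_{label}"] = len(cols)
        rec[f"z_{label}"] = fisher_z(rho, clamp)
    bad = rec[["rho_normal", "rho_tumor"]].isna().any(axis=1)
    if bad.any():
        logger.info("excluding %d genes with undefined correlation", int(bad.sum()))
    rec = rec[~bad].reset_index(drop=True)
    rec["method"] = method
    return rec


def cpg_correlations(
    expr: pd.DataFrame,
    meth_cpg: pd.DataFrame,
    annot: pd.DataFrame,
    groups: pd.Series,
    method: str = "spearman",
    clamp: float = CLAMP_DEFAULT,
) -> pd.DataFrame:
    """Per-CpG correlation of CpG methylation with its gene's expression.

    One record per (cpg, gene) pair present in both matrices, carrying the
    CpG's absolute and signed TSS distance and genomic position for the
    distance-based analyses downstream.
    """
    annot = annot[annot["cpg_id"].isin(meth_cpg.index) & annot["gene_id"].isin(expr.index)]
    samples = [s for s in expr.columns if s in meth_cpg.columns]
    normal, tumor = _split_groups(groups, samples)
    m = meth_cpg.loc[annot["cpg_id"]]
    e = expr.loc[annot["gene_id"]]
    rec = annot[["cpg_id", "gene_id", "chrom", "pos", "abs_tss_dist", "signed_tss_dist"]].copy()
    rec = rec.reset_index(drop=True)
    for label, cols in (("normal", normal), ("tumor", tumor)):
        rho = _rowwise_corr(
            m[cols].to_numpy(dtype=float), e[cols].to_numpy(dtype=float), method
        )
        rec[f"rho_{label}"] = rho
        rec[f"n_{label}"] = len(cols)
        rec[f"z_{label}"] = fisher_z(rho, clamp)
    bad = rec[["rho_normal", "rho_tumor"]].isna().any(axis=1)
    if bad.any():
        logger.info("excluding %d CpGs with undefined correlation", int(bad.sum()))
    rec = rec[~bad].reset_index(drop=True)
    rec["method"] = method
    return rec
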