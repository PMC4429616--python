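"""Descriptive comparisons of methylation/expression levels and variability.

Per-feature means, standard deviations and robust CVs by group, promoter
(< 1 kb from TSS) vs non-promoter stratification, and nonparametric
group comparisons: Wilcoxon signed-rank for paired contrasts (same
feature, tumor vs normal) and rank-sum for disjoint sets (called genes
vs background), both with Hodges-Lehmann location estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .global_diff import ranksum_shift, wilcoxon_signed_rank
from .io_preprocess import robust_cv

__all__ = [
    "PROMOTER_BOUNDARY_BP",
    "GroupComparison",
    "summarize_features",
    "compare_sets",
    "compare_covariates",
    "pvalue_cpg_count_diagnostic",
]

logger = logging.getLogger(__name__)

#: absolute TSS distance below which a CpG counts as promoter-associated
PROMOTER_BOUNDARY_BP = 1000


@dataclass
class GroupComparison:
    contrast: str
    test: str            # wilcoxon_signed | wilcoxon_ranksum
    estimate: float      # Hodges-Lehmann location (a - b)
    ci95: tuple[float, float]
    p: float
    n_a: int
    n_b: int
    q: float | None = None


def summarize_features(
    matrix: pd.DataFrame,
    groups: pd.Series,
    annot: pd.DataFrame | None = None,
    stratify: bool = False,
    promoter_bp: int = PROMOTER_BOUNDARY_BP,
) -> pd.DataFrame:
    """Per-feature, per-group mean, SD (n-1 denominator) and robust CV.

    With ``stratify`` and a CpG annotation, each feature is additionally
    labeled promoter / non_promoter by absolute TSS distance; otherwise
    the stratum is ``all``.  Groups with fewer than 2 samples get NaN SD
    (flagged via a logged warning).
    """
    frames = []
    for label in ("normal", "tumor"):
        cols = [s for s in matrix.columns if groups.get(s) == label]
        vals = matrix[cols].to_numpy(dtype=float)
        if len(cols) < 2:
            logger.warning("group %s has n=%d < 2; SD undefined", label, len(cols))
        sd = vals.std(axis=1, ddof=1) if len(cols) >= 2 else np.full(len(matrix), np.nan)
        med = np.median(vals, axis=1)
        q75, q25 = np.percentile(vals, [75, 25], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(med != 0.0, 100.0 * (q75 - q25) / med, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.index,
                    "group": label,
                    "mean": vals.mean(axis=1),
                    "sd": sd,
                    "cv_iqr": cv,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if stratify and annot is not None:
        strata = pd.Series(
            np.where(annot["abs_tss_dist"] < promoter_bp, "promoter", "non_promoter"),
            index=annot["cpg_id"],
        )
        out["stratum"] = out["feature_id"].map(strata).fillna("all")
    else:
        out["stratum"] = "all"
    return out


def compare_sets(
    values_a, values_b, paired: bool, contrast: str = "", alternative: str = "two-sided"
) -> GroupComparison:
    """Nonparametric comparison of two value sets.

    ``paired=True`` runs the Wilcoxon signed-rank test on matched values
    (same features, two conditions); ``paired=False`` the two-sample
    Wilcoxon rank-sum (Mann-Whitney) test.  Estimates are
    Hodges-Lehmann: pseudomedian of differences (paired) or median of
    pairwise differences a - b (unpaired), with normal-approximation CIs.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty value sets")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs matched lengths")
        est, lo, hi, p = wilcoxon_signed_rank(a, b, alternative=alternative)
        return GroupComparison(contrast, "wilcoxon_signed", est, (lo, hi), p, a.size, b.size)
    mw = scipy.stats.mannwhitneyu(a, b, alternative=alternative)
    est, lo, hi = ranksum_shift(a, b)
    return GroupComparison(
        contrast, "wilcoxon_ranksum", est, (lo, hi), float(mw.pvalue), a.size, b.size
    )


def compare_covariates(
    gene_set, background, covariate: pd.Series, contrast: str = "covariate"
) -> GroupComparison:
    """Rank-sum comparison of a per-gene covariate between a called set
    and the background (genes in both are removed from the background,
    with a logged count)."""
    gene_set = set(gene_set)
    background = set(background)
    overlap = gene_set & background
    if overlap:
        logger.info("removing %d called genes from background", len(overlap))
        background = background - gene_set
    a = covariate.reindex(sorted(gene_set)).dropna()
    b = covariate.reindex(sorted(background)).dropna()
    return compare_sets(a, b, paired=False, contrast=contrast)


def pvalue_cpg_count_diagnostic(dcg_table: pd.DataFrame) -> dict:
    """Spearman association of -log10 gene p-values with CpG counts.

    A strong association would indicate that the Stouffer combination
    rewards coverage rather than signal; reported per direction.
    """
    out = {}
    for direction, sub in dcg_table.groupby("direction"):
        p = np.clip(sub["p_two_sided"].to_numpy(), 1e-300, 1.0)
        if len(sub) < 4 or sub["n_cpgs"].nunique() < 2:
            out[direction] = {"rho": np.nan, "p": np.nan, "n": len(sub)}
            continue
        rho, pval = scipy.stats.spearmanr(-np.log10(p), sub["n_cpgs"])
        out[direction] = {"rho": float(rho), "p": float(pval), "n": len(sub)}
    return out
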