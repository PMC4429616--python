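"""Reading, writing and preprocessing of expression/methylation tables.

Matrices are pandas DataFrames: rows are features (genes or CpGs), columns
are samples.  Methylation may live on the beta scale (proportions in [0,1])
or the M scale (logit2 of beta); statistics downstream are computed on the
M scale, where values are approximately Gaussian.

The preprocessing sequence mirrors common methylation-array practice:
beta -> M conversion, quantile normalization across the samples of a
dataset, averaging of probes/CpGs into one vector per gene, and
intersection of gene sets across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "aggregate_to_gene",
    "intersect_genes",
    "robust_cv",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_groups",
    "write_bed",
    "read_bed",
    "PreprocessResult",
    "preprocess_dataset",
]

#: columns expected in a CpG/probe annotation table
ANNOTATION_COLUMNS = [
    "cpg_id",
    "chrom",
    "pos",
    "gene_id",
    "tss_pos",
    "strand",
    "signed_tss_dist",
    "abs_tss_dist",
]


def beta_to_m(beta, eps: float = 1e-6):
    """Convert methylation beta values to M values, log2(b / (1 - b)).

    Beta values are clamped to [eps, 1 - eps] so boundary values 0 and 1
    map to large finite M values instead of +/-inf.

    Parameters
    ----------
    beta : array-like or scalar in [0, 1]
    eps : clamping bound, must lie in (0, 0.5)
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    # logistic in base 2, written to avoid overflow for large |M|
    out = 0.5 * (1.0 + np.tanh(0.5 * np.log(2.0) * m))
    if np.ndim(out) == 0:
        return float(out)
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so each shares one reference distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; each column's values are replaced by the reference value at
    their rank, with tied entries receiving the mean of the reference
    quantiles they span.

    Requires >= 2 columns and finite values.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in matrix")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def aggregate_to_gene(matrix: pd.DataFrame, mapping: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Average probe/CpG rows into one row per gene.

    ``mapping`` is either a Series (feature id -> gene id) or a DataFrame
    with columns including the feature id column (``cpg_id`` or
    ``probe_id``) and ``gene_id``.  Features mapping to several genes are
    included in every target gene's average (a warning is logged).
    Features absent from the mapping, and genes with no measured feature,
    are dropped.
    """
    if isinstance(mapping, pd.DataFrame):
        feat_col = "cpg_id" if "cpg_id" in mapping.columns else "probe_id"
        pairs = mapping[[feat_col, "gene_id"]].drop_duplicates()
    else:
        pairs = mapping.rename_axis("feature").reset_index()
        pairs.columns = ["feature", "gene_id"]
        feat_col = "feature"
    multi = pairs[feat_col].duplicated(keep=False)
    if multi.any():
        logger.warning(
            "%d features map to multiple genes; included in every target gene",
            pairs.loc[multi, feat_col].nunique(),
        )
    pairs = pairs[pairs[feat_col].isin(matrix.index)]
    if pairs.empty:
        raise ValueError("no features of the matrix appear in the mapping")
    expanded = matrix.loc[pairs[feat_col]].to_numpy(dtype=float)
    out = (
        pd.DataFrame(expanded, columns=matrix.columns)
        .assign(gene_id=pairs["gene_id"].to_numpy())
        .groupby("gene_id")
        .mean()
    )
    out.columns = matrix.columns
    out.index.name = matrix.index.name
    return out


def intersect_genes(datasets: list[pd.DataFrame]) -> tuple[list[str], list[pd.DataFrame]]:
    """Restrict every gene-level matrix to the genes present in all of them.

    Returns the sorted common gene list and the filtered matrices.
    Raises if the intersection is empty.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    common: set = set(datasets[0].index)
    for d in datasets[1:]:
        common &= set(d.index)
    if not common:
        raise ValueError("empty gene intersection across datasets")
    genes = sorted(common)
    return genes, [d.loc[genes] for d in datasets]


def robust_cv(values) -> float:
    """Robust coefficient of variation: 100 * IQR / median.

    A variability measure resistant to outliers; quartiles use linear
    interpolation between order statistics.  Requires >= 4 values and a
    non-zero median.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("robust_cv needs at least 4 values")
    med = float(np.median(v))
    if med == 0.0:
        raise ValueError("robust_cv undefined for zero median")
    q75, q25 = np.percentile(v, [75, 25])
    return float(100.0 * (q75 - q25) / med)


# ---------------------------------------------------------------------------
# table I/O — TSV with feature ids in the first column, sample ids as header

def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Read a CpG annotation TSV; derives signed/absolute TSS distances if absent."""
    annot = pd.read_csv(path, sep="\t")
    return finalize_annotation(annot)


def finalize_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Fill in signed_tss_dist / abs_tss_dist from pos, tss_pos and strand."""
    annot = annot.copy()
    if "signed_tss_dist" not in annot.columns:
        sign = np.where(annot["strand"] == "-", -1, 1)
        annot["signed_tss_dist"] = (annot["pos"] - annot["tss_pos"]) * sign
    if "abs_tss_dist" not in annot.columns:
        annot["abs_tss_dist"] = annot["signed_tss_dist"].abs()
    if (annot["abs_tss_dist"] != annot["signed_tss_dist"].abs()).any():
        raise ValueError("abs_tss_dist inconsistent with signed_tss_dist")
    dup = annot["cpg_id"].duplicated()
    if dup.any():
        raise ValueError(f"{dup.sum()} duplicated cpg_id rows in annotation")
    return annot


def read_groups(path) -> pd.Series:
    """Read a sample->group table (columns sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    groups = pd.Series(df["group"].to_numpy(), index=df["sample_id"], name="group")
    validate_groups(groups)
    return groups


def validate_groups(groups: pd.Series, samples=None) -> None:
    bad = set(groups.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if {"tumor", "normal"} - set(groups.unique()):
        raise ValueError("both tumor and normal groups must be non-empty")
    if samples is not None:
        missing = set(samples) - set(groups.index)
        if missing:
            raise ValueError(f"{len(missing)} matrix samples missing from groups table")


def write_bed(segments: pd.DataFrame, path) -> None:
    """Write a BED file (0-based half-open) with columns chrom/start/end/name."""
    segments[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if "name" not in bed.columns:
        bed["name"] = [f"seg{i}" for i in range(len(bed))]
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("BED segments must satisfy start < end")
    return bed


@dataclass
class PreprocessResult:
    """Gene- and CpG-level matrices ready for correlation analysis."""

    expression: pd.DataFrame          # genes x samples, normalized log intensity
    methylation_m: pd.DataFrame       # CpGs x samples, M scale, normalized
    methylation_gene_m: pd.DataFrame  # genes x samples, CpG-averaged M values
    annotation: pd.DataFrame
    groups: pd.Series


def preprocess_dataset(
    expression: pd.DataFrame,
    methylation_beta: pd.DataFrame,
    annotation: pd.DataFrame,
    groups: pd.Series,
    *,
    eps: float = 1e-6,
    quantile: bool = True,
    separate_groups: bool = False,
    exclude_chroms: tuple[str, ...] = (),
) -> PreprocessResult:
    """Run the standard preprocessing chain on one tumor/normal dataset.

    Beta values are converted to M values, then quantile-normalized —
    jointly across all samples by default, or within tumor and normal
    separately when ``separate_groups`` is set.  CpGs are averaged per
    gene, and both matrices are restricted to genes with expression and
    methylation measures.
    """
    validate_groups(groups, expression.columns)
    validate_groups(groups, methylation_beta.columns)
    annotation = finalize_annotation(annotation)
    if exclude_chroms:
        keep = ~annotation["chrom"].isin(exclude_chroms)
        logger.info("excluding %d CpGs on chromosomes %s", (~keep).sum(), exclude_chroms)
        annotation = annotation[keep]
    meth = methylation_beta.loc[methylation_beta.index.isin(annotation["cpg_id"])]
    meth_m = pd.DataFrame(
        beta_to_m(meth.to_numpy(dtype=float), eps=eps),
        index=meth.index,
        columns=meth.columns,
    )
    if quantile:
        if separate_groups:
            parts = []
            for label in ("normal", "tumor"):
                cols = [s for s in meth_m.columns if groups[s] == label]
                parts.append(quantile_normalize(meth_m[cols]))
            meth_m = pd.concat(parts, axis=1)[meth.columns]
        else:
            meth_m = quantile_normalize(meth_m)
    gene_m = aggregate_to_gene(meth_m, annotation)
    common, mats = intersect_genes([expression, gene_m])
    expr, gene_m = mats
    annotation = annotation[annotation["gene_id"].isin(common)].reset_index(drop=True)
    meth_m = meth_m.loc[meth_m.index.isin(annotation["cpg_id"])]
    return PreprocessResult(
        expression=expr,
        methylation_m=meth_m,
        methylation_gene_m=gene_m,
        annotation=annotation,
        groups=groups,
    )
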