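"""Gene-level differential-correlation testing.

A gene is a DCG when its methylation-expression correlation differs
between tumor and normal tissue.  Two calling modes:

* ``single_corr`` (27K-style arrays) — one gene-averaged correlation per
  group, tested with the Fisher z-test for the difference of two
  correlations:

      z = (atanh(r_tumor) - atanh(r_normal)) / sqrt(1/(n_t - 3) + 1/(n_n - 3))

* ``stouffer`` (450K-style arrays) — each CpG of a gene contributes two
  one-tailed Fisher z p-values (correlation higher in cancer / lower in
  cancer); each tail is combined across the gene's CpGs with Stouffer's
  Z-score method and the gene-level two-sided p is twice the smaller
  combined tail (capped at 1).  With one CpG this reduces exactly to the
  single-correlation test.

Stouffer combination assumes the per-CpG statistics are independent;
spatial autocorrelation of CpG correlation differences would inflate the
gene-level Type I error, so a Mantel permutation diagnostic between
genomic distance and |Δz| dissimilarity is provided per gene within TSS
distance strata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fisher_corr_diff_test",
    "stouffer_combine",
    "call_dcgs",
    "mantel_autocorrelation",
    "mantel_by_stratum",
    "DISTANCE_STRATA",
]

logger = logging.getLogger(__name__)

#: TSS-distance strata (bp) for the Mantel autocorrelation diagnostic
DISTANCE_STRATA = {
    "within_200bp": (0, 200),
    "bp200_1000": (200, 1000),
    "beyond_1000bp": (1000, None),
}


def _fisher_se(n1, n2, spearman_variance: bool = False) -> float:
    scale = 1.06 if spearman_variance else 1.0
    return math.sqrt(scale / (n1 - 3) + scale / (n2 - 3))


def fisher_corr_diff_test(
    rho1: float,
    n1: int,
    rho2: float,
    n2: int,
    clamp: float = 0.999999,
    spearman_variance: bool = False,
) -> tuple[float, float, float]:
    """Fisher z-test for the difference between two correlations.

    Returns ``(z_stat, p_two, p_greater)`` where ``p_greater`` tests
    H1: rho1 > rho2.  ``spearman_variance`` switches the z variance from
    1/(n-3) to the 1.06/(n-3) variant sometimes used for rank
    correlations.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("each group needs n >= 4")
    z1 = math.atanh(max(-clamp, min(clamp, rho1)))
    z2 = math.atanh(max(-clamp, min(clamp, rho2)))
    z_stat = (z1 - z2) / _fisher_se(n1, n2, spearman_variance)
    p_greater = float(norm.sf(z_stat))
    p_two = float(2.0 * norm.sf(abs(z_stat)))
    return z_stat, min(p_two, 1.0), p_greater


def stouffer_combine(p_onetailed, weights=None) -> float:
    """Stouffer's Z-score combination of one-tailed p-values.

    Z = sum(Phi^-1(1 - p_i)) / sqrt(k); returns 1 - Phi(Z).  Unweighted.
    p-values at 0 or 1 are clamped into (0, 1) with a warning.
    """
    p = np.atleast_1d(np.asarray(p_onetailed, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0.0) | (p >= 1.0)):
        logger.warning("clamping %d boundary p-values", int(((p <= 0) | (p >= 1)).sum()))
        p = np.clip(p, 1e-300, 1.0 - 1e-16)
    if p.size == 1:  # identity: the combination of one p-value is itself
        return float(p[0])
    z = norm.isf(p).sum() / math.sqrt(p.size)
    return float(norm.sf(z))


@dataclass
class _GeneCall:
    gene_id: str
    n_cpgs: int
    p_pos_in_cancer: float
    p_neg_in_cancer: float


def call_dcgs(
    records: pd.DataFrame,
    mode: str = "stouffer",
    alpha_fdr: float = 0.05,
    spearman_variance: bool = False,
) -> pd.DataFrame:
    """Call differentially correlated genes from correlation records.

    ``records`` are per-gene records (``single_corr`` mode) or per-CpG
    records (``stouffer`` mode) as produced by
    :mod:`dcgscan.corr_engine`.  Output has one row per gene with the
    one-tailed p-values (``p_pos_in_cancer`` tests H1: correlation higher
    in cancer), the two-sided p = min(1, 2*min(tails)), BH q-value,
    Bonferroni-adjusted p, the calling direction, an ``is_dcg`` flag at
    ``alpha_fdr``, and the CpG count; sorted by (q, p).
    """
    if mode not in ("single_corr", "stouffer"):
        raise ValueError(f"unknown mode {mode!r}")
    calls: list[_GeneCall] = []
    if mode == "single_corr":
        for row in records.itertuples(index=False):
            _, _, p_pos = fisher_corr_diff_test(
                row.rho_tumor, row.n_tumor, row.rho_normal, row.n_normal,
                spearman_variance=spearman_variance,
            )
            calls.append(_GeneCall(row.gene_id, 1, p_pos, 1.0 - p_pos))
    else:
        z_diff = records["z_tumor"].to_numpy() - records["z_normal"].to_numpy()
        n_t = records["n_tumor"].to_numpy(dtype=float)
        n_n = records["n_normal"].to_numpy(dtype=float)
        scale = 1.06 if spearman_variance else 1.0
        se = np.sqrt(scale / (n_t - 3.0) + scale / (n_n - 3.0))
        zs = z_diff / se
        df = pd.DataFrame({"gene_id": records["gene_id"].to_numpy(), "z": zs})
        for gene_id, sub in df.groupby("gene_id", sort=False):
            z = sub["z"].to_numpy()
            p_pos = norm.sf(z)  # per-CpG, H1: correlation higher in cancer
            calls.append(
                _GeneCall(
                    str(gene_id),
                    z.size,
                    stouffer_combine(p_pos),
                    stouffer_combine(1.0 - p_pos),
                )
            )
    if not calls:
        raise ValueError("no usable genes in records")
    out = pd.DataFrame([vars(c) for c in calls])
    p_min = out[["p_pos_in_cancer", "p_neg_in_cancer"]].min(axis=1)
    out["p_two_sided"] = np.minimum(1.0, 2.0 * p_min)
    out["q_value"] = multipletests(out["p_two_sided"], method="fdr_bh")[1]
    out["bonferroni"] = np.minimum(1.0, out["p_two_sided"] * len(out))
    out["direction"] = np.where(
        out["p_pos_in_cancer"] <= out["p_neg_in_cancer"], "pos_in_cancer", "neg_in_cancer"
    )
    out["is_dcg"] = out["q_value"] < alpha_fdr
    out["mode"] = mode
    return out.sort_values(["q_value", "p_two_sided", "gene_id"]).reset_index(drop=True)


def _mantel_r(a_flat: np.ndarray, b_flat: np.ndarray) -> float:
    a = a_flat - a_flat.mean()
    b = b_flat - b_flat.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return np.nan
    return float((a * b).sum() / denom)


def mantel_autocorrelation(
    positions, delta_z, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Mantel permutation test between genomic distance and |Δz| dissimilarity.

    ``positions`` are CpG genomic coordinates and ``delta_z`` the per-CpG
    z_tumor - z_normal values of one gene.  The statistic is the Pearson
    correlation of the off-diagonal entries of |pos_i - pos_j| and
    |Δz_i - Δz_j|; the p-value permutes CpG labels:
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).

    Returns ``(mantel_r, p)``; r is NaN (p = 1) when a distance matrix is
    constant.
    """
    pos = np.asarray(positions, dtype=float)
    dz = np.asarray(delta_z, dtype=float)
    k = pos.size
    if k < 3:
        raise ValueError("Mantel test needs at least 3 CpGs")
    if n_perm < 100:
        logger.warning("n_perm=%d is low for a permutation p-value", n_perm)
    iu = np.triu_indices(k, 1)
    d_pos = np.abs(pos[:, None] - pos[None, :])
    d_z = np.abs(dz[:, None] - dz[None, :])
    r_obs = _mantel_r(d_pos[iu], d_z[iu])
    if np.isnan(r_obs):
        return np.nan, 1.0
    rng = np.random.default_rng(seed)
    identity = np.arange(k)
    count = 0
    for _ in range(n_perm):
        # the observed arrangement already enters through the "+1", so
        # draws come from the non-identity relabelings
        while True:
            perm = rng.permutation(k)
            if not np.array_equal(perm, identity):
                break
        r_p = _mantel_r(d_pos[np.ix_(perm, perm)][iu], d_z[iu])
        if r_p >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def mantel_by_stratum(
    cpg_records: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    min_cpgs: int = 3,
    pooled: bool = False,
) -> pd.DataFrame:
    """Run the Mantel diagnostic per gene within each TSS-distance stratum.

    Strata follow :data:`DISTANCE_STRATA` on absolute TSS distance.  BH
    q-values are computed across genes within each stratum.  With
    ``pooled=True`` all CpGs of a stratum enter one test (gene identity
    ignored) instead of one test per gene.
    """
    rows = []
    rng = np.random.default_rng(seed)
    dz_all = cpg_records["z_tumor"] - cpg_records["z_normal"]
    for stratum, (lo, hi) in DISTANCE_STRATA.items():
        d = cpg_records["abs_tss_dist"]
        mask = (d >= lo) if hi is None else ((d >= lo) & (d < hi))
        sub = cpg_records[mask]
        dz = dz_all[mask]
        if pooled:
            units = [("pooled", sub, dz)]
        else:
            units = [
                (g, sub.loc[idx], dz.loc[idx])
                for g, idx in sub.groupby("gene_id").groups.items()
            ]
        for gene_id, block, dzb in units:
            if len(block) < min_cpgs or block["pos"].nunique() < 2:
                continue
            r, p = mantel_autocorrelation(
                block["pos"].to_numpy(),
                dzb.to_numpy(),
                n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            if np.isnan(r):
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "stratum": stratum,
                    "mantel_r": r,
                    "p_value": p,
                    "n_cpgs": len(block),
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "stratum", "mantel_r", "p_value", "n_cpgs"])
    out["q_value"] = np.nan
    for stratum, idx in out.groupby("stratum").groups.items():
        out.loc[idx, "q_value"] = multipletests(
            out.loc[idx, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out
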