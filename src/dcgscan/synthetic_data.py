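"""Seeded tumor/normal cohort simulator with known correlation structure.

The generator emulates paired expression/methylation array cohorts: an
expression matrix (genes x samples, log-intensity scale), a methylation
matrix (CpGs x samples, beta scale), a CpG annotation with genomic
positions and closest-TSS distances, a sample-group table with unequal
group sizes, and a truth table recording which genes were planted as
differentially correlated (DCGs).

Correlation between a CpG's methylation and its gene's expression is
induced on the M scale through a Gaussian copula: given the gene's latent
standardized expression u, each CpG draws

    M = mu_c + sd * (rho * u + sqrt(1 - rho^2) * v),   v ~ N(0, 1),

so the population M-expression correlation is exactly ``rho`` while the
reported beta = 2^M / (2^M + 1) carries an attenuated correlation (the
logistic map is monotone, so Spearman correlations are unaffected).  The
target rho depends on the group and on the CpG's absolute TSS distance;
by default it is negative near the TSS and mildly positive distally.
CpGs of one gene share only the latent u, so two CpGs with targets
rho_i, rho_j have correlation rho_i * rho_j (independent when either
target is 0).

Planted DCGs split a configured correlation difference symmetrically:
for shift direction d = +/-1, rho_normal -= d * dcg_delta / 2 and
rho_tumor += d * dcg_delta / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .io_preprocess import write_bed

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "default_rho_normal",
    "default_rho_tumor",
    "simulate_dataset",
    "simulate_segment_tracks",
]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def default_rho_normal(abs_dist):
    """Default normal-tissue correlation profile vs absolute TSS distance.

    -0.4 within 2 kb of the TSS, rising smoothly to +0.15 beyond 5 kb —
    the qualitative promoter-repressive / gene-body-positive pattern of
    methylation arrays.
    """
    d = np.asarray(abs_dist, dtype=float)
    return -0.4 + 0.55 * _smoothstep((d - 2000.0) / 3000.0)


def default_rho_tumor(abs_dist):
    """Default tumor profile: slightly more negative than normal near the TSS."""
    d = np.asarray(abs_dist, dtype=float)
    return -0.45 + 0.60 * _smoothstep((d - 2000.0) / 3000.0)


def constant_rho(value: float):
    """A distance-independent correlation profile (handy for null studies)."""

    def fn(abs_dist):
        return np.full_like(np.asarray(abs_dist, dtype=float), float(value))

    return fn


@dataclass
class SimulationConfig:
    """Study-design knobs for one simulated tumor/normal cohort.

    Defaults emulate a 450K-style breast cohort: 8 normal vs 57 tumor
    samples and several CpGs per gene with TSS distances up to 50 kb.
    ``platform_mode="k27"`` switches to the sparse-array regime of 1-2
    CpGs per gene close to the TSS.
    """

    n_genes: int = 200
    n_tumor: int = 57
    n_normal: int = 8
    platform_mode: str = "k450"  # "k27" or "k450"
    cpgs_per_gene_range: tuple[int, int] | None = None
    dcg_fraction: float = 0.0
    rho_normal_fn: Callable = field(default=default_rho_normal)
    rho_tumor_fn: Callable = field(default=default_rho_tumor)
    dcg_delta: float = 0.8
    noise_sd: float = 1.0
    tss_distance_range: tuple[int, int] = (0, 50_000)
    seed: int = 0

    def __post_init__(self):
        if self.platform_mode not in ("k27", "k450"):
            raise ValueError(f"platform_mode must be k27 or k450, got {self.platform_mode}")
        if self.cpgs_per_gene_range is None:
            self.cpgs_per_gene_range = (1, 2) if self.platform_mode == "k27" else (3, 8)
        if self.n_tumor < 4 or self.n_normal < 4:
            raise ValueError("each group needs at least 4 samples")
        if not 0.0 <= self.dcg_fraction <= 1.0:
            raise ValueError("dcg_fraction must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SimulatedDataset:
    expression: pd.DataFrame       # genes x samples, log intensity
    methylation: pd.DataFrame      # CpGs x samples, beta values
    annotation: pd.DataFrame       # CpG -> gene/position/TSS table
    groups: pd.Series              # sample -> tumor|normal
    truth: pd.DataFrame            # per-gene planted ground truth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.methylation.to_csv(out / "methylation.tsv", sep="\t")
        self.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        self.groups.rename_axis("sample_id").reset_index().to_csv(
            out / "groups.tsv", sep="\t", index=False
        )
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


#: genome layout constants for placing genes on toy chromosomes
_GENES_PER_CHROM = 250
_GENE_SPACING = 200_000


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one cohort according to ``config`` (bit-reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    ng, nt, nn = config.n_genes, config.n_tumor, config.n_normal
    lo, hi = config.cpgs_per_gene_range
    n_cpgs_per_gene = rng.integers(lo, hi + 1, size=ng)

    gene_ids = np.array([f"G{i:05d}" for i in range(ng)])
    tumor_ids = [f"T{i:03d}" for i in range(nt)]
    normal_ids = [f"N{i:03d}" for i in range(nn)]
    groups = pd.Series(
        ["tumor"] * nt + ["normal"] * nn, index=tumor_ids + normal_ids, name="group"
    )

    # genomic layout: genes on toy chromosomes, evenly spaced TSSs
    chrom_idx = np.arange(ng) // _GENES_PER_CHROM
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    tss = (np.arange(ng) % _GENES_PER_CHROM + 1) * _GENE_SPACING
    strand = np.where(rng.random(ng) < 0.5, "+", "-")

    # planted DCGs and their shift direction
    n_dcg = int(round(config.dcg_fraction * ng))
    dcg_idx = rng.choice(ng, size=n_dcg, replace=False) if n_dcg else np.array([], dtype=int)
    is_dcg = np.zeros(ng, dtype=bool)
    is_dcg[dcg_idx] = True
    shift_dir = np.zeros(ng)
    shift_dir[dcg_idx] = rng.choice([-1.0, 1.0], size=n_dcg)

    d_lo, d_hi = config.tss_distance_range
    expr_rows = np.empty((ng, nt + nn))
    annot_rows = []
    meth_rows = []
    truth_rho_n = np.empty(ng)
    truth_rho_t = np.empty(ng)

    for g in range(ng):
        k = n_cpgs_per_gene[g]
        abs_dist = np.sort(rng.integers(d_lo, d_hi + 1, size=k))
        side = np.where(rng.random(k) < 0.5, -1, 1)
        rho_n = np.asarray(config.rho_normal_fn(abs_dist), dtype=float) * np.ones(k)
        rho_t = np.asarray(config.rho_tumor_fn(abs_dist), dtype=float) * np.ones(k)
        if is_dcg[g]:
            rho_n = rho_n - shift_dir[g] * config.dcg_delta / 2.0
            rho_t = rho_t + shift_dir[g] * config.dcg_delta / 2.0
        if np.any(np.abs(rho_n) >= 1.0) or np.any(np.abs(rho_t) >= 1.0):
            raise ValueError(
                f"infeasible correlation target for gene {gene_ids[g]}: |rho| >= 1"
            )
        truth_rho_n[g] = rho_n.mean()
        truth_rho_t[g] = rho_t.mean()

        mu_e = rng.uniform(6.0, 12.0)
        mu_m = rng.normal(0.0, 2.0, size=k)  # per-CpG M-value baseline
        u_t = rng.standard_normal(nt)
        u_n = rng.standard_normal(nn)
        expr_rows[g, :nt] = mu_e + config.noise_sd * u_t
        expr_rows[g, nt:] = mu_e + config.noise_sd * u_n
        v_t = rng.standard_normal((k, nt))
        v_n = rng.standard_normal((k, nn))
        m_t = rho_t[:, None] * u_t[None, :] + np.sqrt(1 - rho_t**2)[:, None] * v_t
        m_n = rho_n[:, None] * u_n[None, :] + np.sqrt(1 - rho_n**2)[:, None] * v_n
        m = mu_m[:, None] + 1.5 * np.hstack([m_t, m_n])
        meth_rows.append(m)

        pos = tss[g] + side * abs_dist
        for j in range(k):
            annot_rows.append(
                (
                    f"cg{g:05d}_{j:02d}",
                    chroms[g],
                    int(pos[j]),
                    gene_ids[g],
                    int(tss[g]),
                    strand[g],
                    int(side[j] * abs_dist[j]),
                    int(abs_dist[j]),
                )
            )

    m_all = np.vstack(meth_rows)
    beta = 0.5 * (1.0 + np.tanh(0.5 * np.log(2.0) * m_all))  # 2^M / (2^M + 1)
    # keep betas strictly inside (0, 1) at float precision
    tiny = np.finfo(float).tiny
    beta = np.clip(beta, tiny, 1.0 - 1e-16)

    annotation = pd.DataFrame(
        annot_rows,
        columns=[
            "cpg_id",
            "chrom",
            "pos",
            "gene_id",
            "tss_pos",
            "strand",
            "signed_tss_dist",
            "abs_tss_dist",
        ],
    )
    expression = pd.DataFrame(expr_rows, index=gene_ids, columns=tumor_ids + normal_ids)
    expression.index.name = "gene_id"
    methylation = pd.DataFrame(
        beta, index=annotation["cpg_id"].to_numpy(), columns=tumor_ids + normal_ids
    )
    methylation.index.name = "cpg_id"

    direction = np.where(
        ~is_dcg, "none", np.where(shift_dir > 0, "pos_in_cancer", "neg_in_cancer")
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_dcg": is_dcg,
            "rho_normal_true": truth_rho_n,
            "rho_tumor_true": truth_rho_t,
            "direction_true": direction,
            "n_cpgs": n_cpgs_per_gene,
        }
    )
    return SimulatedDataset(expression, methylation, annotation, groups, truth)


def simulate_segment_tracks(
    n_case: int,
    n_control: int,
    track_hit_rate_case: float,
    track_hit_rate_control: float,
    seed: int = 0,
    segment_length: int = 1000,
    spacing: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene segments plus a synthetic ChIP-seq-like track.

    Returns ``(segments, track)`` as BED-style DataFrames (chrom, start,
    end, name; 0-based half-open).  ``segments`` carries a ``label``
    column marking case/control genes.  Each gene segment is overlapped
    by one track peak with probability equal to its group's hit rate.
    """
    for r in (track_hit_rate_case, track_hit_rate_control):
        if not 0.0 <= r <= 1.0:
            raise ValueError("hit rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    labels = np.array(["case"] * n_case + ["control"] * n_control)
    order = rng.permutation(n)  # interleave cases and controls along the genome
    labels = labels[order]
    starts = np.arange(n) * spacing
    segments = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + segment_length,
            "name": [f"seg{i:04d}" for i in range(n)],
            "label": labels,
        }
    )
    rate = np.where(labels == "case", track_hit_rate_case, track_hit_rate_control)
    hit = rng.random(n) < rate
    peak_len = segment_length // 2
    offsets = rng.integers(0, segment_length - peak_len + 1, size=n)
    track = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts[hit] + offsets[hit],
            "end": starts[hit] + offsets[hit] + peak_len,
            "name": [f"peak{i:04d}" for i in range(int(hit.sum()))],
        }
    )
    return segments, track


def write_tracks(segments: pd.DataFrame, track: pd.DataFrame, out_dir) -> None:
    """Write case/control gene segments and the track as BED files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg = segments.copy()
    seg["name"] = seg["name"] + "|" + seg["label"]
    write_bed(seg, out / "segments.bed")
    write_bed(track, out / "track.bed")
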