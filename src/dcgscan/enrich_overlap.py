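"""Gene-set enrichment and Monte-Carlo genomic overlap testing.

Two complementary tests for asking whether called (case) genes share a
genomic or functional feature more than expected:

* hypergeometric enrichment of a called gene set in an annotation gene
  set against a user-supplied background (upper tail);
* a "preferential overlap" Monte-Carlo test: gene segments labeled
  case/control are intersected with a track (e.g. ChIP-seq peaks); the
  statistic is the number of case base pairs covered by the track, and
  the null redistributes the case/control labels over the fixed segment
  set, preserving the case count.  One-sided
  p = (1 + #{null >= observed}) / (1 + n_mc).

Replicate tracks for one factor are merged with Stouffer's method, and
BH correction is applied within user-defined track batches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dcg_caller import stouffer_combine

__all__ = [
    "OverlapTestResult",
    "hypergeometric_enrichment",
    "mc_overlap_test",
    "merge_replicate_tracks",
    "batched_fdr",
]

logger = logging.getLogger(__name__)


def hypergeometric_enrichment(called, annotation, background) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of ``called`` in ``annotation``.

    The annotation is first intersected with the background universe;
    ``called`` must be a subset of the background.  Returns
    ``(overlap, p)`` with p = P[X >= overlap] for
    X ~ Hypergeom(N=|background|, K=|annotation ∩ background|, n=|called|).
    """
    called = set(called)
    background = set(background)
    if not called <= background:
        raise ValueError("called set must be a subset of the background")
    ann = set(annotation) & background
    if not ann:
        raise ValueError("annotation does not intersect the background")
    overlap = len(called & ann)
    p = float(hypergeom.sf(overlap - 1, len(background), len(ann), len(called)))
    return overlap, min(p, 1.0)


def _per_segment_overlap(segments: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Base pairs of each segment covered by the (possibly overlapping) track."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in track.groupby("chrom"):
        t = IntervalTree.from_tuples(zip(sub["start"], sub["end"]))
        t.merge_overlaps()
        trees[chrom] = t
    out = np.zeros(len(segments), dtype=float)
    for i, row in enumerate(segments.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        out[i] = sum(
            min(iv.end, row.end) - max(iv.begin, row.start)
            for iv in tree.overlap(row.start, row.end)
        )
    return out


@dataclass
class OverlapTestResult:
    track_id: str
    observed_stat: float
    mc_p: float
    n_mc: int
    n_case: int
    n_control: int
    statistic: str = "bp_overlap"
    merged_p: float | None = None
    batch: str | None = None
    q: float | None = None


def mc_overlap_test(
    segments: pd.DataFrame,
    track: pd.DataFrame,
    n_mc: int = 1000,
    seed: int = 0,
    statistic: str = "bp_overlap",
    track_id: str = "track",
) -> OverlapTestResult:
    """Monte-Carlo preferential-overlap test of case segments vs a track.

    ``segments`` is a BED-like frame with a ``label`` column in
    {case, control}; ``track`` a BED-like frame (0-based half-open).
    ``statistic`` is ``"bp_overlap"`` (case base pairs covered, default)
    or ``"segment_count"`` (case segments touched).  An empty track gives
    p = 1 (flagged).
    """
    if statistic not in ("bp_overlap", "segment_count"):
        raise ValueError(f"unknown statistic {statistic!r}")
    labels = segments["label"].to_numpy()
    n_case = int((labels == "case").sum())
    n_control = int((labels == "control").sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("need both case and control segments")
    if len(track) == 0:
        logger.warning("empty track %s: p = 1", track_id)
        return OverlapTestResult(track_id, 0.0, 1.0, n_mc, n_case, n_control, statistic)
    per_seg = _per_segment_overlap(segments, track)
    if statistic == "segment_count":
        per_seg = (per_seg > 0).astype(float)
    observed = float(per_seg[labels == "case"].sum())
    rng = np.random.default_rng(seed)
    count = 0
    n = len(per_seg)
    for _ in range(n_mc):
        idx = rng.choice(n, size=n_case, replace=False)
        if per_seg[idx].sum() >= observed - 1e-9:
            count += 1
    p = (1 + count) / (1 + n_mc)
    return OverlapTestResult(track_id, observed, p, n_mc, n_case, n_control, statistic)


def merge_replicate_tracks(p_values) -> float:
    """Stouffer combination of replicate-track p-values for one factor."""
    return stouffer_combine(p_values)


def batched_fdr(
    results: list[OverlapTestResult], batches: dict[str, str]
) -> list[OverlapTestResult]:
    """BH correction applied independently within each track batch.

    ``batches`` maps track_id -> batch name; every result's track must be
    assigned.  The corrected q is attached to each result (using the
    merged p when present, else the raw Monte-Carlo p).
    """
    missing = [r.track_id for r in results if r.track_id not in batches]
    if missing:
        raise ValueError(f"tracks without batch assignment: {missing}")
    by_batch: dict[str, list[OverlapTestResult]] = {}
    for r in results:
        r.batch = batches[r.track_id]
        by_batch.setdefault(r.batch, []).append(r)
    for rs in by_batch.values():
        ps = [r.merged_p if r.merged_p is not None else r.mc_p for r in rs]
        qs = multipletests(ps, method="fdr_bh")[1]
        for r, q in zip(rs, qs):
            r.q = float(q)
    return results


def results_table(results: list[OverlapTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
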