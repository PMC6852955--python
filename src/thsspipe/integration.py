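"""Expression-side computations and ATAC/RNA joins.

Covers the floored log2 FPKM ratio used for differential heatmaps, the
DE-gene/gene-set Fisher overlap test, the nearest-differential-peak
association for gene lists, directed enhancer/THSS overlap accounting,
and a deterministic hierarchical row ordering for heatmap matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from thsspipe.core import (
    INTRAGENIC,
    GeneModel,
    GenomicInterval,
    nearest_feature,
)
from thsspipe.diffacc import DifferentialPeak

__all__ = [
    "GeneSet",
    "NearestPeakAssociation",
    "log2_ratio_fpkm",
    "build_logratio_matrix",
    "geneset_overlap_test",
    "nearest_diff_peak_per_gene",
    "enhancer_overlap_counts",
    "hierarchical_order",
]

#: pseudocount added to both FPKM values before the ratio
FPKM_PSEUDOCOUNT = 1e-4
#: both-below-this FPKM pairs are floored to a log ratio of 0
FPKM_FLOOR = 1.0


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    gene_ids: frozenset[str]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < len(self.gene_ids):
            raise ValueError("universe smaller than the gene set")


@dataclass(frozen=True)
class NearestPeakAssociation:
    gene_id: str
    stage: str
    peak: DifferentialPeak
    distance: int
    within_250kb: bool


def log2_ratio_fpkm(fpkm_hd: float, fpkm_wt: float) -> float:
    """Floored log2 expression ratio between conditions.

    Both values below 1 FPKM return exactly 0 (the pair is treated as
    unexpressed); otherwise log2((hd + 1e-4) / (wt + 1e-4)), the small
    pseudocount guarding against division by zero.
    """
    if fpkm_hd < 0 or fpkm_wt < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm_hd < FPKM_FLOOR and fpkm_wt < FPKM_FLOOR:
        return 0.0
    return math.log2((fpkm_hd + FPKM_PSEUDOCOUNT) / (fpkm_wt + FPKM_PSEUDOCOUNT))


def build_logratio_matrix(
    records: pd.DataFrame,
    gene_order: Sequence[str],
    stage_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Genes x stages matrix of floored log2 FPKM ratios.

    ``records`` needs gene_id, stage, fpkm_hd, fpkm_wt columns; replicate
    rows for the same (gene, stage) are an error — pool replicate FPKMs
    by mean upstream.  Missing (gene, stage) pairs are imputed as (0, 0).
    """
    dup = records.duplicated(subset=["gene_id", "stage"])
    if dup.any():
        raise ValueError("duplicate (gene_id, stage) rows; pool replicates first")
    if stage_order is None:
        stage_order = list(dict.fromkeys(records["stage"]))
    lut = {
        (r.gene_id, r.stage): (r.fpkm_hd, r.fpkm_wt)
        for r in records.itertuples(index=False)
    }
    mat = np.zeros((len(gene_order), len(stage_order)))
    for i, g in enumerate(gene_order):
        for j, s in enumerate(stage_order):
            hd, wt = lut.get((g, s), (0.0, 0.0))
            mat[i, j] = log2_ratio_fpkm(hd, wt)
    return pd.DataFrame(mat, index=list(gene_order), columns=list(stage_order))


def geneset_overlap_test(
    de_genes: set[str], gene_set: GeneSet
) -> tuple[int, float, float]:
    """Fisher overlap of a DE gene list with an annotated gene set.

    The table is N11 = DE genes in the set, N12 = set genes not DE,
    N21 = DE genes among all annotated genes, N22 = non-DE annotated
    genes — nested rows, tested as-is.  Returns (overlap count,
    percentage of the set that is DE, two-sided Fisher p).
    """
    if not gene_set.gene_ids:
        raise ValueError("empty gene set")
    n11 = len(de_genes & gene_set.gene_ids)
    n12 = len(gene_set.gene_ids) - n11
    n21 = len(de_genes)
    n22 = gene_set.universe_size - n21
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    fraction = 100.0 * n11 / len(gene_set.gene_ids)
    return n11, fraction, float(p)


def nearest_diff_peak_per_gene(
    genes: Sequence[GeneModel],
    diff_peaks: Sequence[DifferentialPeak],
    stage: str = "",
    flag_distance: int = 250_000,
) -> tuple[list[NearestPeakAssociation], int]:
    """Nearest differential peak to each gene's TSS, proximal or distal.

    Distance is measured peak-edge to the TSS point, signed positive when
    the peak lies downstream of the TSS in genome coordinates.  Genes
    with no same-chromosome differential peak are skipped and tallied in
    the returned QC count.
    """
    by_peak = {}
    targets = []
    for dp in diff_peaks:
        targets.append(dp.peak.interval)
        by_peak[(dp.peak.chrom, dp.peak.interval.start, dp.peak.interval.end)] = dp
    out: list[NearestPeakAssociation] = []
    skipped = 0
    for g in genes:
        point = GenomicInterval(g.chrom, g.tss, g.tss + 1)
        target, dist = nearest_feature(point, targets)
        if target is None:
            skipped += 1
            continue
        dp = by_peak[(target.chrom, target.start, target.end)]
        out.append(
            NearestPeakAssociation(
                g.gene_id, stage, dp, int(dist), abs(dist) <= flag_distance
            )
        )
    return out, skipped


def enhancer_overlap_counts(
    diff_distal_peaks: Sequence[DifferentialPeak],
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] = (),
) -> dict:
    """Directed overlap accounting between differential distal peaks and
    candidate enhancer regions.

    Enhancers hit by >= 1 peak and peaks hitting >= 1 enhancer are counted
    separately (the two directions differ when regions nest or chain).
    When gene models are supplied the intragenic fraction of the hit
    enhancers is included.
    """
    trees: dict[str, IntervalTree] = {}
    for i, e in enumerate(enhancers):
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, i)
    enhancers_hit: set[int] = set()
    thss_hitting = 0
    for dp in diff_distal_peaks:
        iv = dp.peak.interval
        tree = trees.get(iv.chrom)
        found = tree.overlap(iv.start, iv.end) if tree is not None else ()
        if found:
            thss_hitting += 1
            enhancers_hit.update(h.data for h in found)
    result = {
        "enhancers_hit": len(enhancers_hit),
        "thss_hitting": thss_hitting,
    }
    if genes:
        from thsspipe.core import classify_genic_context

        n_intra = sum(
            1
            for i in enhancers_hit
            if classify_genic_context(enhancers[i], genes) == INTRAGENIC
        )
        result["intragenic_hit"] = n_intra
        result["intragenic_fraction"] = (
            n_intra / len(enhancers_hit) if enhancers_hit else float("nan")
        )
    return result


def hierarchical_order(matrix: np.ndarray | pd.DataFrame) -> list[int]:
    """Deterministic agglomerative row ordering for heatmap display.

    Average linkage on Euclidean distances; the leaf order of the
    resulting dendrogram.  Seed-free and stable for identical input.
    """
    arr = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix must be finite")
    if arr.ndim != 2:
        raise ValueError("need a 2-D matrix")
    if arr.shape[0] <= 1:
        return list(range(arr.shape[0]))
    link = hierarchy.linkage(pdist(arr, metric="euclidean"), method="average")
    return [int(i) for i in hierarchy.leaves_list(link)]
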