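"""MA-normalized differential accessibility testing between two samples.

The procedure follows the MAnorm idea: for each peak compute the log2
count ratio M and mean log2 intensity A between the two samples, fit a
robust line M ~ A over peaks common to both samples, rescale the second
sample so the common-peak trend vanishes, then test each peak with a
two-sided exact binomial test on the normalized counts and adjust with
Benjamini-Hochberg.  Differential peaks must clear a compound criterion:
logCPM (averaged over the two conditions) > 1, and either q < 0.01 or
|logFC| > 3 with p < 0.01; peaks on excluded chromosomes are dropped.

Sample 1 is the test condition (HD), sample 2 the reference (WT);
M and logFC are log2(HD/WT).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from thsspipe.core import (
    DISTAL,
    PROXIMAL,
    Fragment,
    GeneModel,
    Peak,
    window,
)

__all__ = [
    "PeakCounts",
    "NormalizationFit",
    "DifferentialPeak",
    "SelectionCriteria",
    "MAnormModel",
    "MAnormResults",
    "count_fragments_in_peaks",
    "fit_ma_normalization",
    "apply_normalization",
    "diff_pvalue",
    "bh_adjust",
    "select_differential",
    "summarize_differential",
    "summarize_counts",
    "diff_promoter_occupancy",
    "replicate_correlation",
    "common_peak_mask",
]

HD_UP = "HD_up"
HD_DOWN = "HD_down"
NOT_DIFFERENTIAL = "not_differential"

PSEUDOCOUNT = 0.5


@dataclass
class PeakCounts:
    """Per-peak fragment counts for two samples.

    ``counts`` has shape (n_peaks, 2); ``library_sizes`` are the total
    fragment counts of each sample (at least the column sums).
    """

    peaks: list[Peak]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.peaks), 2):
            raise ValueError("counts must be (n_peaks, 2)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if np.any(self.library_sizes + 1e-9 < colsums):
            raise ValueError("library_sizes below column sums")


@dataclass(frozen=True)
class NormalizationFit:
    """The robust M-on-A line removed by normalization."""

    intercept: float
    slope: float
    n_common: int

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("normalization fit is not finite")
        if self.n_common < 0:
            raise ValueError("n_common must be non-negative")


@dataclass(frozen=True)
class DifferentialPeak:
    peak: Peak
    M: float
    A: float
    logCPM: float
    logFC: float
    p: float
    q: float
    direction: str = NOT_DIFFERENTIAL
    proximity: str = ""
    genic_context: str = ""


@dataclass(frozen=True)
class SelectionCriteria:
    """Compound selection rule for differential peaks."""

    min_logCPM: float = 1.0
    q_cut: float = 0.01
    alt_logFC: float = 3.0
    alt_p: float = 0.01
    excluded_chroms: frozenset[str] = frozenset({"chr2a", "chr2b"})


def _ma(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    l1 = np.log2(x1 + PSEUDOCOUNT)
    l2 = np.log2(x2 + PSEUDOCOUNT)
    return l1 - l2, 0.5 * (l1 + l2)


def count_fragments_in_peaks(
    fragments: Sequence[Fragment],
    peaks: Sequence[Peak],
    library_size: Optional[int] = None,
) -> tuple[np.ndarray, int]:
    """Tally fragments per peak; a fragment counts for every peak it
    overlaps by >= 1 bp.  Returns (counts, library_size) where the library
    size defaults to the total number of fragments."""
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, i
        )
    counts = np.zeros(len(peaks), dtype=float)
    for f in fragments:
        tree = trees.get(f.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(f.interval.start, f.interval.end):
            counts[hit.data] += 1
    return counts, (len(fragments) if library_size is None else library_size)


def fit_ma_normalization(
    counts: PeakCounts, common_mask: np.ndarray
) -> NormalizationFit:
    """Robust linear fit of M against A over common peaks.

    Common peaks are assumed equally accessible in both samples, so any
    M-on-A trend among them reflects depth and intensity-dependent bias.
    The fit is an iteratively reweighted M-estimate: a Huber pass for a
    stable start, refined with a redescending Tukey bisquare so that
    genuinely differential peaks hiding in the common set (gross M
    outliers) get zero weight rather than a bounded pull.
    """
    common_mask = np.asarray(common_mask, dtype=bool)
    x1 = counts.counts[common_mask, 0]
    x2 = counts.counts[common_mask, 1]
    usable = (x1 > 0) & (x2 > 0)
    if usable.sum() < 2:
        raise ValueError("need >= 2 common peaks with positive counts in both samples")
    m, a = _ma(x1[usable], x2[usable])
    exog = sm.add_constant(a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            huber = sm.RLM(m, exog, M=sm.robust.norms.HuberT()).fit(
                maxiter=50, tol=1e-8
            )
            res = sm.RLM(m, exog, M=sm.robust.norms.TukeyBiweight()).fit(
                maxiter=50, tol=1e-8, start_params=huber.params
            )
            params = res.params
        except Exception:
            params = np.array([np.nan, np.nan])
        if not np.all(np.isfinite(params)):  # degenerate spread: plain OLS
            params = sm.OLS(m, exog).fit().params
    return NormalizationFit(float(params[0]), float(params[1]), int(usable.sum()))


def apply_normalization(counts: PeakCounts, fit: NormalizationFit) -> PeakCounts:
    """Rescale sample 2 so the fitted common-peak M trend is removed:
    x2' = x2 * 2^(intercept + slope * A), with A from the input counts."""
    x1, x2 = counts.counts[:, 0], counts.counts[:, 1]
    _, a = _ma(x1, x2)
    factor = 2.0 ** (fit.intercept + fit.slope * a)
    new = counts.counts.copy()
    new[:, 1] = x2 * factor
    lib = counts.library_sizes.copy()
    lib[1] = max(lib[1], new[:, 1].sum())
    return PeakCounts(counts.peaks, new, lib)


def diff_pvalue(x1: float, x2: float) -> float:
    """Two-sided exact binomial p for a normalized count pair.

    Counts are rounded half-even; under the null of equal accessibility
    each fragment falls in either sample with probability 1/2.
    Both counts zero returns 1 by convention.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    k1 = int(np.rint(x1))
    k2 = int(np.rint(x2))
    n = k1 + k2
    if n == 0:
        return 1.0
    return float(stats.binomtest(k1, n, 0.5, alternative="two-sided").pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0,1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(
    peaks: Sequence[DifferentialPeak],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> list[DifferentialPeak]:
    """Apply the compound selection rule and assign directions.

    Keep iff logCPM > min_logCPM AND (q < q_cut OR (|logFC| > alt_logFC
    AND p < alt_p)); drop peaks on excluded chromosomes.
    """
    out = []
    for dp in peaks:
        if dp.peak.chrom in criteria.excluded_chroms:
            continue
        if dp.logCPM <= criteria.min_logCPM:
            continue
        if not (
            dp.q < criteria.q_cut
            or (abs(dp.logFC) > criteria.alt_logFC and dp.p < criteria.alt_p)
        ):
            continue
        direction = HD_UP if dp.logFC > 0 else HD_DOWN
        out.append(replace(dp, direction=direction))
    return out


class MAnormModel:
    """Differential accessibility model for one HD-vs-WT comparison.

    Parameters
    ----------
    counts : PeakCounts
        Per-peak fragment counts, column 0 = HD, column 1 = WT.
    common_mask : array of bool, optional
        Peaks treated as common (equally accessible) for normalization.
        Defaults to every peak with positive counts in both samples.
    criteria : SelectionCriteria
        Compound selection thresholds.
    """

    def __init__(
        self,
        counts: PeakCounts,
        common_mask: Optional[np.ndarray] = None,
        criteria: SelectionCriteria = SelectionCriteria(),
    ) -> None:
        self.counts = counts
        if common_mask is None:
            common_mask = (counts.counts > 0).all(axis=1)
        self.common_mask = np.asarray(common_mask, dtype=bool)
        self.criteria = criteria

    @classmethod
    def from_fragments(
        cls,
        fragments_hd: Sequence[Fragment],
        fragments_wt: Sequence[Fragment],
        peaks: Sequence[Peak],
        common_mask: Optional[np.ndarray] = None,
        criteria: SelectionCriteria = SelectionCriteria(),
    ) -> "MAnormModel":
        c1, lib1 = count_fragments_in_peaks(fragments_hd, peaks)
        c2, lib2 = count_fragments_in_peaks(fragments_wt, peaks)
        pc = PeakCounts(list(peaks), np.column_stack([c1, c2]), np.array([lib1, lib2]))
        return cls(pc, common_mask=common_mask, criteria=criteria)

    def fit(self) -> "MAnormResults":
        fit = fit_ma_normalization(self.counts, self.common_mask)
        normalized = apply_normalization(self.counts, fit)
        x1 = normalized.counts[:, 0]
        x2 = normalized.counts[:, 1]
        m_raw, a_raw = _ma(self.counts.counts[:, 0], self.counts.counts[:, 1])
        logfc, _ = _ma(x1, x2)
        # logCPM averaged over conditions: log2 of the mean CPM, computed
        # from the raw counts (depth is what CPM already corrects).
        cpm = (self.counts.counts + PSEUDOCOUNT) / self.counts.library_sizes * 1e6
        logcpm = np.log2(cpm.mean(axis=1))
        pvals = np.array([diff_pvalue(a, b) for a, b in zip(x1, x2)])
        qvals = bh_adjust(pvals)
        table = [
            DifferentialPeak(
                peak=pk,
                M=float(m_raw[i]),
                A=float(a_raw[i]),
                logCPM=float(logcpm[i]),
                logFC=float(logfc[i]),
                p=float(pvals[i]),
                q=float(qvals[i]),
            )
            for i, pk in enumerate(self.counts.peaks)
        ]
        return MAnormResults(self, fit, normalized, table)


class MAnormResults:
    """Fitted differential-accessibility results.

    Attributes
    ----------
    normalization : NormalizationFit
    table : list of DifferentialPeak for every input peak
    selected : the peaks passing the compound criterion, with directions
    """

    def __init__(
        self,
        model: MAnormModel,
        normalization: NormalizationFit,
        normalized_counts: PeakCounts,
        table: list[DifferentialPeak],
    ) -> None:
        self.model = model
        self.normalization = normalization
        self.normalized_counts = normalized_counts
        self.table = table
        self.selected = select_differential(table, model.criteria)

    def annotate(self, genes: Sequence[GeneModel], radius: int = 500) -> None:
        """Attach proximal/distal and genic-context labels in place."""
        from thsspipe.core import classify_genic_context, classify_tss_proximity

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for attr in ("table", "selected"):
                rows = getattr(self, attr)
                setattr(
                    self,
                    attr,
                    [
                        replace(
                            dp,
                            proximity=classify_tss_proximity(
                                dp.peak.interval, genes, radius
                            ),
                            genic_context=classify_genic_context(
                                dp.peak.interval, genes
                            ),
                        )
                        for dp in rows
                    ],
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": dp.peak.chrom,
                "start": dp.peak.interval.start,
                "end": dp.peak.interval.end,
                "summit": dp.peak.summit,
                "name": dp.peak.name,
                "M": dp.M,
                "A": dp.A,
                "logCPM": dp.logCPM,
                "logFC": dp.logFC,
                "p": dp.p,
                "q": dp.q,
                "direction": dp.direction,
                "proximity": dp.proximity,
                "genic_context": dp.genic_context,
            }
            for dp in self.table
        ]
        sel = {(dp.peak.chrom, dp.peak.interval.start, dp.peak.interval.end): dp
               for dp in self.selected}
        df = pd.DataFrame(rows)
        if len(df):
            keys = list(zip(df["chrom"], df["start"], df["end"]))
            df["direction"] = [
                sel[k].direction if k in sel else NOT_DIFFERENTIAL for k in keys
            ]
        return df

    def summary(self) -> str:
        n_up = sum(1 for dp in self.selected if dp.direction == HD_UP)
        n_down = len(self.selected) - n_up
        lines = [
            "MA-normalized differential accessibility",
            "=" * 46,
            f"peaks tested:          {len(self.table)}",
            f"common peaks (fit):    {self.normalization.n_common}",
            f"normalization line:    M = {self.normalization.intercept:+.4f} "
            f"{self.normalization.slope:+.4f}*A",
            f"selected differential: {len(self.selected)}",
            f"  HD-enriched:         {n_up}",
            f"  HD-depleted:         {n_down}",
        ]
        return "\n".join(lines)


def common_peak_mask(
    merged_peaks: Sequence[Peak],
    peaks_hd: Sequence[Peak],
    peaks_wt: Sequence[Peak],
    max_summit_dist: int = 250,
) -> np.ndarray:
    """Mark merged peaks called in both samples.

    A merged peak is common when a peak from each sample overlaps it by
    >= 1 bp or has a summit within ``max_summit_dist`` bp of its summit.
    """

    def tree_of(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for p in peaks:
            lo = min(p.interval.start, p.summit - max_summit_dist)
            hi = max(p.interval.end, p.summit + max_summit_dist + 1)
            trees.setdefault(p.chrom, IntervalTree()).addi(lo, hi)
        return trees

    t1, t2 = tree_of(peaks_hd), tree_of(peaks_wt)
    mask = np.zeros(len(merged_peaks), dtype=bool)
    for i, p in enumerate(merged_peaks):
        s, e = p.interval.start, p.interval.end
        in1 = p.chrom in t1 and bool(t1[p.chrom].overlap(s, e))
        in2 = p.chrom in t2 and bool(t2[p.chrom].overlap(s, e))
        mask[i] = in1 and in2
    return mask


def _pct(part: int, total: int) -> Optional[float]:
    """Percentage rounded half-up to one decimal; None when total is 0."""
    if total == 0:
        return None
    raw = Decimal(part) / Decimal(total) * 100
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_counts(stage_rows: Sequence[dict]) -> pd.DataFrame:
    """Summary-table arithmetic from per-stage component counts.

    Each row needs ``stage``, ``enriched`` and ``depleted`` (counts of
    HD-enriched / HD-depleted differential peaks); optional
    ``proximal_enriched`` / ``proximal_depleted`` / ``distal_enriched`` /
    ``distal_depleted`` splits feed the grand proximal/distal totals.
    Percentages are of the differential total, half-up to one decimal.
    """
    rows = []
    for r in stage_rows:
        enr, dep = int(r["enriched"]), int(r["depleted"])
        total = enr + dep
        rows.append(
            {
                "stage": r["stage"],
                "total_differential": total,
                "enriched": enr,
                "enriched_pct": _pct(enr, total),
                "depleted": dep,
                "depleted_pct": _pct(dep, total),
                "proximal_differential": (
                    int(r.get("proximal_enriched", 0))
                    + int(r.get("proximal_depleted", 0))
                ),
                "distal_differential": (
                    int(r.get("distal_enriched", 0))
                    + int(r.get("distal_depleted", 0))
                ),
            }
        )
    return pd.DataFrame(rows)


def summarize_differential(
    per_stage: dict[str, Sequence[DifferentialPeak]],
) -> pd.DataFrame:
    """Build the per-stage summary from annotated selected peaks."""
    rows = []
    for stage, sel in per_stage.items():
        row = {"stage": stage, "enriched": 0, "depleted": 0}
        for ctx in (PROXIMAL, DISTAL):
            row[f"{ctx}_enriched"] = 0
            row[f"{ctx}_depleted"] = 0
        for dp in sel:
            kind = "enriched" if dp.direction == HD_UP else "depleted"
            row[kind] += 1
            if dp.proximity in (PROXIMAL, DISTAL):
                row[f"{dp.proximity}_{kind}"] += 1
        rows.append(row)
    return summarize_counts(rows)


def diff_promoter_occupancy(
    mono_fragments_hd: Sequence[Fragment],
    mono_fragments_wt: Sequence[Fragment],
    genes: Sequence[GeneModel],
    half_width: int = 1000,
    criteria: SelectionCriteria = SelectionCriteria(),
) -> "MAnormResults":
    """Differential nucleosome occupancy over TSS-centred 2-kb windows.

    Runs the same count / normalize / test / select machinery as peak
    analysis, but on mononucleosome-class fragments and promoter windows.
    """
    windows = [
        Peak(
            window(g.chrom, g.tss, half_width),
            g.tss if g.tss > 0 else half_width // 2,
            name=g.gene_id,
        )
        for g in genes
    ]
    model = MAnormModel.from_fragments(
        mono_fragments_hd, mono_fragments_wt, windows, criteria=criteria
    )
    if not (mono_fragments_hd or mono_fragments_wt):
        return MAnormResults(
            model, NormalizationFit(0.0, 0.0, 0), model.counts, []
        )
    return model.fit()


def replicate_correlation(
    counts_rep1: np.ndarray, counts_rep2: np.ndarray
) -> float:
    """Pearson correlation of log2(count + 1) across a shared peak set.

    Returns NaN when either vector is constant (correlation undefined).
    """
    a = np.log2(np.asarray(counts_rep1, dtype=float) + 1)
    b = np.log2(np.asarray(counts_rep2, dtype=float) + 1)
    if a.shape != b.shape:
        raise ValueError("replicate count vectors must align")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
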