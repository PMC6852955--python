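"""End-to-end orchestration: fragments -> differential peaks -> motif
enrichment -> expression integration, with tabular reports.

Every stage writes plain TSV/BED intermediates under the configured
output directory, and the whole run is deterministic for a given config:
the analysis itself draws no random numbers.
"""

from __future__ import annotations

import dataclasses
import logging
import statistics
import sys
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pyfaidx import Fasta

from thsspipe import diffacc, integration, io, motifs
from thsspipe.core import (
    DISTAL,
    NON_NUCLEOSOMAL,
    Fragment,
    FragmentRejected,
    Peak,
    merge_intervals,
    shift_tn5,
)

__all__ = [
    "AnalysisConfig",
    "RunReport",
    "run_pipeline",
    "render_summary",
    "merge_peak_calls",
    "config_for_dataset",
]

logger = logging.getLogger("thsspipe")

WT_UP = "WT_up"


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run.

    ``fragments`` and ``peak_calls`` map stage -> condition -> list of
    per-replicate BED paths.  All thresholds default to the standard
    values used throughout the package.
    """

    out_dir: str
    genome_fasta: str
    genes_gtf: str
    motifs_meme: str
    expression_tsv: str
    gene_sets_gmt: str
    enhancers_bed: str
    stages: list[str]
    fragments: dict[str, dict[str, list[str]]]
    peak_calls: dict[str, dict[str, list[str]]]
    min_logCPM: float = 1.0
    q_cut: float = 0.01
    alt_logFC: float = 3.0
    alt_p: float = 0.01
    excluded_chroms: list[str] = field(default_factory=lambda: ["chr2a", "chr2b"])
    proximity_radius: int = 500
    summit_half_width: int = 200
    promoter_half_width: int = 1000
    motif_p_threshold: float = 1e-4
    de_q_cutoff: float = 0.05
    nearest_flag_distance: int = 250_000
    seed: int = 0

    def criteria(self) -> diffacc.SelectionCriteria:
        return diffacc.SelectionCriteria(
            min_logCPM=self.min_logCPM,
            q_cut=self.q_cut,
            alt_logFC=self.alt_logFC,
            alt_p=self.alt_p,
            excluded_chroms=frozenset(self.excluded_chroms),
        )

    def validate(self) -> None:
        for name in ("proximity_radius", "summit_half_width",
                     "promoter_half_width", "nearest_flag_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        missing = []
        for p in (self.genome_fasta, self.genes_gtf, self.motifs_meme,
                  self.expression_tsv, self.gene_sets_gmt, self.enhancers_bed):
            if not Path(p).exists():
                missing.append(p)
        for stage in self.stages:
            for cond in ("HD", "WT"):
                for path in self.fragments[stage][cond] + self.peak_calls[stage][cond]:
                    if not Path(path).exists():
                        missing.append(path)
        if missing:
            raise FileNotFoundError(
                "missing input files: " + ", ".join(sorted(set(missing)))
            )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class RunReport:
    """All tables produced by one pipeline run."""

    differential_summary: pd.DataFrame
    differential_tables: dict[str, pd.DataFrame]
    motif_enrichment: pd.DataFrame
    overlap_tests: pd.DataFrame
    associations: pd.DataFrame
    enhancer_overlap: pd.DataFrame
    logratio_matrix: pd.DataFrame
    qc: pd.DataFrame


def merge_peak_calls(peak_lists: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Union of replicate peak calls with summits carried through.

    Intervals are merged (touching counts as overlapping) and each merged
    peak takes the median summit of the calls it absorbed.
    """
    all_peaks = [p for lst in peak_lists for p in lst]
    merged = merge_intervals([p.interval for p in all_peaks])
    out = []
    for iv in merged:
        member_summits = [
            p.summit
            for p in all_peaks
            if p.chrom == iv.chrom and p.interval.start < iv.end and iv.start < p.interval.end
        ]
        summit = int(statistics.median(member_summits)) if member_summits else (
            (iv.start + iv.end) // 2
        )
        summit = min(max(summit, iv.start), iv.end - 1)
        out.append(Peak(iv, summit, f"{iv.chrom}:{iv.start}-{iv.end}"))
    return out


def _load_filtered_fragments(
    paths: Sequence[str],
) -> tuple[list[list[Fragment]], int]:
    """Read, Tn5-shift and size-filter fragments per replicate; returns
    (per-replicate sub-nucleosomal fragments, number dropped by shift)."""
    per_rep = []
    dropped = 0
    for path in paths:
        kept = []
        for frag in io.read_fragments_bed(path):
            try:
                shifted = shift_tn5(frag)
            except FragmentRejected:
                dropped += 1
                continue
            if shifted.size_class == NON_NUCLEOSOMAL:
                kept.append(shifted)
        per_rep.append(kept)
    return per_rep, dropped


def _window_sequences(
    fasta: Fasta, peaks: Sequence[Peak], half_width: int
) -> dict[str, str]:
    seqs = {}
    for p in peaks:
        chrom_len = len(fasta[p.chrom])
        lo = max(0, p.summit - half_width)
        hi = min(chrom_len, p.summit + half_width)
        seqs[p.name] = str(fasta[p.chrom][lo:hi])
    return seqs


def run_pipeline(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Order: fragment preprocessing -> per-stage counting and MA-normalized
    differential testing -> proximity/genic annotation -> motif scan and
    Fisher enrichment -> expression integration -> summary tables.
    Intermediates land under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    logger.info("run start: stages=%s seed=%d", config.stages, config.seed)
    logger.info(
        "thresholds: logCPM>%g q<%g |logFC|>%g p<%g excluded=%s",
        config.min_logCPM, config.q_cut, config.alt_logFC, config.alt_p,
        config.excluded_chroms,
    )

    genes = io.read_gtf_genes(config.genes_gtf)
    pwms = motifs.load_pwms(config.motifs_meme)
    fasta = Fasta(config.genome_fasta)
    expression = io.read_expression_table(config.expression_tsv)
    gene_sets = io.read_gmt(config.gene_sets_gmt)
    enhancers = io.read_bed(config.enhancers_bed)
    criteria = config.criteria()

    qc_rows = []
    selected_by_stage: dict[str, list[diffacc.DifferentialPeak]] = {}
    diff_tables: dict[str, pd.DataFrame] = {}
    enrich_frames = []
    assoc_frames = []
    enhancer_rows = []

    for stage in config.stages:
        logger.info("stage %s: preprocessing fragments", stage)
        frags_hd, drop_hd = _load_filtered_fragments(config.fragments[stage]["HD"])
        frags_wt, drop_wt = _load_filtered_fragments(config.fragments[stage]["WT"])

        calls_hd = [io.read_peaks_bed(p) for p in config.peak_calls[stage]["HD"]]
        calls_wt = [io.read_peaks_bed(p) for p in config.peak_calls[stage]["WT"]]
        hd_merged = merge_peak_calls(calls_hd)
        wt_merged = merge_peak_calls(calls_wt)
        analysis_peaks = merge_peak_calls([hd_merged, wt_merged])

        # replicate QC on the analysis peak set
        rep_corr = {}
        for cond, reps in (("HD", frags_hd), ("WT", frags_wt)):
            if len(reps) >= 2:
                c1, _ = diffacc.count_fragments_in_peaks(reps[0], analysis_peaks)
                c2, _ = diffacc.count_fragments_in_peaks(reps[1], analysis_peaks)
                rep_corr[cond] = diffacc.replicate_correlation(c1, c2)
            else:
                rep_corr[cond] = float("nan")

        pooled_hd = [f for rep in frags_hd for f in rep]
        pooled_wt = [f for rep in frags_wt for f in rep]
        common = diffacc.common_peak_mask(analysis_peaks, hd_merged, wt_merged)
        model = diffacc.MAnormModel.from_fragments(
            pooled_hd, pooled_wt, analysis_peaks,
            common_mask=common, criteria=criteria,
        )
        results = model.fit()
        results.annotate(genes, radius=config.proximity_radius)
        selected_by_stage[stage] = results.selected
        table = results.to_frame()
        diff_tables[stage] = table
        table.to_csv(out / f"differential_{stage}.tsv", sep="\t", index=False)
        io.write_bed(
            out / f"differential_{stage}_selected.bed",
            [dp.peak.interval for dp in results.selected],
        )
        logger.info(
            "stage %s: %d peaks, %d selected (fit: intercept=%.3f slope=%.3f)",
            stage, len(results.table), len(results.selected),
            results.normalization.intercept, results.normalization.slope,
        )
        qc_rows.append(
            {
                "stage": stage,
                "dropped_fragments_hd": drop_hd,
                "dropped_fragments_wt": drop_wt,
                "replicate_r_hd": rep_corr["HD"],
                "replicate_r_wt": rep_corr["WT"],
                "norm_intercept": results.normalization.intercept,
                "norm_slope": results.normalization.slope,
                "n_common": results.normalization.n_common,
            }
        )

        # motif enrichment: dedup best hit per peak, then per
        # direction x context Fisher tables
        window_seqs = _window_sequences(
            fasta, analysis_peaks, config.summit_half_width
        )
        hits = motifs.scan_windows(window_seqs, pwms, config.motif_p_threshold)
        best = motifs.best_hit_per_peak(hits)
        context_of = {
            dp.peak.name: dp.proximity for dp in results.table
        }
        direction_sets = {
            diffacc.HD_UP: {
                dp.peak.name for dp in results.selected
                if dp.direction == diffacc.HD_UP
            },
            WT_UP: {
                dp.peak.name for dp in results.selected
                if dp.direction == diffacc.HD_DOWN
            },
        }
        universes = {
            diffacc.HD_UP: _condition_universe(analysis_peaks, hd_merged),
            WT_UP: _condition_universe(analysis_peaks, wt_merged),
        }
        enr = motifs.enrichment_scan(
            best, [p.motif_id for p in pwms], direction_sets, universes, context_of
        )
        frame = motifs.enrichment_frame(enr)
        frame.insert(0, "stage", stage)
        enrich_frames.append(frame)

        # nearest differential peak per DE gene of this stage
        de_stage = set(
            expression.loc[
                (expression["stage"] == stage)
                & (expression["q_value"] < config.de_q_cutoff),
                "gene_id",
            ]
        )
        de_genes_models = [g for g in genes if g.gene_id in de_stage]
        assoc, skipped = integration.nearest_diff_peak_per_gene(
            de_genes_models, results.selected, stage=stage,
            flag_distance=config.nearest_flag_distance,
        )
        assoc_frames.append(
            pd.DataFrame(
                {
                    "gene_id": a.gene_id,
                    "stage": a.stage,
                    "chrom": a.peak.peak.chrom,
                    "start": a.peak.peak.interval.start,
                    "end": a.peak.peak.interval.end,
                    "direction": a.peak.direction,
                    "M": a.peak.M,
                    "distance": a.distance,
                    "within_250kb": a.within_250kb,
                }
                for a in assoc
            )
        )
        qc_rows[-1]["genes_without_nearby_peak"] = skipped

        distal_sel = [dp for dp in results.selected if dp.proximity == DISTAL]
        counts = integration.enhancer_overlap_counts(distal_sel, enhancers, genes)
        counts["stage"] = stage
        enhancer_rows.append(counts)

    # expression-side tables
    summary = diffacc.summarize_differential(selected_by_stage)
    de_any = set(
        expression.loc[expression["q_value"] < config.de_q_cutoff, "gene_id"]
    )
    universe = expression["gene_id"].nunique()
    overlap_rows = []
    for set_id, members in gene_sets.items():
        gs = integration.GeneSet(set_id, frozenset(members), universe)
        n11, fraction, p = integration.geneset_overlap_test(de_any, gs)
        overlap_rows.append(
            {
                "set_id": set_id,
                "set_size": len(members),
                "overlap": n11,
                "fraction_pct": fraction,
                "p": p,
            }
        )
    pooled = (
        expression.groupby(["gene_id", "stage"], as_index=False)[
            ["fpkm_hd", "fpkm_wt"]
        ].mean()
    )
    gene_order = sorted(de_any) if de_any else sorted(expression["gene_id"].unique())
    logratio = integration.build_logratio_matrix(
        pooled[pooled["gene_id"].isin(gene_order)], gene_order, config.stages
    )
    if len(logratio) > 1:
        order = integration.hierarchical_order(logratio.to_numpy())
        logratio = logratio.iloc[order]

    report = RunReport(
        differential_summary=summary,
        differential_tables=diff_tables,
        motif_enrichment=(
            pd.concat(enrich_frames, ignore_index=True)
            if enrich_frames else pd.DataFrame()
        ),
        overlap_tests=pd.DataFrame(overlap_rows),
        associations=(
            pd.concat(assoc_frames, ignore_index=True)
            if assoc_frames else pd.DataFrame()
        ),
        enhancer_overlap=pd.DataFrame(enhancer_rows),
        logratio_matrix=logratio,
        qc=pd.DataFrame(qc_rows),
    )
    render_summary(report, out)
    logger.info("run complete: outputs in %s", out)
    return report


def _condition_universe(
    analysis_peaks: Sequence[Peak], condition_merged: Sequence[Peak]
) -> set[str]:
    """Analysis peaks that were called in the given condition."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for p in condition_merged:
        trees.setdefault(p.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end
        )
    out = set()
    for p in analysis_peaks:
        t = trees.get(p.chrom)
        if t is not None and t.overlap(p.interval.start, p.interval.end):
            out.add(p.name)
    return out


def _fmt_cell(count: int, pct: Optional[float]) -> str:
    if pct is None:
        return "NA"
    d = Decimal(str(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{count}({d}%)"


def render_summary(report: RunReport, out_dir: str | Path) -> None:
    """Write the report tables as TSVs, with summary percentage cells
    formatted count(pct%) at one decimal, half-up."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s = report.differential_summary.copy()
    if len(s):
        s["enriched_cell"] = [
            _fmt_cell(c, p) for c, p in zip(s["enriched"], s["enriched_pct"])
        ]
        s["depleted_cell"] = [
            _fmt_cell(c, p) for c, p in zip(s["depleted"], s["depleted_pct"])
        ]
    s.to_csv(out / "differential_summary.tsv", sep="\t", index=False)
    report.motif_enrichment.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    report.overlap_tests.to_csv(out / "overlap_tests.tsv", sep="\t", index=False)
    report.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    report.enhancer_overlap.to_csv(out / "enhancer_overlap.tsv", sep="\t", index=False)
    report.logratio_matrix.to_csv(out / "logratio_matrix.tsv", sep="\t")
    report.qc.to_csv(out / "qc.tsv", sep="\t", index=False)


def _setup_logging(log_path: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(log_path, mode="w"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)


def config_for_dataset(data_dir: str | Path, out_dir: str | Path,
                       stages: Optional[list[str]] = None,
                       n_replicates: int = 2) -> AnalysisConfig:
    """Build an AnalysisConfig for a directory written by
    :meth:`thsspipe.synth.SyntheticDataset.write`."""
    d = Path(data_dir)
    if stages is None:
        stages = sorted(
            {p.name.split("_")[0] for p in (d / "fragments").glob("*.bed")}
        )
        canonical = ["PSC", "NPC", "day3", "astrocyte"]
        stages = [s for s in canonical if s in stages] + [
            s for s in stages if s not in canonical
        ]
    def files(kind: str) -> dict[str, dict[str, list[str]]]:
        return {
            stage: {
                cond: [
                    str(d / kind / f"{stage}_{cond}_rep{r}.bed")
                    for r in range(1, n_replicates + 1)
                ]
                for cond in ("HD", "WT")
            }
            for stage in stages
        }
    return AnalysisConfig(
        out_dir=str(out_dir),
        genome_fasta=str(d / "genome.fa"),
        genes_gtf=str(d / "genes.gtf"),
        motifs_meme=str(d / "motifs.meme"),
        expression_tsv=str(d / "expression.tsv"),
        gene_sets_gmt=str(d / "gene_sets.gmt"),
        enhancers_bed=str(d / "enhancers.bed"),
        stages=stages,
        fragments=files("fragments"),
        peak_calls=files("peaks"),
    )
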