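"""Seeded synthetic datasets with planted ground truth.

The generator emulates the structure of a two-condition (HD vs WT),
four-stage, two-replicate ATAC-seq + RNA-seq study: a small random
genome with decoy chromosomes (chr2a/chr2b) that exercise the exclusion
rule, non-overlapping gene models, peak calls with replicate jitter, a
condition-level sequencing-depth bias that the MA normalization must
remove, planted differential peaks, a motif planted preferentially into
HD-up peak summit windows, and a cuffdiff-style expression table with
stage-patterned differential genes (including an inverse
NPC-vs-astrocyte pattern).

Counting noise is negative binomial with variance mu + dispersion*mu^2;
the default dispersion of 0 is the Poisson limit, matching the
replicate-pooled counting model of the differential test.  All draws go
through one seeded generator, so every output is byte-deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from thsspipe import io
from thsspipe.core import Fragment, GeneModel, GenomicInterval, Peak
from thsspipe.diffacc import bh_adjust
from thsspipe.motifs import BASES, PWM, write_pwms_meme

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset",
           "make_genome", "make_pwms", "simulate_peak_counts",
           "plant_motifs", "simulate_expression"]

STAGES = ("PSC", "NPC", "day3", "astrocyte")
CONDITIONS = ("HD", "WT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the standard study conditions.

    ``nb_dispersion`` is the extra-Poisson dispersion of fragment counts
    (variance mu + dispersion * mu^2); 0 is the Poisson limit.
    ``scale_factor`` multiplies every WT count, planting the depth bias
    the normalization is expected to remove.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    decoy_length: int = 100_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    n_peaks: int = 1_000
    peak_width: int = 400
    frac_proximal: float = 0.2
    n_decoy_peaks: int = 20
    frac_differential: float = 0.10
    true_logFC: float = 4.0
    scale_factor: float = 2.0
    nb_dispersion: float = 0.0
    mean_count: float = 50.0  # per replicate; replicates pool to ~100
    mean_count_sigma: float = 0.4
    n_background_fragments: int = 20_000
    n_motifs: int = 20
    motif_width: int = 10
    planted_motif_rate: float = 0.8
    background_motif_rate: float = 0.1
    n_stages: int = 4
    n_replicates: int = 2
    de_fraction: float = 0.15
    de_effect: float = 3.0  # log2 units
    expr_base_mean: float = 3.0  # log2 FPKM
    expr_base_sigma: float = 1.5
    expr_rep_sigma: float = 0.25
    n_enhancers_random: int = 100

    def __post_init__(self) -> None:
        for name in ("frac_proximal", "frac_differential", "planted_motif_rate",
                     "background_motif_rate", "de_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.chrom_length, self.peak_width) <= 0 or self.n_peaks < 0:
            raise ValueError("lengths and counts must be positive")


@dataclass
class SyntheticDataset:
    """A complete in-memory dataset plus its planted truth tables."""

    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    peaks: list[Peak]
    peak_truth: pd.DataFrame  # name, direction, motif_planted
    peak_calls: dict[tuple[str, str, int], list[Peak]]  # (stage, cond, rep)
    fragments: dict[tuple[str, str, int], list[Fragment]]
    pwms: list[PWM]
    planted_motif: str
    expression: pd.DataFrame
    gene_truth: pd.DataFrame  # gene_id, is_de, pattern
    gene_sets: dict[str, list[str]]
    enhancers: list[GenomicInterval]
    qc: dict = field(default_factory=dict)

    @property
    def stages(self) -> list[str]:
        return list(STAGES[: self.config.n_stages])

    def true_direction(self, peak_name: str) -> str:
        row = self.peak_truth.loc[self.peak_truth["name"] == peak_name]
        return row["direction"].iloc[0] if len(row) else "none"

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "fragments").mkdir(parents=True, exist_ok=True)
        (out / "peaks").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        io.write_fasta(out / "genome.fa", self.genome)
        io.write_gtf_genes(out / "genes.gtf", self.genes)
        io.write_peaks_bed(out / "truth" / "true_peaks.bed", self.peaks)
        for (stage, cond, rep), peaks in self.peak_calls.items():
            io.write_peaks_bed(out / "peaks" / f"{stage}_{cond}_rep{rep}.bed", peaks)
        for (stage, cond, rep), frags in self.fragments.items():
            io.write_bed(
                out / "fragments" / f"{stage}_{cond}_rep{rep}.bed",
                [f.interval for f in frags],
            )
        write_pwms_meme(out / "motifs.meme", self.pwms)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
        io.write_gmt(out / "gene_sets.gmt", self.gene_sets)
        io.write_bed(out / "enhancers.bed", self.enhancers)
        self.peak_truth.to_csv(out / "truth" / "peaks.tsv", sep="\t", index=False)
        self.gene_truth.to_csv(out / "truth" / "genes.tsv", sep="\t", index=False)
        with open(out / "truth" / "planted_motif.txt", "w") as fh:
            fh.write(self.planted_motif + "\n")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def make_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel]]:
    """Uniform-base chromosomes plus chr2a/chr2b decoys, with genes
    placed on an evenly spaced grid so bodies never overlap."""
    genome: dict[str, str] = {}
    main_chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    for chrom in main_chroms:
        genome[chrom] = _random_sequence(rng, config.chrom_length)
    for chrom in ("chr2a", "chr2b"):
        genome[chrom] = _random_sequence(rng, config.decoy_length)
    genes: list[GeneModel] = []
    if config.n_genes:
        per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
        slot = config.chrom_length // per_chrom
        lo_len, hi_len = config.gene_length_range
        if slot < hi_len + 2_000:
            raise ValueError(
                "cannot place genes without overlap; use longer chromosomes "
                "or fewer/shorter genes"
            )
        gid = 0
        for chrom in main_chroms:
            for s in range(per_chrom):
                if gid >= config.n_genes:
                    break
                length = int(rng.integers(lo_len, hi_len + 1))
                margin = slot - length - 1_000
                start = s * slot + 500 + int(rng.integers(0, max(margin, 1)))
                body = GenomicInterval(chrom, start, start + length)
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel.from_body(f"gene{gid:04d}", body, strand))
                gid += 1
    return genome, genes


def make_pwms(config: SyntheticConfig, rng: np.random.Generator) -> list[PWM]:
    """Sharp random PWMs (dominant base 0.85) over a uniform background,
    averaging well above 1 bit of information per position."""
    pwms = []
    bg = np.full(4, 0.25)
    for m in range(config.n_motifs):
        probs = np.full((config.motif_width, 4), 0.05)
        dominant = rng.integers(0, 4, size=config.motif_width)
        probs[np.arange(config.motif_width), dominant] = 0.85
        pwms.append(PWM(f"motif{m:02d}", probs, bg))
    return pwms


def _place_peaks(
    config: SyntheticConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
) -> tuple[list[Peak], pd.DataFrame]:
    half = config.peak_width // 2
    peaks: list[Peak] = []
    n_prox = int(round(config.frac_proximal * config.n_peaks))
    usable_genes = [g for g in genes if g.tss > half + 10]
    if usable_genes:
        idx = rng.choice(len(usable_genes), size=min(n_prox, len(usable_genes)),
                         replace=False)
        for i in sorted(idx):
            g = usable_genes[i]
            center = g.tss + int(rng.integers(-100, 101))
            iv = GenomicInterval(g.chrom, center - half, center + half)
            summit = center + int(rng.integers(-50, 51))
            summit = min(max(summit, iv.start), iv.end - 1)
            peaks.append(Peak(iv, summit))
    # distal peaks on a spaced grid, kept clear of TSS neighbourhoods
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom] = np.append(
            tss_by_chrom.get(g.chrom, np.array([])), g.tss
        )
    n_distal = max(config.n_peaks - len(peaks), 0)
    main_chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = int(np.ceil(n_distal / len(main_chroms)))
    slot = config.chrom_length // per_chrom if per_chrom else config.chrom_length
    placed = 0
    for chrom in main_chroms:
        tss = np.sort(np.asarray(tss_by_chrom.get(chrom, np.array([]))))
        for s in range(per_chrom):
            if placed >= n_distal:
                break
            for _ in range(30):
                center = s * slot + half + int(
                    rng.integers(0, max(slot - config.peak_width, 1))
                )
                # stay > 1.2 kb from any TSS so the peak is robustly distal
                j = np.searchsorted(tss, center)
                near = min(
                    abs(center - tss[j - 1]) if j > 0 else 10**9,
                    abs(tss[j] - center) if j < len(tss) else 10**9,
                )
                if near > 1_200:
                    iv = GenomicInterval(chrom, center - half, center + half)
                    summit = center + int(rng.integers(-50, 51))
                    summit = min(max(summit, iv.start), iv.end - 1)
                    peaks.append(Peak(iv, summit))
                    placed += 1
                    break
    # decoy peaks on the excluded chromosomes
    for d in range(config.n_decoy_peaks):
        chrom = "chr2a" if d % 2 == 0 else "chr2b"
        slot_d = (chrom_lengths[chrom] - config.peak_width) // max(
            config.n_decoy_peaks // 2, 1
        )
        start = (d // 2) * slot_d + int(rng.integers(0, max(slot_d // 2, 1)))
        iv = GenomicInterval(chrom, start, start + config.peak_width)
        peaks.append(Peak(iv, start + half))
    peaks.sort(key=lambda p: (p.chrom, p.interval.start))
    names = [f"peak{i:05d}" for i in range(len(peaks))]
    peaks = [Peak(p.interval, p.summit, name) for p, name in zip(peaks, names)]

    # differential truth: decoys are always planted differential (they must
    # be excluded downstream); main-chromosome peaks at frac_differential
    main_idx = [i for i, p in enumerate(peaks) if p.chrom not in ("chr2a", "chr2b")]
    n_diff = int(round(config.frac_differential * len(main_idx)))
    diff_idx = rng.choice(main_idx, size=n_diff, replace=False).astype(int)
    direction = np.array(["none"] * len(peaks), dtype=object)
    half_n = n_diff // 2
    shuffled = rng.permutation(diff_idx)
    direction[shuffled[:half_n]] = "HD_up"
    direction[shuffled[half_n:]] = "HD_down"
    for i, p in enumerate(peaks):
        if p.chrom in ("chr2a", "chr2b"):
            direction[i] = "HD_up" if i % 2 == 0 else "HD_down"
    truth = pd.DataFrame(
        {
            "name": names,
            "chrom": [p.chrom for p in peaks],
            "start": [p.interval.start for p in peaks],
            "end": [p.interval.end for p in peaks],
            "summit": [p.summit for p in peaks],
            "direction": direction,
            "motif_planted": False,
        }
    )
    return peaks, truth


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_peak_counts(
    config: SyntheticConfig,
    peaks: Sequence[Peak],
    peak_truth: pd.DataFrame,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str, int], list[Fragment]], dict[str, np.ndarray]]:
    """Fragment sets per (stage, condition, replicate), plus the
    per-condition expected replicate count of every peak.

    Per-peak lognormal base intensities are shared across stages; HD-up
    (HD-down) truth peaks have their HD mean multiplied (divided) by
    2^true_logFC; every WT count is scaled by ``scale_factor``.
    Peak fragments are sub-nucleosomal (shifted length < 125 bp) and
    scatter around the summit; background fragments are uniform with a
    mixture of size classes.  Raw intervals are 9 bp longer than their
    Tn5-shifted lengths, so downstream shifting reproduces the target
    size classes.
    """
    base_mu = config.mean_count * np.exp(
        rng.normal(0, config.mean_count_sigma, size=len(peaks))
    )
    direction = peak_truth["direction"].to_numpy()
    hd_mult = np.ones(len(peaks))
    hd_mult[direction == "HD_up"] = 2.0 ** config.true_logFC
    hd_mult[direction == "HD_down"] = 2.0 ** (-config.true_logFC)
    cond_means = {
        "HD": base_mu * hd_mult,
        "WT": base_mu * config.scale_factor,
    }
    out: dict[tuple[str, str, int], list[Fragment]] = {}
    starts = np.array([p.interval.start for p in peaks])
    summits = np.array([p.summit for p in peaks])
    chroms = [p.chrom for p in peaks]
    for stage in STAGES[: config.n_stages]:
        for cond in CONDITIONS:
            mu = base_mu * (hd_mult if cond == "HD" else 1.0)
            if cond == "WT":
                mu = mu * config.scale_factor
            for rep in range(1, config.n_replicates + 1):
                counts = _nb_counts(rng, mu, config.nb_dispersion)
                frags: list[Fragment] = []
                for i, c in enumerate(counts):
                    if c == 0:
                        continue
                    lens = rng.integers(40, 125, size=c) + 9
                    centers = np.rint(rng.normal(summits[i], 60, size=c)).astype(int)
                    clen = chrom_lengths[chroms[i]]
                    s = np.clip(centers - lens // 2, 0, None)
                    e = np.minimum(s + lens, clen)
                    s = np.minimum(s, e - 10)
                    for a, b in zip(s, e):
                        frags.append(Fragment(GenomicInterval(chroms[i], int(a), int(b))))
                n_bg = config.n_background_fragments
                if cond == "WT":
                    n_bg = int(round(n_bg * config.scale_factor))
                frags.extend(_background_fragments(rng, chrom_lengths, n_bg))
                out[(stage, cond, rep)] = frags
    return out, cond_means


def _background_fragments(
    rng: np.random.Generator, chrom_lengths: dict[str, int], n: int
) -> list[Fragment]:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    pick = rng.choice(len(chroms), size=n, p=weights)
    u = rng.random(size=n)
    # shifted-length mixture: sub-nucleosomal / linker / mononucleosome
    lens = np.where(
        u < 0.5,
        rng.integers(40, 125, size=n),
        np.where(u < 0.75, rng.integers(125, 171, size=n),
                 rng.integers(171, 255, size=n)),
    ) + 9
    frags = []
    for k in range(n):
        chrom = chroms[pick[k]]
        clen = chrom_lengths[chrom]
        start = int(rng.integers(0, max(clen - lens[k], 1)))
        frags.append(Fragment(GenomicInterval(chrom, start, start + int(lens[k]))))
    return frags


def _jittered_calls(
    config: SyntheticConfig,
    peaks: Sequence[Peak],
    cond_means: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    call_rate: float = 0.97,
    jitter: int = 10,
    min_call_mean: float = 20.0,
) -> dict[tuple[str, str, int], list[Peak]]:
    """Per-replicate peak calls: jittered copies of the true peaks.

    A peak is only callable in a condition when its expected replicate
    count there reaches ``min_call_mean`` — mimicking a peak caller that
    cannot call a peak the condition barely covers, which is what makes
    strongly differential peaks condition-specific."""
    calls: dict[tuple[str, str, int], list[Peak]] = {}
    for stage in STAGES[: config.n_stages]:
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                sample = []
                for i, p in enumerate(peaks):
                    if cond_means[cond][i] < min_call_mean:
                        continue
                    if rng.random() > call_rate:
                        continue
                    ds = int(rng.integers(-jitter, jitter + 1))
                    de = int(rng.integers(-jitter, jitter + 1))
                    start = max(0, p.interval.start + ds)
                    end = min(chrom_lengths[p.chrom], p.interval.end + de)
                    summit = min(max(p.summit, start), end - 1)
                    sample.append(
                        Peak(GenomicInterval(p.chrom, start, end), summit, p.name)
                    )
                calls[(stage, cond, rep)] = sample
    return calls


def plant_motifs(
    config: SyntheticConfig,
    genome: dict[str, str],
    peaks: Sequence[Peak],
    peak_truth: pd.DataFrame,
    pwms: Sequence[PWM],
    rng: np.random.Generator,
    window_half_width: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write motif consensus sequences into peak summit windows.

    The designated (first) motif goes into ``planted_motif_rate`` of the
    HD-up truth peaks and ``background_motif_rate`` of every other peak;
    each remaining motif is planted at the background rate across all
    peaks.  Strand is random; planted positions avoid one another within
    a window.  Windows too short for the motif are skipped and recorded.
    """
    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
            for c, s in genome.items()}
    truth = peak_truth.copy()
    planted_col = np.zeros(len(peaks), dtype=bool)
    skipped = 0
    direction = truth["direction"].to_numpy()
    for i, p in enumerate(peaks):
        lo = max(0, p.summit - window_half_width)
        hi = min(len(seqs[p.chrom]), p.summit + window_half_width)
        used: list[tuple[int, int]] = []
        for m, pwm in enumerate(pwms):
            if m == 0:
                rate = (
                    config.planted_motif_rate
                    if direction[i] == "HD_up"
                    else config.background_motif_rate
                )
            else:
                rate = config.background_motif_rate
            if rng.random() >= rate:
                continue
            w = pwm.width
            if hi - lo < w:
                skipped += 1
                continue
            pos = None
            for _ in range(30):
                cand = lo + int(rng.integers(0, hi - lo - w + 1))
                if all(cand + w <= a or cand >= b for a, b in used):
                    pos = cand
                    break
            if pos is None:
                continue
            word = pwm.consensus
            if rng.random() < 0.5:
                word = word.translate(_COMPLEMENT)[::-1]
            seqs[p.chrom][pos : pos + w] = np.frombuffer(
                word.encode(), dtype=np.uint8
            )
            used.append((pos, pos + w))
            if m == 0:
                planted_col[i] = True
    truth["motif_planted"] = planted_col
    new_genome = {c: arr.tobytes().decode() for c, arr in seqs.items()}
    return new_genome, truth


_DE_PATTERNS = {
    "all_up": (1, 1, 1, 1),
    "all_down": (-1, -1, -1, -1),
    "late_up": (0, 0, 1, 1),
    "inverse": (0, -1, 0, 1),  # depleted in NPCs, enriched in astrocytes
}


def simulate_expression(
    config: SyntheticConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cuffdiff-style expression table with planted DE truth.

    Per gene: a lognormal baseline; DE genes get a 2^de_effect shift with
    one of four stage-sign patterns.  Replicate FPKMs add lognormal noise
    and the reported p is a two-sample z-test on log2 replicate means
    with the replicate noise treated as known and shared across genes
    (the way count-model DE tools borrow variance information across
    genes — a per-gene variance estimate from duplicate samples would
    carry a single degree of freedom and essentially no power).
    q is BH-adjusted per stage.
    """
    stages = list(STAGES[: config.n_stages])
    n = len(genes)
    base = rng.normal(config.expr_base_mean, config.expr_base_sigma, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    pattern_names = list(_DE_PATTERNS)
    patterns = rng.integers(0, len(pattern_names), size=n_de)
    delta = np.zeros((n, len(stages)))
    gene_pattern = np.array(["none"] * n, dtype=object)
    for k, gi in enumerate(de_idx):
        name = pattern_names[patterns[k]]
        gene_pattern[gi] = name
        signs = _DE_PATTERNS[name][: len(stages)]
        delta[gi, :] = np.array(signs) * config.de_effect
    rows = []
    for j, stage in enumerate(stages):
        mean_hd = base + delta[:, j]
        mean_wt = base
        reps_hd = mean_hd[:, None] + rng.normal(
            0, config.expr_rep_sigma, size=(n, config.n_replicates)
        )
        reps_wt = mean_wt[:, None] + rng.normal(
            0, config.expr_rep_sigma, size=(n, config.n_replicates)
        )
        se = config.expr_rep_sigma * np.sqrt(2.0 / config.n_replicates)
        for i, g in enumerate(genes):
            z = (np.mean(reps_hd[i]) - np.mean(reps_wt[i])) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "stage": stage,
                    "fpkm_hd": float(np.mean(2.0 ** reps_hd[i])),
                    "fpkm_wt": float(np.mean(2.0 ** reps_wt[i])),
                    "log2_fold_change": float(
                        np.mean(reps_hd[i]) - np.mean(reps_wt[i])
                    ),
                    "p_value": float(p),
                }
            )
    df = pd.DataFrame(rows)
    df["q_value"] = 0.0
    for stage in stages:
        mask = df["stage"] == stage
        df.loc[mask, "q_value"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_de": [gene_pattern[i] != "none" for i in range(n)],
            "pattern": gene_pattern,
        }
    )
    return df, truth


def generate_dataset(
    config: SyntheticConfig = SyntheticConfig(),
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Generate a complete dataset; ``seed`` overrides the config seed."""
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)
    genome, genes = make_genome(config, rng)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    pwms = make_pwms(config, rng)
    peaks, peak_truth = _place_peaks(config, genes, rng, chrom_lengths)
    genome, peak_truth = plant_motifs(
        config, genome, peaks, peak_truth, pwms, rng
    )
    fragments, cond_means = simulate_peak_counts(
        config, peaks, peak_truth, chrom_lengths, rng
    )
    peak_calls = _jittered_calls(config, peaks, cond_means, chrom_lengths, rng)
    expression, gene_truth = simulate_expression(config, genes, rng)
    de_truth_genes = sorted(gene_truth.loc[gene_truth["is_de"], "gene_id"])
    other = sorted(
        rng.choice(
            gene_truth.loc[~gene_truth["is_de"], "gene_id"].to_numpy(),
            size=min(30, int((~gene_truth["is_de"]).sum())),
            replace=False,
        )
    )
    gene_sets = {"planted_de_set": de_truth_genes, "random_set": other}
    enhancers = _make_enhancers(config, peaks, peak_truth, genes, chrom_lengths, rng)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        peaks=peaks,
        peak_truth=peak_truth,
        peak_calls=peak_calls,
        fragments=fragments,
        pwms=pwms,
        planted_motif=pwms[0].motif_id,
        expression=expression,
        gene_truth=gene_truth,
        gene_sets=gene_sets,
        enhancers=enhancers,
    )


def evaluate_recovery(dataset: SyntheticDataset, report) -> dict:
    """Score a pipeline report against the dataset's planted truth.

    Returns sensitivity and empirical FDR of differential-peak recovery
    (aggregated over stages; a selected peak is a true positive when it
    overlaps a truth peak of the same planted direction), the worst
    across-stage rank of the planted motif among HD-up distal Fisher
    p-values, and the planted DE gene-set overlap p.
    """
    from intervaltree import IntervalTree

    truth = dataset.peak_truth
    main = truth[~truth.chrom.isin(["chr2a", "chr2b"])]
    trees: dict[str, IntervalTree] = {}
    for r in main[main.direction != "none"].itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.direction)
    n_truth = int((main.direction != "none").sum())
    tp = fp = 0
    recovered: set[tuple] = set()
    for stage, table in report.differential_tables.items():
        sel = table[table.direction != "not_differential"]
        for r in sel.itertuples():
            hits = trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end)
            match = [h for h in hits if h.data == r.direction]
            if match:
                tp += 1
                for h in match:
                    recovered.add((stage, r.chrom, h.begin, h.end))
            else:
                fp += 1
    n_stages = len(report.differential_tables)
    sensitivity = (
        len(recovered) / (n_truth * n_stages) if n_truth and n_stages else float("nan")
    )
    fdr = fp / (tp + fp) if (tp + fp) else 0.0

    enr = report.motif_enrichment
    worst_rank = 0
    for stage in report.differential_tables:
        sub = enr[
            (enr.stage == stage)
            & (enr.direction == "HD_up")
            & (enr.context == "distal")
        ].sort_values(["p", "motif_id"])
        ranks = {m: i + 1 for i, m in enumerate(sub.motif_id)}
        worst_rank = max(worst_rank, ranks.get(dataset.planted_motif, len(ranks) + 1))

    ov = report.overlap_tests
    row = ov[ov.set_id == "planted_de_set"]
    geneset_p = float(row.p.iloc[0]) if len(row) else float("nan")
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_truth_differential": n_truth,
        "n_selected": int(tp + fp),
        "planted_motif_worst_rank": worst_rank,
        "planted_geneset_p": geneset_p,
    }


def _make_enhancers(
    config: SyntheticConfig,
    peaks: Sequence[Peak],
    peak_truth: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Candidate enhancers: padded copies of half the distal peaks plus
    random 1-kb regions."""
    from thsspipe.core import DISTAL, classify_tss_proximity

    enhancers = []
    for p in peaks:
        if p.chrom in ("chr2a", "chr2b"):
            continue
        if classify_tss_proximity(p.interval, list(genes)) != DISTAL:
            continue
        if rng.random() < 0.5:
            enhancers.append(
                GenomicInterval(
                    p.chrom,
                    max(0, p.interval.start - 200),
                    min(chrom_lengths[p.chrom], p.interval.end + 200),
                )
            )
    main = [c for c in chrom_lengths if c not in ("chr2a", "chr2b")]
    for _ in range(config.n_enhancers_random):
        chrom = main[int(rng.integers(0, len(main)))]
        start = int(rng.integers(0, chrom_lengths[chrom] - 1_000))
        enhancers.append(GenomicInterval(chrom, start, start + 1_000))
    enhancers.sort(key=lambda e: (e.chrom, e.start))
    return enhancers
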