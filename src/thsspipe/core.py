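"""Genomic coordinate primitives shared by every analysis stage.

All internal coordinates are 0-based half-open ([start, end)), the BED
convention.  GTF-style 1-based inclusive coordinates are converted at I/O
time (see :mod:`thsspipe.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "Fragment",
    "GeneModel",
    "OffsetRule",
    "FragmentRejected",
    "shift_tn5",
    "classify_fragment_length",
    "merge_intervals",
    "classify_tss_proximity",
    "classify_genic_context",
    "nearest_feature",
    "window",
]

NON_NUCLEOSOMAL = "non_nucleosomal"
MONONUCLEOSOME = "mononucleosome"
OTHER = "other"

#: Sub-nucleosomal fragments are shorter than this (exclusive bound).
NON_NUCLEOSOMAL_MAX = 125
#: Mononucleosome fragments span one nucleosome: closed interval in bp.
MONONUCLEOSOME_RANGE = (171, 254)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Signed gap between closest edges; 0 if overlapping.

        Positive when ``other`` lies downstream (higher coordinates) of
        self, negative when upstream.  None on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return -(self.start - other.end)


@dataclass(frozen=True)
class Fragment:
    """A sequenced ATAC fragment with its nucleosomal size class."""

    interval: GenomicInterval
    size_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.size_class:
            object.__setattr__(
                self, "size_class", classify_fragment_length(len(self.interval))
            )

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class Peak:
    """A called accessibility peak with an absolute summit coordinate."""

    interval: GenomicInterval
    summit: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and a body interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValueError("tss must lie inside or at the edge of the gene body")

    @classmethod
    def from_body(cls, gene_id: str, body: GenomicInterval, strand: str) -> "GeneModel":
        """Build a gene model from a body interval; TSS is the 5' end."""
        if strand == "+":
            tss, tes = body.start, body.end
        else:
            tss, tes = body.end, body.start
        return cls(gene_id, body.chrom, strand, tss, tes, body)


@dataclass(frozen=True)
class OffsetRule:
    """Tn5 insertion-site correction: +4 bp on the plus strand end,
    -5 bp on the minus strand end, the standard ATAC-seq adjustment."""

    plus_shift: int = 4
    minus_shift: int = -5


class FragmentRejected(ValueError):
    """Raised when a Tn5-shifted fragment degenerates (start >= end)."""


def shift_tn5(fragment: Fragment, rule: OffsetRule = OffsetRule()) -> Fragment:
    """Apply the Tn5 insertion offset to both fragment ends.

    The fragment's left coordinate is the 5' cut on the plus strand and is
    moved by ``plus_shift``; the right coordinate is the 5' cut on the
    minus strand and is moved by ``minus_shift`` (negative moves it left).

    Raises
    ------
    FragmentRejected
        If the shifted interval is empty or inverted.
    """
    iv = fragment.interval
    new_start = iv.start + rule.plus_shift
    new_end = iv.end + rule.minus_shift
    if new_start >= new_end:
        raise FragmentRejected(
            f"fragment {iv.chrom}:{iv.start}-{iv.end} degenerates to "
            f"[{new_start}, {new_end}) after Tn5 shift"
        )
    return Fragment(GenomicInterval(iv.chrom, new_start, new_end))


def classify_fragment_length(length: int) -> str:
    """Assign an ATAC fragment length to a nucleosomal size class.

    Fragments shorter than 125 bp are transposase-hypersensitive
    (non-nucleosomal); 171-254 bp fragments span a single nucleosome.
    """
    if length <= 0:
        raise ValueError(f"fragment length must be positive, got {length}")
    if length < NON_NUCLEOSOMAL_MAX:
        return NON_NUCLEOSOMAL
    lo, hi = MONONUCLEOSOME_RANGE
    if lo <= length <= hi:
        return MONONUCLEOSOME
    return OTHER


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals: sorted, non-overlapping cover per chromosome.

    Intervals closer than or equal to ``min_gap`` are merged; with the
    default 0, touching intervals (end == next start) merge, matching
    common merge-tool behaviour.  Idempotent.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= min_gap:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


PROXIMAL = "proximal"
DISTAL = "distal"


def classify_tss_proximity(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    radius: int = 500,
) -> str:
    """Label a region promoter-proximal or distal.

    A region is proximal iff any edge of it falls within ``radius`` bp of
    any gene's TSS, i.e. it overlaps the closed window [tss - radius,
    tss + radius].  Every transcript/gene TSS counts.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not genes:
        warnings.warn("empty gene list: all regions classified distal")
        return DISTAL
    for g in genes:
        if g.chrom != region.chrom:
            continue
        lo = max(0, g.tss - radius)
        hi = g.tss + radius + 1  # closed -> half-open
        if region.start < hi and lo < region.end:
            return PROXIMAL
    return DISTAL


INTRAGENIC = "intragenic"
INTERGENIC = "intergenic"


def classify_genic_context(
    region: GenomicInterval, genes: Sequence[GeneModel]
) -> str:
    """Intragenic iff the region overlaps any gene body by >= 1 bp."""
    for g in genes:
        if region.overlaps(g.body):
            return INTRAGENIC
    return INTERGENIC


def nearest_feature(
    query: GenomicInterval, targets: Sequence[GenomicInterval]
) -> tuple[Optional[GenomicInterval], Optional[int]]:
    """Nearest same-chromosome target and its signed edge distance.

    Distance is 0 for any overlap, otherwise the gap between closest
    edges, positive when the target is downstream of the query.  Ties are
    broken by smaller absolute distance, then upstream over downstream,
    then smaller target start — a fixed deterministic order.

    Returns ``(None, None)`` when no target shares the chromosome.
    """
    best: Optional[GenomicInterval] = None
    best_d: Optional[int] = None
    for t in targets:
        d = query.distance_to(t)
        if d is None:
            continue
        if best_d is None:
            best, best_d = t, d
            continue
        key_new = (abs(d), d > 0, t.start)
        key_old = (abs(best_d), best_d > 0, best.start)
        if key_new < key_old:
            best, best_d = t, d
    return best, best_d


def window(chrom: str, center: int, half_width: int) -> GenomicInterval:
    """Fixed-width window centred on a point, clipped at position 0."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    return GenomicInterval(chrom, max(0, center - half_width), center + half_width)
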