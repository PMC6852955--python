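"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is native (0-based half-open, tab-separated, no header).  Peak BED
files may carry a 7th column holding the summit offset relative to the
interval start.  The GTF-subset reader converts 1-based inclusive
coordinates to half-open on input.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from thsspipe.core import Fragment, GeneModel, GenomicInterval, Peak

__all__ = [
    "read_bed",
    "write_bed",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_fragments_bed",
    "read_gtf_genes",
    "write_gtf_genes",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_expression_table",
]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ as intervals, ignoring extra columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peak BED; column 7, when present, is the summit offset from
    ``start``.  Without it the summit defaults to the interval midpoint."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else ""
            if len(parts) > 6:
                summit = iv.start + int(parts[6])
            else:
                summit = (iv.start + iv.end) // 2
            peaks.append(Peak(iv, summit, name))
    return peaks


def write_peaks_bed(path: str | Path, peaks: Iterable[Peak]) -> None:
    """BED6+1: name, score 0, strand '.', then summit offset."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\t"
                f"{p.summit - iv.start}\n"
            )


def read_fragments_bed(path: str | Path) -> list[Fragment]:
    return [Fragment(iv) for iv in read_bed(path)]


_GTF_ATTR_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene features from a GTF subset (gene/transcript rows only).

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open.  One GeneModel per ``gene`` feature row.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            m = _GTF_ATTR_RE.search(f[8])
            if m is None:
                raise ValueError(f"GTF row without gene_id attribute: {line!r}")
            body = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]))
            genes.append(GeneModel.from_body(m.group(1), body, f[6]))
    return genes


def write_gtf_genes(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\tthsspipe\tgene\t{g.body.start + 1}\t{g.body.end}"
                f"\t.\t{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then gene ids."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(path: str | Path, sets: dict[str, Sequence[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(genes)) + "\n")


EXPRESSION_COLUMNS = [
    "gene_id",
    "stage",
    "fpkm_hd",
    "fpkm_wt",
    "log2_fold_change",
    "p_value",
    "q_value",
]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a cuffdiff-style differential expression TSV.

    Accepts either this package's column names or cuffdiff's
    (``value_1``/``value_2`` FPKM columns with ``sample_1``/``sample_2``
    labels, ``p_value``, ``q_value``).
    """
    df = pd.read_csv(path, sep="\t")
    if "value_1" in df.columns:  # cuffdiff layout; sample_1 is the test condition
        df = df.rename(
            columns={"value_1": "fpkm_hd", "value_2": "fpkm_wt", "gene": "gene_id"}
        )
    missing = {"gene_id", "fpkm_hd", "fpkm_wt", "p_value", "q_value"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if "stage" not in df.columns:
        df["stage"] = "all"
    return df
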