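"""PWM motif scanning in peak summit windows and Fisher enrichment.

Scanning mirrors the FIMO approach: each window position is scored with
the motif's log-odds against a 0-order background, the score's p-value is
taken from the exact distribution of the discretized score of a random
background word (computed by positionwise convolution), and positions on
both strands with p <= the match threshold are reported.  Where several
motifs match the same peak only the most significant match is kept, and
per-motif enrichment of a differential direction (HD-up or WT-up) against
all same-condition peaks is tested with a two-sided Fisher exact test on
the contingency table

    N11  N12        N11 = direction peaks whose best motif is X
    N21  N22        N21 = all condition peaks whose best motif is X

with N12/N22 the corresponding counts for every other motif.  The rows
are nested (direction peaks are a subset of all peaks) — deliberately so;
the null tested is N11/(N11+N12) = N21/(N21+N22).  Raw p-values are
reported without multiple-test correction because motif p-values are
strongly dependent across related transcription factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "MotifHit",
    "MotifContingency",
    "EnrichmentResult",
    "load_pwms",
    "write_pwms_meme",
    "ScoreDistribution",
    "score_pvalue_table",
    "scan_peak_window",
    "scan_windows",
    "best_hit_per_peak",
    "build_contingency",
    "fisher_exact",
    "enrichment_scan",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: score discretization used for the exact p-value table, in bits
SCORE_GRANULARITY = 1e-3
#: pseudo-probability mixed into PWM columns before taking log-odds
SCORE_PSEUDO = 0.01


@dataclass
class PWM:
    """Position probability matrix with a 0-order background."""

    motif_id: str
    probabilities: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray  # (4,), sums to 1

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if self.width < 4:
            raise ValueError(f"{self.motif_id}: motif width must be >= 4")
        rowsums = self.probabilities.sum(axis=1)
        if np.any(np.abs(rowsums - 1) > 1e-3):
            bad = int(np.argmax(np.abs(rowsums - 1)))
            raise ValueError(
                f"{self.motif_id}: row {bad} sums to {rowsums[bad]:.4f}, not 1"
            )
        self.probabilities = self.probabilities / rowsums[:, None]
        if abs(self.background.sum() - 1) > 1e-6:
            raise ValueError(f"{self.motif_id}: background must sum to 1")
        self._dist: Optional[ScoreDistribution] = None

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Log2-odds score matrix with a small pseudo-probability mixed in
        to keep impossible bases finite (FIMO-style regularization)."""
        p = (1 - SCORE_PSEUDO) * self.probabilities + SCORE_PSEUDO * 0.25
        return np.log2(p / self.background[None, :])

    def score_distribution(self) -> "ScoreDistribution":
        if self._dist is None:
            self._dist = score_pvalue_table(self)
        return self._dist


@dataclass(frozen=True)
class MotifHit:
    peak_id: str
    motif_id: str
    offset: int
    strand: str
    score: float  # log2-odds, bits
    p: float


@dataclass(frozen=True)
class MotifContingency:
    motif_id: str
    N11: int
    N12: int
    N21: int
    N22: int
    context: str = ""
    direction: str = ""

    def __post_init__(self) -> None:
        for v in (self.N11, self.N12, self.N21, self.N22):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    context: str
    direction: str
    table: MotifContingency
    p_fisher: float
    proportion_diff: float
    significant: bool


def load_pwms(path: str | Path) -> list[PWM]:
    """Read a MEME minimal motif file.

    Rows off unity by <= 1e-3 are renormalized; worse is an error naming
    the motif.  The file's background applies to every motif (uniform
    when absent).  Parsed directly: the common MEME parsers round the
    letter probabilities through integer site counts, which loses the
    stated values.
    """
    bg = np.full(4, 0.25)
    out: list[PWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = {tokens[j]: float(tokens[j + 1])
                     for j in range(0, len(tokens) - 1, 2)}
            bg = np.array([freqs.get(b, 0.25) for b in BASES])
            bg = bg / bg.sum()
        elif line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else "motif"
            i += 1
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    raise ValueError(f"{motif_id}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise ValueError(f"{motif_id}: missing probability matrix")
            header = lines[i]
            width = None
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and j + 2 < len(toks) + 1:
                    width = int(toks[j + 2])
            if width is None:
                raise ValueError(f"{motif_id}: matrix header lacks a width")
            rows = []
            for k in range(width):
                i += 1
                vals = lines[i].split()
                if len(vals) != 4:
                    raise ValueError(f"{motif_id}: row {k} has {len(vals)} fields")
                rows.append([float(v) for v in vals])
            out.append(PWM(motif_id, np.array(rows), bg.copy()))
        i += 1
    return out


def write_pwms_meme(path: str | Path, pwms: Sequence[PWM]) -> None:
    """Write motifs in MEME minimal format (shared background from the
    first motif)."""
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probabilities:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


class ScoreDistribution:
    """Exact distribution of the discretized log-odds score of a random
    background word, from positionwise convolution of per-position score
    distributions."""

    def __init__(self, min_int: int, pmf: np.ndarray, granularity: float) -> None:
        self.min_int = min_int
        self.pmf = pmf
        self.granularity = granularity
        # tail[i] = P(score_int >= min_int + i)
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def pvalue(self, score: float) -> float:
        """P(random word scores >= score), discretized to the table grid."""
        idx = int(round(score / self.granularity)) - self.min_int
        if idx <= 0:
            return 1.0
        # a float score can land just past the last achievable bin;
        # clamp to the best-word tail mass
        return float(self.tail[min(idx, len(self.tail) - 1)])

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest score (in bits) whose p-value is <= p_threshold."""
        idx = int(np.searchsorted(-self.tail, -p_threshold))
        return (self.min_int + idx) * self.granularity


def score_pvalue_table(
    pwm: PWM, granularity: float = SCORE_GRANULARITY
) -> ScoreDistribution:
    """Exact null score distribution by dynamic programming.

    Scores are discretized to integer multiples of ``granularity`` (bits)
    and the distributions of successive positions are convolved; the
    background supplies the per-base probabilities.
    """
    lo = pwm.log_odds()
    ints = np.rint(lo / granularity).astype(np.int64)
    mins = ints.min(axis=1)
    maxs = ints.max(axis=1)
    total_min = int(mins.sum())
    pmf = np.ones(1)
    for pos in range(pwm.width):
        new = np.zeros(len(pmf) + int(maxs[pos] - mins[pos]))
        for b in range(4):
            off = int(ints[pos, b] - mins[pos])
            new[off : off + len(pmf)] += pwm.background[b] * pmf
        pmf = new
    return ScoreDistribution(total_min, pmf, granularity)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _scan_strand(
    codes: np.ndarray, ints: np.ndarray, granularity: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of every valid start position (N-containing windows
    masked out).  Returns (positions, int_scores)."""
    L = ints.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.array([], dtype=int), np.array([], dtype=np.int64)
    valid = codes >= 0
    ok = np.ones(n, dtype=bool)
    scores = np.zeros(n, dtype=np.int64)
    safe = np.where(valid, codes, 0)
    for j in range(L):
        seg = slice(j, j + n)
        ok &= valid[seg]
        scores += ints[j, safe[seg]]
    return np.nonzero(ok)[0], scores[ok]


def scan_peak_window(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    peak_id: str = "",
) -> list[MotifHit]:
    """Scan one window sequence on both strands for motif matches.

    Positions whose window contains N are skipped.  Minus-strand hits are
    reported at the leftmost forward-strand coordinate of the match.
    """
    if len(sequence) < pwm.width:
        return []
    dist = pwm.score_distribution()
    ints = np.rint(pwm.log_odds() / dist.granularity).astype(np.int64)
    # minimum integer score clearing the match threshold, found once
    thr_idx = int(np.searchsorted(-dist.tail, -p_threshold))
    if thr_idx >= len(dist.tail):
        return []
    thr_int = dist.min_int + thr_idx
    hits: list[MotifHit] = []
    fwd = _encode(sequence)
    rev = _encode(sequence.translate(_COMPLEMENT)[::-1])
    for strand, codes in (("+", fwd), ("-", rev)):
        pos, scores = _scan_strand(codes, ints, dist.granularity)
        keep = scores >= thr_int
        for o, s_int in zip(pos[keep], scores[keep]):
            score = float(s_int) * dist.granularity
            p = float(dist.tail[min(int(s_int) - dist.min_int, len(dist.tail) - 1)])
            offset = int(o) if strand == "+" else len(sequence) - pwm.width - int(o)
            hits.append(MotifHit(peak_id, pwm.motif_id, offset, strand, score, p))
    hits.sort(key=lambda h: (h.p, -h.score, h.offset, h.strand))
    return hits


def scan_windows(
    window_seqs: Mapping[str, str],
    pwms: Sequence[PWM],
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan every (window, motif) pair; windows keyed by peak id."""
    hits: list[MotifHit] = []
    for pwm in pwms:
        for peak_id, seq in window_seqs.items():
            hits.extend(scan_peak_window(seq, pwm, p_threshold, peak_id=peak_id))
    return hits


def best_hit_per_peak(hits: Iterable[MotifHit]) -> dict[str, MotifHit]:
    """Keep the single most significant hit per peak.

    Ties broken by higher score, leftmost offset, plus strand, then
    lexicographic motif id — a fixed deterministic order.
    """
    best: dict[str, MotifHit] = {}
    for h in hits:
        cur = best.get(h.peak_id)
        key = (h.p, -h.score, h.offset, h.strand, h.motif_id)
        if cur is None or key < (cur.p, -cur.score, cur.offset, cur.strand, cur.motif_id):
            best[h.peak_id] = h
    return best


def build_contingency(
    motif_id: str,
    dedup_hits: Mapping[str, MotifHit],
    direction_peaks: Iterable[str],
    all_peaks: Iterable[str],
    context: str = "",
    direction: str = "",
) -> MotifContingency:
    """Count the nested 2x2 table for one motif.

    ``direction_peaks`` are the differential peaks of one direction;
    ``all_peaks`` every peak of that condition (the differential ones
    included).  Only peaks with a deduplicated hit contribute.
    """
    n11 = n12 = n21 = n22 = 0
    direction_set = set(direction_peaks)
    for pid in all_peaks:
        hit = dedup_hits.get(pid)
        if hit is None:
            continue
        is_x = hit.motif_id == motif_id
        if is_x:
            n21 += 1
        else:
            n22 += 1
        if pid in direction_set:
            if is_x:
                n11 += 1
            else:
                n12 += 1
    return MotifContingency(motif_id, n11, n12, n21, n22, context, direction)


def fisher_exact(table: MotifContingency) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities no
    larger than the observed table's).  A zero row sum returns 1."""
    if (table.N11 + table.N12 == 0) or (table.N21 + table.N22 == 0):
        warnings.warn(f"{table.motif_id}: zero row sum, p = 1")
        return 1.0
    _, p = stats.fisher_exact(
        [[table.N11, table.N12], [table.N21, table.N22]], alternative="two-sided"
    )
    return float(p)


def enrichment_scan(
    dedup_hits: Mapping[str, MotifHit],
    motif_ids: Sequence[str],
    direction_sets: Mapping[str, set[str]],
    condition_universes: Mapping[str, set[str]],
    context_of: Mapping[str, str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-motif Fisher enrichment for each direction x context.

    ``direction_sets`` maps a direction label (e.g. ``HD_up``) to its
    differential peak ids; ``condition_universes`` maps the same label to
    every peak of the matching condition.  Proximal and distal peaks are
    tested separately using ``context_of``.  Raw p-values; results with
    p < ``alpha`` are flagged significant.
    """
    results: list[EnrichmentResult] = []
    for direction, diff_ids in direction_sets.items():
        universe = condition_universes[direction]
        for context in sorted({context_of[p] for p in universe if p in context_of}):
            d_ids = [p for p in diff_ids if context_of.get(p) == context]
            u_ids = [p for p in universe if context_of.get(p) == context]
            for mid in motif_ids:
                tab = build_contingency(
                    mid, dedup_hits, d_ids, u_ids, context, direction
                )
                if not d_ids:
                    p = 1.0
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = fisher_exact(tab)
                top = tab.N11 + tab.N12
                bot = tab.N21 + tab.N22
                prop = (tab.N11 / top if top else 0.0) - (
                    tab.N21 / bot if bot else 0.0
                )
                results.append(
                    EnrichmentResult(mid, context, direction, tab, p, prop, p < alpha)
                )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif_id": r.motif_id,
            "direction": r.direction,
            "context": r.context,
            "N11": r.table.N11,
            "N12": r.table.N12,
            "N21": r.table.N21,
            "N22": r.table.N22,
            "proportion_diff": r.proportion_diff,
            "p": r.p_fisher,
            "significant": r.significant,
        }
        for r in results
    )
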