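"""PWM scanning, exact score p-values and Fisher contingency enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from thsspipe.motifs import (
    PWM,
    MotifContingency,
    MotifHit,
    best_hit_per_peak,
    build_contingency,
    enrichment_scan,
    fisher_exact,
    load_pwms,
    scan_peak_window,
    score_pvalue_table,
    write_pwms_meme,
)

RC = str.maketrans("ACGT", "TGCA")


def sharp_pwm(word, motif_id="m", dominant=0.85):
    probs = np.full((len(word), 4), (1 - dominant) / 3)
    for i, b in enumerate(word):
        probs[i, "ACGT".index(b)] = dominant
    return PWM(motif_id, probs, np.full(4, 0.25))


MEME_TWO = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF alpha

letter-probability matrix: alength= 4 w= 5 nsites= 20 E= 0
0.8 0.1 0.05 0.05
0.05 0.8 0.1 0.05
0.1 0.1 0.7 0.1
0.25 0.25 0.25 0.25
0.05 0.05 0.05 0.85

MOTIF beta

letter-probability matrix: alength= 4 w= 6 nsites= 20 E= 0
0.9 0.03 0.03 0.04
0.9 0.03 0.03 0.04
0.03 0.9 0.03 0.04
0.03 0.9 0.03 0.04
0.03 0.03 0.9 0.04
0.03 0.03 0.9 0.04
"""


class TestLoadPwms:
    def test_two_motifs_with_stated_widths(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwms = load_pwms(path)
        assert [(p.motif_id, p.width) for p in pwms] == [("alpha", 5), ("beta", 6)]

    def test_slightly_off_rows_are_renormalized(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO.replace("0.25 0.25 0.25 0.25",
                                         "0.2498 0.2498 0.2498 0.2498"))
        (alpha, _) = load_pwms(path)
        assert np.allclose(alpha.probabilities.sum(axis=1), 1.0)

    def test_badly_malformed_row_raises_with_motif_name(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO.replace("0.25 0.25 0.25 0.25",
                                         "0.125 0.125 0.125 0.125"))
        with pytest.raises(ValueError, match="alpha"):
            load_pwms(path)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(MEME_TWO)
        pwms = load_pwms(path)
        out = tmp_path / "o.meme"
        write_pwms_meme(out, pwms)
        back = load_pwms(out)
        for a, b in zip(pwms, back):
            assert a.motif_id == b.motif_id
            assert np.allclose(a.probabilities, b.probabilities, atol=1e-5)


class TestScoreDistribution:
    @pytest.mark.parametrize("word", ["ACGT", "ACGTA", "TTTTT"])
    def test_matches_exhaustive_word_enumeration(self, word):
        """Tail p at every achievable score equals brute force over all
        4^L background words on the same integer score grid."""
        pwm = sharp_pwm(word)
        dist = pwm.score_distribution()
        ints = np.rint(pwm.log_odds() / dist.granularity).astype(np.int64)
        from collections import Counter

        exact = Counter()
        for codes in itertools.product(range(4), repeat=pwm.width):
            s = sum(ints[i, c] for i, c in enumerate(codes))
            exact[s] += 0.25 ** pwm.width
        for s in exact:
            brute = sum(v for k, v in exact.items() if k >= s)
            assert dist.pvalue(s * dist.granularity) == pytest.approx(
                brute, rel=1e-9
            )

    def test_best_score_p_is_consensus_probability(self):
        pwm = sharp_pwm("ACGTG")
        dist = pwm.score_distribution()
        best = pwm.log_odds().max(axis=1).sum()
        assert dist.pvalue(best) == pytest.approx(0.25**5, rel=1e-9)

    def test_tail_mass_at_minimum_score_is_one(self):
        dist = sharp_pwm("ACGTAC").score_distribution()
        assert dist.tail[0] == pytest.approx(1.0, abs=1e-12)


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 200)])
        planted = seq[:73] + pwm.consensus + seq[83:]
        hits = scan_peak_window(planted, pwm, p_threshold=1e-4, peak_id="pk")
        fwd = [h for h in hits if h.strand == "+" and h.offset == 73]
        assert len(fwd) == 1
        assert fwd[0].p <= 1e-4

    def test_reverse_complement_hit_on_minus_strand(self, rng):
        pwm = sharp_pwm("ACGTACGTAC")
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 200)])
        rc = pwm.consensus.translate(RC)[::-1]
        planted = seq[:50] + rc + seq[60:]
        hits = scan_peak_window(planted, pwm, p_threshold=1e-4)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.offset == 50 for h in minus)

    def test_n_positions_are_skipped(self):
        pwm = sharp_pwm("ACGTACGTAC")
        seq = "N" * 50 + pwm.consensus + "N" * 50
        hits = scan_peak_window(seq, pwm, p_threshold=1e-4)
        assert [h.offset for h in hits if h.strand == "+"] == [50]

    def test_window_shorter_than_motif(self):
        assert scan_peak_window("ACG", sharp_pwm("ACGTACGTAC")) == []

    def test_false_positive_rate_matches_score_table(self, rng):
        """Hit counts on random sequence agree with the exact null
        expectation from the score distribution within 3 Poisson SDs."""
        pwm = sharp_pwm("ACGTACGTAC", dominant=0.7)
        dist = pwm.score_distribution()
        thr = 1e-3
        idx = int(np.searchsorted(-dist.tail, -thr))
        p_exact = float(dist.tail[idx])  # attainable p at the threshold
        bases = np.array(list("ACGT"))
        n_hits = 0
        n_positions = 0
        for _ in range(20):
            seq = "".join(bases[rng.integers(0, 4, 500)])
            hits = scan_peak_window(seq, pwm, p_threshold=thr)
            n_hits += len(hits)
            n_positions += 2 * (500 - pwm.width + 1)
        expect = n_positions * p_exact
        assert abs(n_hits - expect) <= 3 * np.sqrt(expect)


class TestBestHit:
    def hit(self, peak, motif, p, score=5.0, offset=0, strand="+"):
        return MotifHit(peak, motif, offset, strand, score, p)

    def test_most_significant_kept(self):
        best = best_hit_per_peak(
            [self.hit("pk", "a", 1e-3), self.hit("pk", "b", 1e-6)]
        )
        assert best["pk"].motif_id == "b"

    def test_missing_peak_absent(self):
        assert "other" not in best_hit_per_peak([self.hit("pk", "a", 0.5)])

    def test_tie_breaks_leftmost(self):
        best = best_hit_per_peak(
            [
                self.hit("pk", "a", 1e-4, score=3.0, offset=40),
                self.hit("pk", "a", 1e-4, score=3.0, offset=10),
            ]
        )
        assert best["pk"].offset == 10


class TestContingency:
    def test_direct_count_example(self):
        hits = {}
        for i in range(5):
            hits[f"hd{i}"] = MotifHit(f"hd{i}", "X", 0, "+", 5.0, 1e-5)
        for i in range(5, 10):
            hits[f"hd{i}"] = MotifHit(f"hd{i}", "Y", 0, "+", 5.0, 1e-5)
        tab = build_contingency(
            "X", hits, ["hd0", "hd1", "hd2"], [f"hd{i}" for i in range(10)]
        )
        assert (tab.N11, tab.N12, tab.N21, tab.N22) == (3, 0, 5, 5)

    def test_motif_absent_everywhere(self):
        hits = {"p1": MotifHit("p1", "Y", 0, "+", 5.0, 1e-5)}
        tab = build_contingency("X", hits, ["p1"], ["p1"])
        assert (tab.N11, tab.N12, tab.N21, tab.N22) == (0, 1, 0, 1)

    def test_recount_oracle_on_random_assignment(self, rng):
        peaks = [f"p{i}" for i in range(200)]
        motifs = [f"m{j}" for j in range(8)]
        hits = {
            p: MotifHit(p, motifs[int(rng.integers(0, 8))], 0, "+", 5.0, 1e-5)
            for p in peaks
            if rng.random() < 0.7
        }
        direction = [p for p in peaks if rng.random() < 0.2]
        for m in motifs:
            tab = build_contingency(m, hits, direction, peaks)
            n11 = sum(1 for p in direction if p in hits and hits[p].motif_id == m)
            n21 = sum(1 for p in peaks if p in hits and hits[p].motif_id == m)
            n12 = sum(1 for p in direction if p in hits) - n11
            n22 = len(hits) - n21
            assert (tab.N11, tab.N12, tab.N21, tab.N22) == (n11, n12, n21, n22)

    def test_sum_of_n11_over_motifs_counts_hit_direction_peaks(self, rng):
        peaks = [f"p{i}" for i in range(100)]
        motifs = [f"m{j}" for j in range(5)]
        hits = {
            p: MotifHit(p, motifs[int(rng.integers(0, 5))], 0, "+", 5.0, 1e-5)
            for p in peaks
            if rng.random() < 0.6
        }
        direction = [p for p in peaks if rng.random() < 0.3]
        total_n11 = sum(
            build_contingency(m, hits, direction, peaks).N11 for m in motifs
        )
        assert total_n11 == sum(1 for p in direction if p in hits)


def enumeration_fisher(a, b, c, d):
    """Independent two-sided Fisher p: enumerate all tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(v for v in pmf.values() if v <= obs * (1 + 1e-9))


class TestFisher:
    def test_no_association(self):
        assert fisher_exact(MotifContingency("m", 5, 5, 5, 5)) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        from scipy.special import comb

        p = fisher_exact(MotifContingency("m", 10, 0, 0, 10))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_zero_row_sum_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact(MotifContingency("m", 0, 0, 3, 4)) == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            got = fisher_exact(MotifContingency("m", a, b, c, d))
            assert got == pytest.approx(enumeration_fisher(a, b, c, d), rel=1e-6)

    def test_symmetric_under_row_label_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 12, size=4))
            p1 = fisher_exact(MotifContingency("m", a, b, c, d))
            p2 = fisher_exact(MotifContingency("m", c, d, a, b))
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestEnrichmentScan:
    @staticmethod
    def _random_hits(rng, peaks, motifs, rate=0.7):
        return {
            p: MotifHit(p, motifs[int(rng.integers(0, len(motifs)))], 0, "+",
                        5.0, 1e-5)
            for p in peaks
            if rng.random() < rate
        }

    def test_empty_direction_gives_all_p_one(self, rng):
        peaks = [f"p{i}" for i in range(50)]
        motifs = ["mA", "mB"]
        hits = self._random_hits(rng, peaks, motifs)
        res = enrichment_scan(
            hits, motifs, {"HD_up": set()}, {"HD_up": set(peaks)},
            {p: "distal" for p in peaks},
        )
        assert res and all(r.p_fisher == 1.0 for r in res)
        assert not any(r.significant for r in res)

    def test_label_shuffle_null_rarely_significant(self, rng):
        """With differential labels assigned at random, few motifs reach
        p < 0.05 (loose bound: motif p-values are dependent)."""
        peaks = [f"p{i}" for i in range(1000)]
        motifs = [f"m{j}" for j in range(20)]
        hits = self._random_hits(rng, peaks, motifs, rate=0.8)
        shuffled = set(rng.choice(peaks, size=100, replace=False))
        res = enrichment_scan(
            hits, motifs, {"HD_up": shuffled}, {"HD_up": set(peaks)},
            {p: "distal" for p in peaks},
        )
        frac = np.mean([r.significant for r in res])
        assert frac <= 0.15

    def test_planted_motif_has_smallest_p(self, rng):
        peaks = [f"p{i}" for i in range(400)]
        motifs = [f"m{j}" for j in range(10)]
        diff = set(peaks[:40])
        hits = {}
        for p in peaks:
            if p in diff and rng.random() < 0.8:
                hits[p] = MotifHit(p, "m0", 0, "+", 5.0, 1e-5)
            elif rng.random() < 0.5:
                m = motifs[int(rng.integers(0, 10))]
                hits[p] = MotifHit(p, m, 0, "+", 5.0, 1e-5)
        res = enrichment_scan(
            hits, motifs, {"HD_up": diff}, {"HD_up": set(peaks)},
            {p: "distal" for p in peaks},
        )
        best = min(res, key=lambda r: r.p_fisher)
        assert best.motif_id == "m0" and best.significant
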