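"""MA normalization, the exact binomial test and compound selection."""

import numpy as np
import pytest
from scipy import stats

from thsspipe.core import Fragment, GeneModel, GenomicInterval, Peak
from thsspipe.diffacc import (
    HD_DOWN,
    HD_UP,
    DifferentialPeak,
    MAnormModel,
    NormalizationFit,
    PeakCounts,
    SelectionCriteria,
    apply_normalization,
    bh_adjust,
    count_fragments_in_peaks,
    diff_promoter_occupancy,
    diff_pvalue,
    fit_ma_normalization,
    replicate_correlation,
    select_differential,
    summarize_counts,
    summarize_differential,
)


def peak(start, end, chrom="chr1", name=""):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2, name)


def frag(start, end, chrom="chr1"):
    return Fragment(GenomicInterval(chrom, start, end))


def make_counts(x1, x2, peaks=None):
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if peaks is None:
        peaks = [peak(1000 * i, 1000 * i + 400) for i in range(len(x1))]
    libs = np.array([max(x1.sum(), 1.0), max(x2.sum(), 1.0)])
    return PeakCounts(peaks, np.column_stack([x1, x2]), libs)


class TestCounting:
    def test_fragment_overlapping_two_peaks_counts_in_both(self):
        peaks = [peak(100, 200), peak(190, 300)]
        counts, lib = count_fragments_in_peaks([frag(195, 210)], peaks)
        assert counts.tolist() == [1.0, 1.0]
        assert lib == 1

    def test_no_fragments(self):
        counts, lib = count_fragments_in_peaks([], [peak(0, 100)])
        assert counts.tolist() == [0.0]
        assert lib == 0

    def test_matches_pairwise_overlap_oracle(self, rng):
        peaks = [
            peak(int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 9000, 40), rng.integers(50, 600, 40))
        ]
        frags = [
            frag(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 9500, 300), rng.integers(20, 120, 300))
        ]
        counts, _ = count_fragments_in_peaks(frags, peaks)
        expect = [
            sum(1 for f in frags if f.interval.overlaps(p.interval)) for p in peaks
        ]
        assert counts.tolist() == [float(e) for e in expect]


class TestNormalizationFit:
    def test_pure_scaling_recovers_minus_log2(self, rng):
        x1 = rng.integers(20, 500, size=300).astype(float)
        counts = make_counts(x1, 4 * x1)
        fit = fit_ma_normalization(counts, np.ones(300, bool))
        assert fit.intercept == pytest.approx(-2.0, abs=0.05)
        assert fit.slope == pytest.approx(0.0, abs=0.02)

    def test_identity(self, rng):
        x = rng.integers(20, 500, size=300).astype(float)
        fit = fit_ma_normalization(make_counts(x, x), np.ones(300, bool))
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_scale_under_nb_noise(self):
        rng = np.random.default_rng(42)
        s = 3.0
        mu = 100 * np.exp(rng.normal(0, 0.5, size=2000))
        r = 100.0  # mild NB dispersion
        x1 = rng.negative_binomial(r, r / (r + mu)).astype(float)
        x2 = rng.negative_binomial(r, r / (r + s * mu)).astype(float)
        fit = fit_ma_normalization(make_counts(x1, x2), np.ones(2000, bool))
        assert fit.intercept == pytest.approx(-np.log2(s), abs=0.1)

    def test_too_few_common_peaks(self):
        with pytest.raises(ValueError):
            fit_ma_normalization(make_counts([5.0], [5.0]), np.ones(1, bool))


class TestApplyNormalization:
    def test_identity_fit_is_noop(self, rng):
        counts = make_counts(
            rng.integers(1, 100, 50).astype(float),
            rng.integers(1, 100, 50).astype(float),
        )
        out = apply_normalization(counts, NormalizationFit(0.0, 0.0, 50))
        assert np.allclose(out.counts, counts.counts)

    def test_scaling_fit_zeroes_median_m(self, rng):
        x1 = rng.integers(50, 500, size=500).astype(float)
        counts = make_counts(x1, 4 * x1)
        fit = fit_ma_normalization(counts, np.ones(500, bool))
        out = apply_normalization(counts, fit)
        m = np.log2((out.counts[:, 0] + 0.5) / (out.counts[:, 1] + 0.5))
        assert abs(np.median(m)) < 0.05

    def test_slope_fit_decorrelates_m_from_a(self):
        rng = np.random.default_rng(5)
        mu = 100 * np.exp(rng.normal(0, 0.8, size=2000))
        x1 = rng.poisson(mu).astype(float)
        # intensity-dependent bias: stronger peaks relatively deeper in x2
        x2 = rng.poisson(mu * (mu / mu.mean()) ** 0.15).astype(float)
        counts = make_counts(x1, x2)
        fit = fit_ma_normalization(counts, np.ones(2000, bool))
        out = apply_normalization(counts, fit)
        m = np.log2((out.counts[:, 0] + 0.5) / (out.counts[:, 1] + 0.5))
        a = 0.5 * np.log2((out.counts[:, 0] + 0.5) * (out.counts[:, 1] + 0.5))
        assert abs(np.corrcoef(m, a)[0, 1]) < 0.05

    def test_refit_after_normalization_is_self_consistent(self, rng):
        mu = 100 * np.exp(rng.normal(0, 0.5, 1000))
        x1 = rng.poisson(mu).astype(float)
        x2 = rng.poisson(3 * mu).astype(float)
        counts = make_counts(x1, x2)
        fit = fit_ma_normalization(counts, np.ones(1000, bool))
        out = apply_normalization(counts, fit)
        refit = fit_ma_normalization(out, np.ones(1000, bool))
        assert abs(refit.intercept) < 0.05
        assert abs(refit.slope) < 0.02


class TestDiffPvalue:
    def test_symmetric_counts(self):
        assert diff_pvalue(10, 10) == 1.0

    def test_one_sided_extreme(self):
        assert diff_pvalue(10, 0) == pytest.approx(2 * 0.5**10)

    def test_both_zero_convention(self):
        assert diff_pvalue(0, 0) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        """Two-sided p equals the summed pmf over the rejection set
        {k : pmf(k) <= pmf(observed)}."""
        for _ in range(50):
            k1 = int(rng.integers(0, 30))
            k2 = int(rng.integers(0, 30))
            if k1 + k2 == 0:
                continue
            n = k1 + k2
            pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
            expected = pmf[pmf <= pmf[k1] * (1 + 1e-12)].sum()
            assert diff_pvalue(k1, k2) == pytest.approx(expected, rel=1e-9)

    def test_rounding_is_half_even(self):
        assert diff_pvalue(10.5, 9.5) == diff_pvalue(10, 10)


class TestBHAdjust:
    def test_hand_computed_values(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal(self):
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_empty(self):
        assert len(bh_adjust([])) == 0


def dpeak(logCPM, p, q, logFC, chrom="chr1", start=0):
    return DifferentialPeak(
        peak=peak(start, start + 100, chrom=chrom),
        M=logFC, A=5.0, logCPM=logCPM, logFC=logFC, p=p, q=q,
    )


class TestSelection:
    def test_q_branch(self):
        kept = select_differential([dpeak(2.0, 0.001, 0.005, 1.0)])
        assert len(kept) == 1 and kept[0].direction == HD_UP

    def test_logcpm_gate_blocks_tiny_peaks(self):
        assert select_differential([dpeak(0.5, 1e-12, 1e-9, 5.0)]) == []

    def test_alternate_branch_and_chrom_exclusion(self):
        good = dpeak(2.0, 0.004, 0.05, 3.5)
        on_decoy = dpeak(2.0, 0.004, 0.05, 3.5, chrom="chr2a")
        kept = select_differential([good, on_decoy])
        assert len(kept) == 1 and kept[0].peak.chrom == "chr1"

    def test_direction_partition(self):
        peaks = [dpeak(2.0, 1e-5, 1e-4, fc, start=100 * i)
                 for i, fc in enumerate([2.0, -2.0, 1.0, -3.0])]
        kept = select_differential(peaks)
        ups = sum(1 for k in kept if k.direction == HD_UP)
        downs = sum(1 for k in kept if k.direction == HD_DOWN)
        assert ups + downs == len(kept) == 4

    def test_lowering_q_cut_never_adds_peaks(self, rng):
        peaks = [
            dpeak(float(c), float(p), float(q), float(fc), start=50 * i)
            for i, (c, p, q, fc) in enumerate(
                zip(
                    rng.uniform(0, 4, 200),
                    rng.uniform(0, 1, 200),
                    rng.uniform(0, 1, 200),
                    rng.normal(0, 3, 200),
                )
            )
        ]
        cuts = [0.2, 0.05, 0.01, 0.001]
        sizes = [
            len(select_differential(peaks, SelectionCriteria(q_cut=c)))
            for c in cuts
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestSummaries:
    def test_enriched_depleted_arithmetic(self):
        df = summarize_counts([{"stage": "PSC", "enriched": 1923, "depleted": 753}])
        row = df.iloc[0]
        assert row["total_differential"] == 2676
        assert row["enriched_pct"] == 71.9
        assert row["depleted_pct"] == 28.1

    def test_zero_totals_report_na(self):
        df = summarize_counts([{"stage": "s", "enriched": 0, "depleted": 0}])
        assert df.iloc[0]["enriched_pct"] is None

    def test_proximal_total_sums_enriched_plus_depleted(self):
        df = summarize_counts(
            [
                {
                    "stage": "all",
                    "enriched": 315,
                    "depleted": 2152,
                    "proximal_enriched": 315,
                    "proximal_depleted": 2152,
                }
            ]
        )
        assert df.iloc[0]["proximal_differential"] == 2467

    def test_counts_from_annotated_peaks(self):
        from dataclasses import replace

        sel = [
            replace(dpeak(2, 1e-4, 1e-3, 2.0, start=i * 200),
                    direction=HD_UP if i % 2 else HD_DOWN,
                    proximity="proximal" if i < 2 else "distal")
            for i in range(5)
        ]
        df = summarize_differential({"NPC": sel})
        row = df.iloc[0]
        assert row["total_differential"] == 5
        assert row["enriched"] + row["depleted"] == 5
        assert row["proximal_differential"] + row["distal_differential"] == 5


class TestPromoterOccupancy:
    @staticmethod
    def _genes(n, spacing=5000):
        return [
            GeneModel.from_body(
                f"g{i}", GenomicInterval("chr1", 2000 + i * spacing,
                                         2000 + i * spacing + 2000), "+"
            )
            for i in range(n)
        ]

    @staticmethod
    def _frags_for_means(rng, genes, means, n_frags=None):
        frags = []
        for g, mu in zip(genes, means):
            c = rng.poisson(mu)
            centers = rng.integers(g.tss - 900, g.tss + 900, size=c)
            for ctr in centers:
                frags.append(frag(int(ctr) - 100, int(ctr) + 100))
        return frags

    def test_planted_occupancy_gain_recovered(self):
        rng = np.random.default_rng(17)
        genes = self._genes(500)
        base = 100 * np.exp(rng.normal(0, 0.3, size=500))
        hd = base.copy()
        hd[:10] *= 3.0  # planted 3x occupancy gain
        res = diff_promoter_occupancy(
            self._frags_for_means(rng, genes, hd),
            self._frags_for_means(rng, genes, base),
            genes,
            criteria=SelectionCriteria(min_logCPM=-np.inf, alt_logFC=np.inf),
        )
        selected = {dp.peak.name for dp in res.selected}
        planted = {f"g{i}" for i in range(10)}
        assert len(selected & planted) >= 8
        assert len(selected - planted) <= 2

    def test_identical_samples_select_almost_nothing(self):
        rng = np.random.default_rng(23)
        genes = self._genes(400)
        base = 80 * np.exp(rng.normal(0, 0.3, size=400))
        res = diff_promoter_occupancy(
            self._frags_for_means(rng, genes, base),
            self._frags_for_means(rng, genes, base),
            genes,
            criteria=SelectionCriteria(min_logCPM=-np.inf, alt_logFC=np.inf),
        )
        assert len(res.selected) <= 4  # <= 1% of promoters

    def test_zero_fragments_empty_result(self):
        res = diff_promoter_occupancy([], [], self._genes(5))
        assert res.table == [] and res.selected == []


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        assert replicate_correlation([1, 5, 9], [1, 5, 9]) == pytest.approx(1.0)

    def test_poisson_noise_keeps_high_correlation(self):
        rng = np.random.default_rng(2)
        mu = 50 * np.exp(rng.normal(0, 0.6, size=1000))
        r = replicate_correlation(rng.poisson(mu), rng.poisson(mu))
        assert r > 0.9

    def test_constant_vector_is_nan(self):
        assert np.isnan(replicate_correlation([3, 3, 3], [1, 2, 3]))


class TestModelResults:
    def test_fit_returns_populated_results(self, rng):
        x1 = rng.poisson(100, size=200).astype(float)
        x2 = rng.poisson(100, size=200).astype(float)
        res = MAnormModel(make_counts(x1, x2)).fit()
        assert len(res.table) == 200
        assert all(0 <= dp.p <= 1 and 0 <= dp.q <= 1 for dp in res.table)
        assert "MA-normalized" in res.summary()

    def test_null_data_selects_nothing(self, rng):
        x1 = rng.poisson(100, size=500).astype(float)
        x2 = rng.poisson(100, size=500).astype(float)
        res = MAnormModel(make_counts(x1, x2)).fit()
        assert len(res.selected) <= 5
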