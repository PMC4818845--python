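"""Enhancer/TSS calling, coverage grouping, enrichment and matching."""

import numpy as np
import pytest
from scipy import stats

from aluhic.regulatory import (
    ActiveTSS,
    background_coverage,
    call_active_enhancers,
    call_active_tss,
    classify_enhancer_origin,
    compare_active_expression,
    count_in_binpair,
    coverage_enrichment_test,
    deredundant_loci,
    element_coverage_correlation,
    flank_coverage,
    group_bins_by_coverage,
    match_peak_sets,
)
from aluhic.types import BinPair, GeneLocus, GenomicInterval, Peak, TEAnnotation


def peak(start, end, chrom="chrA", summit=None, signal=1.0):
    return Peak(GenomicInterval(chrom, start, end), summit_offset=summit,
                signal=signal)


def gene(start, end, symbol, tss, strand="+", chrom="chrA"):
    return GeneLocus(GenomicInterval(chrom, start, end, strand=strand),
                     symbol=symbol, strand=strand, tss_positions=tuple(tss))


def alu(start, end, chrom="chrA"):
    return TEAnnotation(GenomicInterval(chrom, start, end), "SINE", "Alu",
                        "AluSx")


class TestDeredundant:
    def test_longest_kept(self):
        genes = [gene(0, 5_000, "X", [0]), gene(10_000, 17_000, "X", [10_000])]
        (kept,) = deredundant_loci(genes)
        assert len(kept.interval) == 7_000

    def test_unique_symbols_unchanged(self):
        genes = [gene(0, 5_000, "A", [0]), gene(10_000, 15_000, "B", [10_000])]
        assert deredundant_loci(genes) == genes

    def test_tie_broken_by_smaller_start(self):
        genes = [gene(10_000, 15_000, "X", [10_000]), gene(0, 5_000, "X", [0])]
        (kept,) = deredundant_loci(genes)
        assert kept.interval.start == 0


class TestCallActiveEnhancers:
    def test_disjoint_sets_empty(self):
        assert call_active_enhancers(
            [peak(0, 100)], [peak(500, 600)]
        ) == []

    def test_documented_overlap(self):
        (call,) = call_active_enhancers([peak(100, 500)], [peak(400, 800)])
        assert (call.interval.start, call.interval.end) == (400, 500)

    def test_chained_touching_intersections_merged(self):
        me1 = [peak(0, 300), peak(300, 600)]
        ac = [peak(100, 500)]
        (call,) = call_active_enhancers(me1, ac)
        assert (call.interval.start, call.interval.end) == (100, 500)

    def test_matches_per_base_and_oracle(self, rng):
        for _ in range(100):
            me1 = [
                peak(int(s), int(s) + int(rng.integers(1, 300)))
                for s in rng.integers(0, 3_000, int(rng.integers(1, 10)))
            ]
            ac = [
                peak(int(s), int(s) + int(rng.integers(1, 300)))
                for s in rng.integers(0, 3_000, int(rng.integers(1, 10)))
            ]
            calls = call_active_enhancers(me1, ac)
            mask1 = np.zeros(4_000, dtype=bool)
            mask2 = np.zeros(4_000, dtype=bool)
            for p in me1:
                mask1[p.interval.start : p.interval.end] = True
            for p in ac:
                mask2[p.interval.start : p.interval.end] = True
            want = mask1 & mask2
            got = np.zeros(4_000, dtype=bool)
            for c in calls:
                assert not got[c.interval.start : c.interval.end].any()
                got[c.interval.start : c.interval.end] = True
            assert np.array_equal(got, want)


class TestCallActiveTss:
    def test_peak_on_second_tss_only(self):
        genes = [gene(0, 10_000, "X", [100, 5_000])]
        (active,) = call_active_tss(genes, [peak(4_900, 5_100)])
        assert active.position == 5_000
        assert active.n_supporting_peaks == 1

    def test_no_peaks_no_active_tss(self):
        assert call_active_tss([gene(0, 10_000, "X", [100])], []) == []

    def test_tie_broken_by_signal(self):
        genes = [gene(0, 10_000, "X", [1_000, 5_000])]
        peaks = [
            peak(900, 1_100, signal=5.0),
            peak(4_900, 5_100, signal=10.0),
        ]
        (active,) = call_active_tss(genes, peaks)
        assert active.position == 5_000

    def test_count_beats_signal(self):
        genes = [gene(0, 10_000, "X", [1_000, 5_000])]
        peaks = [
            peak(900, 1_100, signal=1.0),
            peak(950, 1_050, signal=1.0),
            peak(4_900, 5_100, signal=100.0),
        ]
        (active,) = call_active_tss(genes, peaks)
        assert active.position == 1_000
        assert active.n_supporting_peaks == 2


class TestCountInBinpair:
    PAIR = BinPair("chrA", 0, 80_000, 5.0)

    def test_midpoint_rule(self):
        inside = peak(10_000, 11_000)  # midpoint in bin i
        straddle = peak(39_000, 43_000)  # midpoint 41,000: outside both bins
        assert count_in_binpair([inside], self.PAIR) == 1
        assert count_in_binpair([straddle], self.PAIR) == 0

    def test_point_elements(self):
        tss_in = ActiveTSS("chrA", "X", 85_000, 1, "+")
        tss_out = ActiveTSS("chrA", "Y", 50_000, 1, "+")
        assert count_in_binpair([tss_in, tss_out], self.PAIR) == 1

    def test_matches_bruteforce_midpoint_filter(self, rng):
        elements = [
            peak(int(s), int(s) + int(rng.integers(1, 5_000)))
            for s in rng.integers(0, 200_000, 500)
        ]
        got = count_in_binpair(elements, self.PAIR)
        want = 0
        for p in elements:
            m = p.interval.midpoint
            if 0 <= m < 40_000 or 80_000 <= m < 120_000:
                want += 1
        assert got == want


class TestGroupBins:
    def bins(self, n, chrom="chrA"):
        return [
            GenomicInterval(chrom, k * 40_000, (k + 1) * 40_000)
            for k in range(n)
        ]

    def test_ten_bins_five_groups_of_two(self):
        alus = [alu(k * 40_000, k * 40_000 + 1_000 * k) for k in range(1, 10)]
        groups = group_bins_by_coverage(self.bins(10), alus, k=5)
        sizes = [int((groups.assignment == g).sum()) for g in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_equal_coverage_grouped_by_genomic_order(self):
        groups = group_bins_by_coverage(self.bins(10), [], k=5)
        assert list(groups.assignment) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_group_means_non_decreasing(self, rng):
        alus = [
            alu(k * 40_000 + 100, k * 40_000 + 100 + int(rng.integers(1, 30_000)))
            for k in range(40)
        ]
        groups = group_bins_by_coverage(self.bins(40), alus, k=5)
        means = groups.group_mean_coverage
        assert np.all(np.diff(means) >= 0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            group_bins_by_coverage(self.bins(3), [], k=5)


class TestElementCoverageCorrelation:
    def test_linear_counts_give_r_one(self):
        bins = [
            GenomicInterval("chrA", k * 40_000, (k + 1) * 40_000)
            for k in range(10)
        ]
        # coverage grows with k; plant k elements in bin k
        alus = [
            alu(k * 40_000, k * 40_000 + 2_000 * k) for k in range(1, 10)
        ]
        elements = [
            peak(k * 40_000 + 100 + 20 * j, k * 40_000 + 110 + 20 * j)
            for k in range(10)
            for j in range(k)
        ]
        groups = group_bins_by_coverage(bins, alus, k=5)
        res = element_coverage_correlation(groups, elements)
        assert res.n == 5
        assert res.r > 0.97

    def test_constant_counts_rejected(self):
        bins = [
            GenomicInterval("chrA", k * 40_000, (k + 1) * 40_000)
            for k in range(10)
        ]
        groups = group_bins_by_coverage(bins, [], k=5)
        with pytest.raises(ValueError):
            element_coverage_correlation(groups, [])

    def test_agrees_with_correlate_xy_on_same_points(self):
        from aluhic.enrichment import correlate_xy

        bins = [
            GenomicInterval("chrA", k * 40_000, (k + 1) * 40_000)
            for k in range(10)
        ]
        alus = [alu(k * 40_000, k * 40_000 + 1_500 * k) for k in range(1, 10)]
        elements = [
            peak(k * 40_000 + 50, k * 40_000 + 150)
            for k in range(10)
            for _ in range(k % 4)
        ]
        groups = group_bins_by_coverage(bins, alus, k=5)
        res = element_coverage_correlation(groups, elements)
        counts = np.zeros(10)
        for el in elements:
            counts[el.interval.midpoint // 40_000] += 1
        x = groups.group_mean_coverage
        y = [counts[groups.assignment == g].mean() for g in range(5)]
        want = correlate_xy(x, y)
        assert res.r == pytest.approx(want.r, abs=1e-12)
        assert res.p == pytest.approx(want.p, abs=1e-12)


class TestEnhancerOrigin:
    ALUS = [alu(10_000, 10_300)]

    def test_summit_inside_alu(self):
        p = peak(9_000, 11_000, summit=1_100)  # summit at 10,100
        assert classify_enhancer_origin([p], self.ALUS) == ["Alu_derived"]

    def test_summit_outside_alu(self):
        p = peak(9_000, 11_000, summit=100)
        assert classify_enhancer_origin([p], self.ALUS) == ["non_Alu"]

    def test_midpoint_fallback(self):
        p = peak(10_100, 10_200)  # no summit; midpoint inside the Alu
        assert classify_enhancer_origin([p], self.ALUS) == ["Alu_derived"]


class TestFlankCoverage:
    def test_window_width_and_clipping(self):
        alus = [alu(0, 25_000)]
        p = peak(4_000, 6_000)  # reference midpoint 5,000
        (cov,) = flank_coverage([p], alus, flank=20_000,
                                chrom_sizes={"chrA": 1_000_000})
        # window [0, 25,000): fully covered by the Alu
        assert cov == pytest.approx(1.0)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            alus = [
                alu(int(s), int(s) + int(rng.integers(100, 5_000)))
                for s in rng.integers(0, 100_000, 10)
            ]
            start = int(rng.integers(0, 60_000))
            p = peak(start, start + 2_000)
            (cov,) = flank_coverage([p], alus, flank=10_000,
                                    chrom_sizes={"chrA": 120_000})
            ref = p.interval.midpoint
            lo, hi = max(0, ref - 10_000), min(120_000, ref + 10_000)
            covered = np.zeros(120_000, dtype=bool)
            for a in alus:
                covered[a.interval.start : a.interval.end] = True
            assert cov == pytest.approx(covered[lo:hi].mean())


class TestBackgroundCoverage:
    def test_determinism_and_bounds(self, bundle, te_index):
        cov1, m1 = background_coverage(bundle.chrom_sizes, te_index, 200, seed=9)
        cov2, m2 = background_coverage(bundle.chrom_sizes, te_index, 200, seed=9)
        assert np.array_equal(cov1, cov2) and m1 == m2
        assert np.all((cov1 >= 0) & (cov1 <= 1))

    def test_mean_converges_to_genome_alu_fraction(self, bundle, te_index):
        cov, mean = background_coverage(
            bundle.chrom_sizes, te_index, 10_000, seed=11
        )
        alu_bases = sum(
            len(t.interval) for t in bundle.repeats if t.family == "Alu"
        )
        genome_fraction = alu_bases / sum(bundle.chrom_sizes.values())
        sigma = cov.std() / np.sqrt(cov.size)
        assert abs(mean - genome_fraction) < 3 * sigma + 1e-3

    def test_width_larger_than_genome_rejected(self, te_index):
        with pytest.raises(ValueError):
            background_coverage({"chrA": 10_000}, te_index, 10, width=40_000)


class TestEnrichmentTest:
    def test_closed_form_binomial_tail(self, rng):
        # background with p0 = 0.5 and all 20 observed windows above its mean
        background = np.concatenate([np.zeros(500), np.ones(500)])
        observed = np.full(20, 0.9)
        res = coverage_enrichment_test(observed, background, method="binomial")
        assert res.background_p0 == pytest.approx(0.5)
        assert res.k_above_background == 20
        assert res.p_value == pytest.approx(0.5**20, rel=1e-9)

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            coverage_enrichment_test(np.array([]), np.array([0.1, 0.9]))

    def test_permutation_null_calibration_median(self, rng):
        background = rng.random(2_000)
        pvals = []
        for k in range(60):
            observed = rng.choice(background, 40)
            res = coverage_enrichment_test(
                observed, background, method="permutation", seed=k,
                n_permutations=500,
            )
            pvals.append(res.p_value)
        assert 0.25 < np.median(pvals) < 0.75


class TestMatchPeakSets:
    def test_identical_sets_fully_shared(self):
        peaks = [peak(100 + 1_000 * k, 200 + 1_000 * k) for k in range(10)]
        res = match_peak_sets(peaks, list(peaks))
        assert res.shared == 10
        assert res.fraction_a == res.fraction_b == 1.0

    def test_distance_threshold_strict(self):
        a = [peak(1_000, 1_001)]
        assert match_peak_sets(a, [peak(1_260, 1_261)]).shared == 0  # 260 bp
        assert match_peak_sets(a, [peak(1_240, 1_241)]).shared == 1  # 240 bp

    def test_symmetry(self, rng):
        a = [peak(int(s), int(s) + 100) for s in rng.integers(0, 50_000, 30)]
        b = [peak(int(s), int(s) + 100) for s in rng.integers(0, 50_000, 20)]
        fwd = match_peak_sets(a, b)
        rev = match_peak_sets(b, a)
        assert fwd.shared == rev.shared
        assert fwd.fraction_a == rev.fraction_b

    def test_matches_exhaustive_mutual_nearest_oracle(self, rng):
        for _ in range(100):
            xa = sorted(int(x) for x in rng.integers(0, 20_000, 15))
            xb = sorted(int(x) for x in rng.integers(0, 20_000, 12))
            a = [peak(x, x + 1) for x in xa]
            b = [peak(x, x + 1) for x in xb]
            ra = [p.reference_point for p in a]
            rb = [p.reference_point for p in b]

            def nearest(x, others):
                best = min(range(len(others)),
                           key=lambda j: (abs(others[j] - x), others[j]))
                return best

            want = 0
            for i, x in enumerate(ra):
                j = nearest(x, rb)
                if nearest(rb[j], ra) == i and abs(x - rb[j]) < 250:
                    want += 1
            assert match_peak_sets(a, b).shared == want


class TestExpressionComparison:
    def test_separated_samples(self):
        expression = {f"a{k}": 10.0 + k for k in range(25)}
        expression.update({f"b{k}": 1.0 + 0.1 * k for k in range(25)})
        res = compare_active_expression(expression, [f"a{k}" for k in range(25)])
        assert res.direction == 1
        assert res.p < 0.01

    def test_null_calibration(self, rng):
        pvals = []
        for _ in range(50):
            values = rng.normal(size=40)
            expression = {f"g{k}": float(v) for k, v in enumerate(values)}
            active = [f"g{k}" for k in rng.choice(40, 20, replace=False)]
            pvals.append(compare_active_expression(expression, active).p)
        assert stats.kstest(pvals, "uniform").statistic < 0.3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_active_expression({"a": 1.0}, ["a"])
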