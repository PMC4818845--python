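"""Origin partition and GC/CpG/methylation accounting."""

import numpy as np
import pytest

from aluhic.composition import (
    CLASSES,
    GenomeComposition,
    CpGTable,
    composition_summary,
    cpg_density,
    cpg_density_ratio,
    estimate_methylation_rate,
    gc_contribution,
    methylation_density,
    partition_binpair,
    subfamily_methylation,
)
from aluhic.types import BinPair, CpGSite, GenomicInterval, TEAnnotation


def te(start, end, family="Alu", chrom="chrA", sub=None, cls="SINE"):
    sub = sub or {"Alu": "AluSx", "MIR": "MIRb"}.get(family, family)
    return TEAnnotation(GenomicInterval(chrom, start, end), cls, family, sub)


PAIR = BinPair("chrA", 0, 40_000, 10.0)


def naive_partition(pair, annotations):
    """Per-base class assignment with the Alu > SINE_non_Alu precedence."""
    windows = [range(pair.start_i, pair.start_i + pair.bin_size),
               range(pair.start_j, pair.start_j + pair.bin_size)]
    labels = {}
    for w in windows:
        for b in w:
            labels[b] = "non_SINE"
    for t in annotations:
        if t.te_class != "SINE" or t.family == "Alu":
            continue
        if t.interval.chrom != pair.chrom:
            continue
        for b in range(t.interval.start, t.interval.end):
            if b in labels:
                labels[b] = "SINE_non_Alu"
    for t in annotations:
        if t.family != "Alu" or t.interval.chrom != pair.chrom:
            continue
        for b in range(t.interval.start, t.interval.end):
            if b in labels:
                labels[b] = "Alu"
    return labels


class TestPartition:
    def test_no_sines_all_non_sine(self):
        part = partition_binpair(PAIR, [te(100, 400, family="L1", cls="LINE")])
        assert part.class_length("non_SINE") == 80_000
        assert part.class_length("Alu") == 0
        assert part.class_length("SINE_non_Alu") == 0

    def test_documented_lengths(self):
        part = partition_binpair(
            PAIR, [te(0, 300, "Alu"), te(300, 400, "MIR")]
        )
        assert part.class_length("Alu") == 300
        assert part.class_length("SINE_non_Alu") == 100
        assert part.class_length("non_SINE") == 79_600

    def test_alu_precedence_on_overlap(self):
        part = partition_binpair(
            PAIR, [te(100, 200, "Alu"), te(100, 200, "MIR")]
        )
        assert part.class_length("Alu") == 100
        assert part.class_length("SINE_non_Alu") == 0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(40):
            pair = BinPair("chrA", 0, 1_000, 5.0, bin_size=1_000)
            annotations = []
            for _ in range(int(rng.integers(0, 10))):
                s = int(rng.integers(0, 1_900))
                e = s + int(rng.integers(1, 300))
                fam = "Alu" if rng.random() < 0.5 else "MIR"
                annotations.append(te(s, e, fam))
            part = partition_binpair(pair, annotations)
            oracle = naive_partition(pair, annotations)
            for cls in CLASSES:
                bases = set()
                for iv in part.classes[cls]:
                    bases.update(range(iv.start, iv.end))
                want = {b for b, c in oracle.items() if c == cls}
                assert bases == want, cls

    def test_disjoint_cover_invariant(self, bundle, te_index):
        pair = bundle.binpairs[0]
        part = partition_binpair(pair, te_index)
        total = sum(part.class_length(c) for c in CLASSES)
        assert total == 2 * pair.bin_size


def make_genome(seq, chrom="chrA"):
    return {chrom: seq}


class TestCompositionSummary:
    def test_direct_counts_cgcg(self):
        # toy 1-bp-bin pair over the sequence "CGCG...": sites at 0 and 2
        pair = BinPair("chrA", 0, 4, 1.0, bin_size=4)
        genome = make_genome("CGCGATAT")
        calls = [CpGSite("chrA", 0, True), CpGSite("chrA", 2, True)]
        part = partition_binpair(pair, [])
        s = composition_summary(genome, part, calls)
        cc = s.counts["non_SINE"]
        assert (cc.gc_count, cc.cpg_count, cc.meth_cpg_count) == (4, 2, 2)

    def test_at_only_sequence(self):
        pair = BinPair("chrA", 0, 4, 1.0, bin_size=4)
        s = composition_summary(
            make_genome("ATATATAT"), partition_binpair(pair, []), []
        )
        assert s.total("gc_count") == 0
        assert s.total("cpg_count") == 0

    def test_c_position_assigns_class(self):
        # CpG with C as the last Alu base and G outside -> counted in Alu
        seq = "A" * 99 + "CG" + "A" * 99
        pair = BinPair("chrA", 0, 100, 1.0, bin_size=100)
        annotations = [te(0, 100, "Alu")]
        calls = [CpGSite("chrA", 99, True)]
        s = composition_summary(
            make_genome(seq), partition_binpair(pair, annotations), calls
        )
        assert s.counts["Alu"].cpg_count == 1
        assert s.counts["non_SINE"].cpg_count == 0

    def test_non_cg_call_rejected(self):
        pair = BinPair("chrA", 0, 4, 1.0, bin_size=4)
        with pytest.raises(ValueError, match="not a CG"):
            composition_summary(
                make_genome("ATATATAT"),
                partition_binpair(pair, []),
                [CpGSite("chrA", 1, True)],
            )

    def test_n_bases_count_length_not_gc(self):
        pair = BinPair("chrA", 0, 4, 1.0, bin_size=4)
        s = composition_summary(
            make_genome("GNNCATAT"), partition_binpair(pair, []), []
        )
        assert s.counts["non_SINE"].total_len == 8
        assert s.counts["non_SINE"].gc_count == 2  # G and C only

    def test_matches_naive_per_base_scan(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(rng.choice(bases, 2_000))
            pair = BinPair("chrA", 0, 1_000, 5.0, bin_size=1_000)
            annotations = [
                te(int(s), int(s) + int(rng.integers(50, 300)),
                   "Alu" if rng.random() < 0.5 else "MIR")
                for s in rng.integers(0, 1_800, int(rng.integers(0, 6)))
            ]
            cg_positions = [
                k for k in range(1_999)
                if seq[k] == "C" and seq[k + 1] == "G"
            ]
            calls = [
                CpGSite("chrA", k, bool(rng.random() < 0.7))
                for k in cg_positions
            ]
            s = composition_summary(
                make_genome(seq), partition_binpair(pair, annotations), calls
            )
            labels = naive_partition(pair, annotations)
            want = {c: [0, 0, 0, 0] for c in CLASSES}
            meth = {c.pos: c.methylated for c in calls}
            for b, cls in labels.items():
                want[cls][0] += 1
                want[cls][1] += seq[b] in "GC"
                if b in meth:
                    want[cls][2] += 1
                    want[cls][3] += meth[b]
            for cls in CLASSES:
                cc = s.counts[cls]
                assert [cc.total_len, cc.gc_count, cc.cpg_count,
                        cc.meth_cpg_count] == want[cls], cls


class TestDerivedQuantities:
    def make_summary(self):
        # 100-bp combined region: Alu bin [0,50) with 30 G/C,
        # non_SINE bin [50,100) with 20 G/C
        pair = BinPair("chrA", 0, 50, 1.0, bin_size=50)
        seq = ("G" * 30 + "A" * 20) + ("C" * 20 + "T" * 30)
        return composition_summary(
            make_genome(seq), partition_binpair(pair, [te(0, 50, "Alu")]), []
        )

    def test_gc_contribution_conservation(self):
        contributions, background = gc_contribution(self.make_summary())
        assert contributions["Alu"] == pytest.approx(0.30)
        assert contributions["SINE_non_Alu"] == 0
        assert contributions["non_SINE"] == pytest.approx(0.20)
        assert background == pytest.approx(0.50)
        assert background == pytest.approx(sum(contributions.values()))

    def test_cpg_density_and_absence(self):
        s = self.make_summary()
        s.counts["Alu"].cpg_count = 2
        s.counts["Alu"].gc_count = 4
        assert cpg_density(s, "Alu") == pytest.approx(0.5)
        s.counts["SINE_non_Alu"].gc_count = 0
        assert cpg_density(s, "SINE_non_Alu") is None

    def test_cpg_density_ratio(self):
        s = self.make_summary()
        s.counts["Alu"].gc_count, s.counts["Alu"].cpg_count = 4, 2
        s.counts["non_SINE"].gc_count, s.counts["non_SINE"].cpg_count = 8, 2
        s.counts["SINE_non_Alu"].gc_count = 0
        s.counts["SINE_non_Alu"].cpg_count = 0
        assert cpg_density_ratio(s) == pytest.approx(2.0)

    def test_methylation_density(self):
        s = self.make_summary()
        s.counts["Alu"].cpg_count, s.counts["Alu"].meth_cpg_count = 10, 9
        assert methylation_density(s, "Alu") == pytest.approx(0.9)
        assert methylation_density(s, "non_SINE") is None


class TestMethylationRate:
    def test_equal_densities_zero(self):
        assert estimate_methylation_rate(0.9, 81, 0.9, 36) == 0

    def test_direct_arithmetic(self):
        rate = estimate_methylation_rate(0.92, 81, 0.90, 36)
        assert rate == pytest.approx((0.92 - 0.90) / (81 - 36))
        assert rate == pytest.approx(4.44e-4, rel=0.01)

    def test_antisymmetry_and_equal_age_error(self):
        fwd = estimate_methylation_rate(0.92, 81, 0.90, 36)
        rev = estimate_methylation_rate(0.90, 36, 0.92, 81)
        assert fwd == pytest.approx(rev)  # consistent swap leaves rate fixed
        assert estimate_methylation_rate(0.90, 81, 0.92, 36) == pytest.approx(
            -estimate_methylation_rate(0.92, 81, 0.90, 36)
        )
        with pytest.raises(ValueError):
            estimate_methylation_rate(0.9, 50, 0.8, 50)


class TestSubfamilyMethylation:
    def test_recovers_planted_rates(self, bundle, te_index):
        densities = subfamily_methylation(bundle.cpg_sites, te_index)
        for g in ("AluJ", "AluS", "AluY"):
            assert abs(densities[g] - bundle.config.meth_rate[g]) < 0.02

    def test_all_methylated_and_absent_group(self):
        annotations = [te(0, 300, "Alu", sub="AluJb")]
        calls = [CpGSite("chrA", p, True) for p in (10, 20, 30)]
        d = subfamily_methylation(calls, annotations)
        assert d == {"AluJ": 1.0}
        assert "AluY" not in d


class TestConservationOnBundle:
    def test_exact_identities_every_retained_pair(self, bundle, stratified,
                                                  te_index):
        comp = GenomeComposition(bundle.genome, te_index, bundle.cpg_sites)
        table = CpGTable(bundle.cpg_sites)
        for pair in stratified.intra[:300]:
            s = comp.pair_summary(pair)
            assert s.total("total_len") == 2 * pair.bin_size
            contributions, background = gc_contribution(s)
            assert background == pytest.approx(sum(contributions.values()),
                                               abs=1e-15)
            pos_i, _ = table.in_range(
                pair.chrom, pair.start_i, pair.start_i + pair.bin_size
            )
            pos_j, _ = table.in_range(
                pair.chrom, pair.start_j, pair.start_j + pair.bin_size
            )
            assert s.total("cpg_count") == pos_i.size + pos_j.size
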