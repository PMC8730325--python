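import math
import statistics

import numpy as np
import pytest

import pirnakit as pk
from pirnakit.align import AlignmentSet, Placement, ReadRecord
from pirnakit.annotation import Feature, FeatureSet
from pirnakit.signatures import (FivePrimeMap, OverlapHistogram,
                                 alignment_five_prime_map, base_composition,
                                 five_prime_map, length_spectrum,
                                 overlap_histogram, oxidation_enrichment,
                                 pingpong_by_family, pingpong_z, strand_bias)


def brute_force_overlaps(plus, minus, dmax=20):
    """Oracle: all-pairs double loop over 5' ends (pos, weight) lists."""
    counts = {d: 0.0 for d in range(1, dmax + 1)}
    for p, wp in plus:
        for q, wq in minus:
            d = q - p + 1
            if 1 <= d <= dmax:
                counts[d] += wp * wq
    return counts


class TestFivePrimeMap:
    def test_conventions_and_conservation(self):
        aln = AlignmentSet()
        aln.add(ReadRecord("r1", "A" * 27, 1),
                [Placement("c", 100, 127, "+"), Placement("c", 300, 327, "-")])
        fpm = alignment_five_prime_map(aln)
        assert fpm.strand_map("c", "+") == {100: 0.5}
        assert fpm.strand_map("c", "-") == {326: 0.5}
        assert fpm.total() == pytest.approx(1.0)


class TestOverlapHistogram:
    def _map(self, plus, minus):
        fpm = FivePrimeMap()
        for p, w in plus:
            fpm.add("c", "+", p, w)
        for p, w in minus:
            fpm.add("c", "-", p, w)
        return fpm

    def test_ten_nt_overlap(self):
        hist = overlap_histogram(self._map([(100, 1.0)], [(109, 1.0)]))
        assert hist[10] == 1.0
        assert sum(hist.counts.values()) == 1.0

    def test_coincident_five_primes_are_distance_one(self):
        hist = overlap_histogram(self._map([(100, 1.0)], [(100, 1.0)]))
        assert hist[1] == 1.0

    def test_product_weighting(self):
        hist = overlap_histogram(self._map([(100, 2.0)], [(109, 3.0)]))
        assert hist[10] == 6.0

    def test_min_weighting_mode(self):
        hist = overlap_histogram(self._map([(100, 2.0)], [(109, 3.0)]),
                                 pair_weight="min")
        assert hist[10] == 2.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 200))
            plus = [(int(rng.integers(0, 300)), float(rng.integers(1, 5)))
                    for _ in range(n // 2)]
            minus = [(int(rng.integers(0, 300)), float(rng.integers(1, 5)))
                     for _ in range(n - n // 2)]
            fpm = FivePrimeMap()
            for p, w in plus:
                fpm.add("c", "+", p, w)
            for p, w in minus:
                fpm.add("c", "-", p, w)
            got = overlap_histogram(fpm).counts
            # the oracle works on raw lists; collapse duplicates first
            from collections import defaultdict
            cp, cm = defaultdict(float), defaultdict(float)
            for p, w in plus:
                cp[p] += w
            for p, w in minus:
                cm[p] += w
            expected = brute_force_overlaps(sorted(cp.items()),
                                            sorted(cm.items()))
            assert got == pytest.approx(expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(23)
        fpm = FivePrimeMap()
        for _ in range(100):
            fpm.add("c", "+-"[rng.integers(0, 2)],
                    int(rng.integers(0, 500)), 1.0)
        h0 = overlap_histogram(fpm).counts
        h1 = overlap_histogram(fpm.shifted(1234)).counts
        assert h0 == h1


class TestPingPongZ:
    def test_worked_example(self):
        """Background alternating 4/6 (nine each), c10=100: the Z-score
        equals (100-5)/sqrt(18/17), checked against direct arithmetic."""
        from pirnakit.signatures import BACKGROUND_DISTANCES
        counts = {d: (4.0 if i % 2 == 0 else 6.0)
                  for i, d in enumerate(BACKGROUND_DISTANCES)}
        counts[10] = 100.0
        counts[20] = 0.0
        res = pingpong_z(OverlapHistogram(counts))
        bg = [4.0, 6.0] * 9
        mu = sum(bg) / 18
        sd = statistics.stdev(bg)
        assert res.valid
        assert res.z == pytest.approx((100 - mu) / sd, abs=1e-9)
        assert res.z == pytest.approx(92.32, abs=0.01)

    def test_c10_at_background_mean_gives_zero(self):
        from pirnakit.signatures import BACKGROUND_DISTANCES
        counts = {d: (4.0 if i % 2 == 0 else 6.0)
                  for i, d in enumerate(BACKGROUND_DISTANCES)}
        counts[10] = 5.0
        counts[20] = 7.0
        res = pingpong_z(OverlapHistogram(counts))
        assert res.z == pytest.approx(0.0)

    def test_flat_histogram_is_degenerate(self):
        counts = {d: 3.0 for d in range(1, 21)}
        res = pingpong_z(OverlapHistogram(counts))
        assert not res.valid
        assert math.isnan(res.z)

    def test_distance_20_excluded_from_background(self):
        counts = {d: 5.0 for d in range(1, 21)}
        counts[3] = 4.0        # some variance in 1..19 background
        counts[20] = 1000.0    # must not perturb mu/sigma
        res = pingpong_z(OverlapHistogram(counts))
        assert res.bg_mean == pytest.approx((5.0 * 17 + 4.0) / 18)


def _family_genome():
    features = FeatureSet([
        Feature("c", 0, 1000, "+", "transposon", family="LTR/Gypsy",
                feature_id="te0"),
        Feature("c", 2000, 3000, "-", "transposon", family="DNA/PIF-Harbinger",
                feature_id="te1"),
    ])
    return features


def _aln(entries):
    """entries: list of (contig, start, length, strand, count)."""
    aln = AlignmentSet()
    for i, (c, s, L, st, n) in enumerate(entries):
        aln.add(ReadRecord(f"r{i}", "A" * L, n),
                [Placement(c, s, s + L, st)])
    return aln


class TestPerFamily:
    def test_planted_family_outscores_untouched_family(self):
        rng = np.random.default_rng(31)
        entries = []
        # family 1: 30 planted ping-pong pairs
        for _ in range(30):
            p = int(rng.integers(0, 950))
            entries.append(("c", p, 27, "+", 1))
            entries.append(("c", p + 10 - 27, 27, "-", 1))
        # family 2: random reads, no pairing structure
        for _ in range(60):
            entries.append(("c", int(rng.integers(2000, 2970)), 27,
                            "+-"[rng.integers(0, 2)], 1))
        pp = pingpong_by_family(_aln(entries), _family_genome())
        zf = pp["LTR/Gypsy"].z
        zg = pp["DNA/PIF-Harbinger"].z
        assert zf > 10
        assert not pp["DNA/PIF-Harbinger"].valid or zg < 5

    def test_single_family_equals_overall(self):
        entries = [("c", 100, 27, "+", 2), ("c", 100 + 10 - 27, 27, "-", 3),
                   ("c", 400, 27, "+", 1), ("c", 500, 27, "-", 1)]
        pp = pingpong_by_family(_aln(entries), FeatureSet([
            Feature("c", 0, 1000, "+", "transposon", family="LTR/Gypsy")]))
        assert pp["LTR/Gypsy"].c10 == pp["overall"].c10
        if pp["overall"].valid:
            assert pp["LTR/Gypsy"].z == pytest.approx(pp["overall"].z)

    def test_sparse_family_never_crashes(self):
        pp = pingpong_by_family(_aln([("c", 100, 27, "+", 1)]),
                                _family_genome())
        assert not pp["LTR/Gypsy"].valid


class TestStrandBias:
    def test_definition_and_extremes(self):
        features = _family_genome()
        # all reads opposite the + element
        aln = _aln([("c", 100, 27, "-", 1), ("c", 300, 27, "-", 2)])
        sb = strand_bias(aln, features)
        assert sb.antisense_fraction("LTR/Gypsy") == 1.0
        # read on -, feature on -: sense
        aln = _aln([("c", 2100, 27, "-", 1)])
        sb = strand_bias(aln, features)
        assert sb.antisense_fraction("DNA/PIF-Harbinger") == 0.0

    def test_per_length_split_sums_to_family_totals(self):
        features = _family_genome()
        aln = _aln([("c", 100, 27, "-", 1), ("c", 150, 25, "+", 2),
                    ("c", 2100, 26, "-", 1)])
        sb = strand_bias(aln, features)
        for fam in sb.by_length:
            s = sum(v[0] for v in sb.by_length[fam].values())
            a = sum(v[1] for v in sb.by_length[fam].values())
            assert s == pytest.approx(sb.sense.get(fam, 0.0))
            assert a == pytest.approx(sb.antisense.get(fam, 0.0))


class TestBaseComposition:
    def _reads(self, seqs):
        return [ReadRecord(f"r{i}", s, 1) for i, s in enumerate(seqs)]

    def test_all_t_start(self):
        _m, first_u, _ = base_composition(self._reads(["T" + "A" * 26] * 5))
        assert first_u == 1.0

    def test_equal_mix(self):
        seqs = [b + "A" * 26 for b in "ACGT"]
        mat, first_u, _ = base_composition(self._reads(seqs))
        assert first_u == pytest.approx(0.25)
        assert mat.freq[0].sum() == pytest.approx(1.0)

    def test_rows_weighted_by_count(self):
        reads = [ReadRecord("a", "T" + "A" * 26, 3),
                 ReadRecord("b", "G" + "A" * 26, 1)]
        _m, first_u, _ = base_composition(reads)
        assert first_u == pytest.approx(0.75)

    def test_short_reads_only_fill_their_rows(self):
        reads = self._reads(["TACGTACGTACGTACGTACG",          # 20 nt
                             "TACGTACGTACGTACGTACGTACGTAC"])  # 27 nt
        mat, _, _ = base_composition(reads)
        assert mat.freq[26].sum() == pytest.approx(1.0)   # one read long enough
        assert mat.freq[29].sum() == 0.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            base_composition([])


class TestLengthSpectrum:
    def test_single_length(self, sim_classified):
        cfg, genome, features, reads, truth, aln, cr = sim_classified
        spec = length_spectrum(cr)
        assert spec.total() == pytest.approx(aln.mapped_weight())

    def test_simulator_modes(self, sim_classified):
        """Default simulator conditions give the bimodal 22/27 spectrum."""
        cfg, genome, features, reads, truth, aln, cr = sim_classified
        spec = length_spectrum(cr)
        assert spec.mode("miRNA") == 22
        assert spec.mode("transposon") == 27


class TestOxidation:
    def test_identical_libraries_ratio_one(self, sim_classified):
        cfg, genome, features, reads, truth, aln, cr = sim_classified
        ox = oxidation_enrichment(cr, cr)
        for c, r in ox.class_ratio.items():
            if cr.class_weight.get(c, 0.0) > 0:
                assert r == pytest.approx(1.0)
        assert ox.oxidized_long_fraction == pytest.approx(
            ox.untreated_long_fraction)

    def test_empty_oxidized_class_ratio_zero(self):
        from pirnakit.annotation import FeatureIndex
        index = FeatureIndex([Feature("c", 0, 30, "+", "miRNA")])
        a1 = _aln([("c", 4, 22, "+", 1), ("c", 200, 27, "+", 1)])
        a2 = _aln([("c", 200, 27, "+", 1)])
        cr1 = pk.annotate_reads(a1, index)
        cr2 = pk.annotate_reads(a2, index)
        ox = oxidation_enrichment(cr1, cr2)
        assert ox.class_ratio["miRNA"] == 0.0
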