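import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnakit.align import AlignmentSet, Placement, ReadRecord
from pirnakit.annotation import GeneModel
from pirnakit.metagene import (ranksum_test, region_rpkm, scaled_profile,
                               to_transcript_coords, top_quartile_genes)


def _plus_gene(gid="g1"):
    return GeneModel(gid, "c1", "+", five_utr=[(0, 100)],
                     cds=[(100, 400)], three_utr=[(400, 600)])


def _minus_gene(gid="g2"):
    return GeneModel(gid, "c1", "-", five_utr=[(400, 600)],
                     cds=[(100, 400)], three_utr=[(0, 100)])


def _placement(start, length, strand, contig="c1"):
    return Placement(contig, start, start + length, strand)


class TestTranscriptCoords:
    def test_plus_gene_five_utr_start(self):
        assert to_transcript_coords(_placement(0, 27, "+"), _plus_gene()) == \
            ("five_utr", 0, "sense")

    def test_minus_gene_strand_symmetry(self):
        # 5' end of a minus-strand read at the rightmost base of the
        # rightmost block is transcript position 0
        p = _placement(573, 27, "-")       # interval [573, 600), 5' at 599
        assert to_transcript_coords(p, _minus_gene()) == \
            ("five_utr", 0, "sense")

    def test_antisense_orientation(self):
        assert to_transcript_coords(_placement(0, 27, "-"), _plus_gene())[2] \
            == "antisense"

    def test_intronic_five_prime_returns_none(self):
        m = GeneModel("g", "c1", "+", five_utr=[(0, 100)],
                      cds=[(200, 500)], three_utr=[(500, 600)],
                      introns=[(100, 200)])
        assert to_transcript_coords(_placement(150, 27, "+"), m) is None

    def test_spliced_offset_accumulates_across_blocks(self):
        m = GeneModel("g", "c1", "+", five_utr=[(0, 50), (100, 150)],
                      cds=[(150, 400)], three_utr=[(400, 600)])
        region, off, _ = to_transcript_coords(_placement(110, 27, "+"), m)
        assert (region, off) == ("five_utr", 60)


def _aln(entries):
    aln = AlignmentSet()
    for i, (start, L, strand) in enumerate(entries):
        aln.add(ReadRecord(f"r{i}", "A" * L, 1),
                [_placement(start, L, strand)])
    return aln


class TestScaledProfile:
    def test_boundary_bins(self):
        model = _plus_gene()
        aln = _aln([(0, 27, "+"), (100, 27, "+")])
        prof = scaled_profile(aln, [model], mapped_weight=1e6)
        assert prof.sense[0] > 0          # first base of 5'UTR -> bin 0
        assert prof.sense[350] > 0        # first base of CDS -> bin 350
        assert prof.sense[1:350].sum() == 0
        assert prof.region_starts == (0, 350, 1350)

    def test_mass_conservation(self):
        """Summed bin mass equals summed per-gene scaled abundance."""
        rng = np.random.default_rng(2)
        model = _plus_gene()
        entries = [(int(rng.integers(0, 580)), 20, "+") for _ in range(200)]
        aln = _aln(entries)
        mapped = 200.0
        prof = scaled_profile(aln, [model], mapped)
        rpkm = region_rpkm(aln, [model], mapped)
        # profile mass: sum over bins of density * bin-kb * millions
        dens = 0.0
        for region, start, nb in (("five_utr", 0, 350), ("cds", 350, 1000),
                                  ("three_utr", 1350, 800)):
            kb = model.region_length(region) / nb / 1000
            dens += prof.sense[start:start + nb].sum() * kb * (mapped / 1e6)
        exonic = rpkm[rpkm.orientation == "sense"]["weight"].sum()
        assert dens == pytest.approx(exonic)

    def test_uniform_reads_give_flat_region_means(self):
        rng = np.random.default_rng(4)
        model = _plus_gene()
        entries = [(int(rng.integers(0, 600)), 1, "+") for _ in range(20000)]
        aln = _aln(entries)
        prof = scaled_profile(aln, [model], mapped_weight=20000.0)
        means = prof.region_means("sense")
        assert max(means.values()) / min(means.values()) < 1.5

    def test_intronic_reads_counted_separately(self):
        m = GeneModel("g", "c1", "+", five_utr=[(0, 100)],
                      cds=[(200, 500)], three_utr=[(500, 600)],
                      introns=[(100, 200)])
        aln = _aln([(150, 27, "+")])
        prof = scaled_profile(aln, [m], mapped_weight=10.0)
        assert prof.sense.sum() == 0
        assert prof.intron_weight == pytest.approx(1.0)


class TestRegionRpkm:
    def test_worked_example(self):
        # weight 10 in a 1 kb region, library 1e6 -> 10 RPKM
        m = GeneModel("g", "c1", "+", five_utr=[(0, 100)],
                      cds=[(100, 1100)], three_utr=[(1100, 1200)])
        aln = AlignmentSet()
        for i in range(10):
            aln.add(ReadRecord(f"r{i}", "A" * 27, 1),
                    [_placement(200 + i, 27, "+")])
        df = region_rpkm(aln, [m], 1e6)
        row = df[(df.region == "cds") & (df.orientation == "sense")]
        assert row["rpkm"].iloc[0] == pytest.approx(10.0)

    def test_doubling_library_halves_rpkm(self):
        m = _plus_gene()
        aln = _aln([(150, 27, "+")] * 1)
        r1 = region_rpkm(aln, [m], 1e6)["rpkm"]
        r2 = region_rpkm(aln, [m], 2e6)["rpkm"]
        assert np.allclose(r2, r1 / 2)

    def test_no_reads_zero_rpkm(self):
        df = region_rpkm(AlignmentSet(), [_plus_gene()], 1e6)
        assert (df["rpkm"] == 0).all()


class TestTopQuartile:
    def _abundance(self, weights):
        return pd.DataFrame([{"gene_id": g, "region": "cds",
                              "orientation": "sense", "weight": w,
                              "rpkm": w} for g, w in weights.items()])

    def test_eight_genes_top_two(self):
        ab = self._abundance({f"g{i}": float(i + 1) for i in range(8)})
        assert top_quartile_genes(ab) == ["g7", "g6"]

    def test_ceil_rule_n5(self):
        ab = self._abundance({f"g{i}": float(i + 1) for i in range(5)})
        assert len(top_quartile_genes(ab)) == 2

    def test_tie_broken_lexicographically(self):
        ab = self._abundance({"gb": 5.0, "ga": 5.0, "gc": 9.0, "gd": 1.0})
        assert top_quartile_genes(ab) == ["gc"]
        ab = self._abundance({"gb": 5.0, "ga": 5.0, "gc": 9.0, "gd": 1.0,
                              "ge": 0.5})
        assert top_quartile_genes(ab) == ["gc", "ga"]

    def test_fewer_than_four_returns_all(self):
        ab = self._abundance({"ga": 1.0, "gb": 2.0})
        assert top_quartile_genes(ab) == ["ga", "gb"]


def permutation_oracle(x, y):
    """Exhaustive two-sided permutation p-value for the rank-sum test."""
    pooled = np.asarray(list(x) + list(y), float)
    ranks = stats.rankdata(pooled)
    nx, ny = len(x), len(y)
    center = nx * ny / 2.0
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    dev = abs(u_obs - center)
    hits = total = 0
    for idx in combinations(range(nx + ny), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        hits += abs(u - center) >= dev - 1e-12
        total += 1
    return hits / total


class TestRankSum:
    def test_worked_example(self):
        u, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _u, p = ranksum_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0
        _u, p = ranksum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            vals = rng.permutation(100)[:nx + ny].astype(float)
            x, y = vals[:nx], vals[nx:]
            u, p = ranksum_test(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_permutation_with_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            nx = int(rng.integers(1, 6))
            ny = int(rng.integers(1, 6))
            x = rng.integers(0, 4, nx).astype(float)
            y = rng.integers(0, 4, ny).astype(float)
            if len(set(x) | set(y)) == 1:
                continue
            _u, p = ranksum_test(x, y)
            assert p == pytest.approx(permutation_oracle(x, y), abs=1e-12)

    def test_large_sample_close_to_exact_at_n12(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(loc=0.5, size=7)   # combined n=13: approx branch
            _u, p_approx = ranksum_test(list(x), list(y))
            p_exact = permutation_oracle(list(x), list(y))
            assert abs(p_approx - p_exact) < 0.02
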