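"""piRNA sequence signatures.

Length spectra, positional base composition (1U/10A), 5'-end maps, the
ping-pong 5'-5' overlap histogram and its Z-score, per-family strand bias,
and oxidation enrichment.

The ping-pong signal is an excess of read pairs on opposite genomic strands
whose 5' ends overlap by exactly 10 nt — the geometric footprint of
reciprocal PIWI cleavage.  The Z-score compares the 10-nt overlap mass
against the 1-9 and 11-19 nt overlaps as background.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .align import AlignmentSet
from .annotation import FeatureIndex, FeatureSet
from .classify import ClassifiedReads, SHORT_LONG_BOUNDARY

#: Overlap distances used as the Z-score background (10 is the signal).
BACKGROUND_DISTANCES = tuple(d for d in range(1, 20) if d != 10)

#: One-sided normal threshold for calling a Z-score significant (alpha=0.05).
Z_SIGNIFICANCE = 1.645


# ---------------------------------------------------------------------------
# length spectrum

@dataclass
class LengthSpectrum:
    """Summed read weight per (length, class) bin over 18-30 nt."""

    table: dict[str, dict[int, float]]

    def mode(self, klass: str) -> Optional[int]:
        row = self.table.get(klass)
        if not row or not any(row.values()):
            return None
        return max(sorted(row), key=lambda ln: row[ln])

    def total(self) -> float:
        return sum(w for row in self.table.values() for w in row.values())

    def length_totals(self) -> dict[int, float]:
        out: dict[int, float] = defaultdict(float)
        for row in self.table.values():
            for ln, w in row.items():
                out[ln] += w
        return dict(out)

    def long_fraction(self, boundary: int = SHORT_LONG_BOUNDARY) -> float:
        """Weight fraction of reads longer than ``boundary`` nt."""
        totals = self.length_totals()
        tot = sum(totals.values())
        if tot == 0:
            return 0.0
        return sum(w for ln, w in totals.items() if ln > boundary) / tot


def length_spectrum(cr: ClassifiedReads, min_len: int = 18,
                    max_len: int = 30) -> LengthSpectrum:
    """Bin mapped read weight by (length, annotation class)."""
    table: dict[str, dict[int, float]] = {}
    for rid, klass in cr.read_class.items():
        if klass == "unmapped":
            continue
        read = cr.alignments.reads[rid]
        ln = len(read.seq)
        if not (min_len <= ln <= max_len):
            continue
        table.setdefault(klass, {ln: 0.0 for ln in range(min_len, max_len + 1)})
        table[klass][ln] += read.count
    return LengthSpectrum(table)


# ---------------------------------------------------------------------------
# base composition

@dataclass
class PositionBaseMatrix:
    """Position (1..max_pos) x base {A,C,G,U} frequency matrix.

    Row p is computed over reads of length >= p, weighted by read count;
    each populated row sums to 1.
    """

    freq: np.ndarray        # shape (max_pos, 4), ordered A,C,G,U
    n_reads: float
    bases = ("A", "C", "G", "U")

    def fraction(self, position: int, base: str) -> float:
        """Frequency of ``base`` (U == T) at 1-based ``position``."""
        j = self.bases.index("U" if base == "T" else base)
        return float(self.freq[position - 1, j])


_BASE_COL = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def base_composition(reads, max_pos: int = 30):
    """Positional base composition plus the 1U and 10A headline fractions.

    Returns ``(matrix, first_u, tenth_a)``.  T is reported as U.
    """
    counts = np.zeros((max_pos, 4))
    n = 0.0
    for r in reads:
        w = getattr(r, "count", 1)
        n += w
        for p, b in enumerate(r.seq[:max_pos]):
            counts[p, _BASE_COL[b]] += w
    if n == 0:
        raise ValueError("no reads for base composition")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    mat = PositionBaseMatrix(freq, n)
    first_u = mat.fraction(1, "U")
    tenth_a = mat.fraction(10, "A") if max_pos >= 10 else float("nan")
    return mat, first_u, tenth_a


# ---------------------------------------------------------------------------
# 5' end maps and overlap histogram

class FivePrimeMap:
    """Apportioned read weight keyed by (contig, strand, 5' position)."""

    def __init__(self) -> None:
        # contig -> strand -> pos -> weight
        self._m: dict[str, dict[str, dict[int, float]]] = {}

    def add(self, contig: str, strand: str, pos: int, weight: float) -> None:
        self._m.setdefault(contig, {"+": {}, "-": {}})
        d = self._m[contig][strand]
        d[pos] = d.get(pos, 0.0) + weight

    def contigs(self) -> list[str]:
        return sorted(self._m)

    def strand_map(self, contig: str, strand: str) -> dict[int, float]:
        return self._m.get(contig, {}).get(strand, {})

    def total(self) -> float:
        return sum(w for c in self._m.values() for s in c.values()
                   for w in s.values())

    def shifted(self, offset: int) -> "FivePrimeMap":
        out = FivePrimeMap()
        for c, strands in self._m.items():
            for s, d in strands.items():
                for p, w in d.items():
                    out.add(c, s, p + offset, w)
        return out


def five_prime_map(weighted_placements) -> FivePrimeMap:
    """Build a 5'-end weight map from (placement, weight) pairs.

    Plus-strand placements contribute at ``start``; minus-strand at
    ``end - 1``.
    """
    fpm = FivePrimeMap()
    for placement, w in weighted_placements:
        fpm.add(placement.contig, placement.strand, placement.five_prime, w)
    return fpm


def alignment_five_prime_map(aln: AlignmentSet) -> FivePrimeMap:
    return five_prime_map((p, w) for _r, p, w in aln.iter_weighted())


@dataclass
class OverlapHistogram:
    """Weighted pair mass c_d at 5'-5' overlap distances d = 1..dmax."""

    counts: dict[int, float]
    dmax: int = 20

    def __getitem__(self, d: int) -> float:
        return self.counts.get(d, 0.0)


def overlap_histogram(fpm: FivePrimeMap, dmax: int = 20,
                      pair_weight: str = "product") -> OverlapHistogram:
    """Pair mass per 5'-5' overlap distance between opposite-strand reads.

    A plus-strand 5' end at p and a minus-strand 5' end at p+d-1 overlap by
    d nt (d=10 is the ping-pong distance; d=1 is exact 5' coincidence).
    Pair mass is the product of the apportioned 5'-end weights by default;
    ``pair_weight="min"`` uses the smaller of the two.
    """
    if pair_weight not in ("product", "min"):
        raise ValueError(f"unknown pair weighting {pair_weight!r}")
    counts = {d: 0.0 for d in range(1, dmax + 1)}
    for contig in fpm.contigs():
        plus = fpm.strand_map(contig, "+")
        minus = fpm.strand_map(contig, "-")
        if not plus or not minus:
            continue
        for p, wp in plus.items():
            for d in range(1, dmax + 1):
                wm = minus.get(p + d - 1)
                if wm is not None:
                    counts[d] += wp * wm if pair_weight == "product" \
                        else min(wp, wm)
    return OverlapHistogram(counts, dmax)


@dataclass
class PingPongResult:
    """Z-score of the 10-nt overlap against the 1-9/11-19 background."""

    z: float
    c10: float
    bg_mean: float
    bg_sd: float
    n_pairs: float
    valid: bool

    @property
    def significant(self) -> bool:
        return self.valid and self.z >= Z_SIGNIFICANCE


def pingpong_z(hist: OverlapHistogram) -> PingPongResult:
    """Z = (c10 - mean) / sd over the 18 background distances (sample SD,
    divisor 17).  A zero-variance background yields ``valid=False``."""
    bg = [hist[d] for d in BACKGROUND_DISTANCES]
    mu = sum(bg) / len(bg)
    ss = sum((b - mu) ** 2 for b in bg)
    sd = math.sqrt(ss / (len(bg) - 1))
    c10 = hist[10]
    n_pairs = sum(hist.counts.values())
    if sd == 0:
        return PingPongResult(float("nan"), c10, mu, sd, n_pairs, False)
    return PingPongResult((c10 - mu) / sd, c10, mu, sd, n_pairs, True)


def _family_filter(aln: AlignmentSet, index: FeatureIndex,
                   overlap_frac: float = 0.5):
    """Yield (family, placement, weight) for transposon-overlapping
    placements (majority-overlap rule); a placement overlapping several
    copies of one family is attributed once."""
    for _read, p, w in aln.iter_weighted():
        need = overlap_frac * (p.end - p.start)
        fams = set()
        for f in index.overlapping(p.contig, p.start, p.end):
            if f.klass != "transposon":
                continue
            if min(p.end, f.end) - max(p.start, f.start) >= need:
                fams.add((f.family, f.strand))
        for fam, fstrand in sorted(fams):
            yield fam, fstrand, p, w


def pingpong_by_family(aln: AlignmentSet, features: FeatureSet,
                       index: Optional[FeatureIndex] = None,
                       dmax: int = 20,
                       pair_weight: str = "product") -> dict[str, PingPongResult]:
    """Ping-pong Z-score per transposon family plus an ``overall`` entry.

    Per-family scores pair only placements overlapping that family's copies;
    the overall score pairs all placements, so cross-family pairs count only
    toward it.
    """
    if index is None:
        index = features.build_index()
    maps: dict[str, FivePrimeMap] = defaultdict(FivePrimeMap)
    seen_fams = set()
    for fam, _fs, p, w in _family_filter(aln, index):
        maps[fam].add(p.contig, p.strand, p.five_prime, w)
        seen_fams.add(fam)
    out: dict[str, PingPongResult] = {}
    for fam in sorted(seen_fams):
        out[fam] = pingpong_z(overlap_histogram(maps[fam], dmax, pair_weight))
    out["overall"] = pingpong_z(
        overlap_histogram(alignment_five_prime_map(aln), dmax, pair_weight))
    return out


# ---------------------------------------------------------------------------
# strand bias

@dataclass
class StrandBias:
    """Per-family sense/antisense weight, with a per-read-length split."""

    sense: dict[str, float] = field(default_factory=dict)
    antisense: dict[str, float] = field(default_factory=dict)
    # family -> length -> (sense, antisense)
    by_length: dict[str, dict[int, tuple[float, float]]] = \
        field(default_factory=dict)

    def antisense_fraction(self, family: str) -> float:
        tot = self.sense.get(family, 0.0) + self.antisense.get(family, 0.0)
        if tot == 0:
            return float("nan")
        return self.antisense.get(family, 0.0) / tot

    def overall_antisense_fraction(self) -> float:
        s = sum(self.sense.values())
        a = sum(self.antisense.values())
        if s + a == 0:
            return float("nan")
        return a / (s + a)


def strand_bias(aln: AlignmentSet, features: FeatureSet,
                index: Optional[FeatureIndex] = None) -> StrandBias:
    """Sense/antisense apportioned weight per transposon family.

    A placement is sense when its genomic strand equals the annotated strand
    of the element copy it overlaps.
    """
    if index is None:
        index = features.build_index()
    sb = StrandBias()
    for fam, fstrand, p, w in _family_filter(aln, index):
        ln = p.end - p.start
        sb.by_length.setdefault(fam, {})
        s, a = sb.by_length[fam].get(ln, (0.0, 0.0))
        if p.strand == fstrand:
            sb.sense[fam] = sb.sense.get(fam, 0.0) + w
            sb.by_length[fam][ln] = (s + w, a)
        else:
            sb.antisense[fam] = sb.antisense.get(fam, 0.0) + w
            sb.by_length[fam][ln] = (s, a + w)
    return sb


# ---------------------------------------------------------------------------
# oxidation enrichment

@dataclass
class OxidationEnrichment:
    """Composition-fraction ratios oxidised/untreated.

    2'-O-methylated 3' termini resist periodate oxidation, so piRNAs survive
    the treatment while miRNAs and degradation fragments drop out; class and
    length enrichment ratios quantify that shift.  ``inf`` marks classes
    absent from the untreated library.
    """

    class_ratio: dict[str, float]
    length_ratio: dict[int, float]
    oxidized_long_fraction: float
    untreated_long_fraction: float


def oxidation_enrichment(untreated: ClassifiedReads,
                         oxidized: ClassifiedReads) -> OxidationEnrichment:
    """Ratio of class/length composition fractions between an oxidised and
    an untreated library, plus the >23 nt read fraction of each."""

    def _class_fracs(cr: ClassifiedReads) -> dict[str, float]:
        tot = sum(cr.class_weight.values())
        return {c: (w / tot if tot else 0.0)
                for c, w in cr.class_weight.items()}

    def _length_fracs(cr: ClassifiedReads) -> dict[int, float]:
        out: dict[int, float] = defaultdict(float)
        tot = 0.0
        for rid, klass in cr.read_class.items():
            if klass == "unmapped":
                continue
            r = cr.alignments.reads[rid]
            out[len(r.seq)] += r.count
            tot += r.count
        return {ln: w / tot for ln, w in out.items()} if tot else {}

    fu, fo = _class_fracs(untreated), _class_fracs(oxidized)
    class_ratio = {}
    for c in sorted(set(fu) | set(fo)):
        if fu.get(c, 0.0) == 0.0:
            class_ratio[c] = float("inf") if fo.get(c, 0.0) > 0 else 0.0
        else:
            class_ratio[c] = fo.get(c, 0.0) / fu[c]
    lu, lo = _length_fracs(untreated), _length_fracs(oxidized)
    length_ratio = {}
    for ln in sorted(set(lu) | set(lo)):
        if lu.get(ln, 0.0) == 0.0:
            length_ratio[ln] = float("inf") if lo.get(ln, 0.0) > 0 else 0.0
        else:
            length_ratio[ln] = lo.get(ln, 0.0) / lu[ln]

    def _long_frac(fr: dict[int, float]) -> float:
        return sum(v for ln, v in fr.items() if ln > SHORT_LONG_BOUNDARY)

    return OxidationEnrichment(class_ratio, length_ratio,
                               _long_frac(lo), _long_frac(lu))
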