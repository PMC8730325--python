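"""Perfect-match read placement and multi-mapper apportionment.

Small-RNA reads are retained only when they match the genome exactly; a read
matching n loci (over both strands) is apportioned with weight count/n per
locus, so abundance mass is conserved per read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A (possibly collapsed) small-RNA read.

    ``count`` is the number of identical raw reads collapsed into this
    record; ``methylated`` is a simulator truth flag carried through for
    oxidation modelling and is ignored by the analysis proper.
    """

    read_id: str
    seq: str
    count: int = 1
    methylated: Optional[bool] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Placement:
    """One perfect-match locus of a read (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' end (end-1 on the minus strand)."""
        return self.start if self.strand == "+" else self.end - 1


class AlignmentSet:
    """Placements per read plus library totals.

    Each mapped read's count is split uniformly over its placements
    (weight = count / n_placements), so the summed placement weight of a
    mapped read equals its count.
    """

    def __init__(self) -> None:
        self.reads: dict[str, ReadRecord] = {}
        self.placements: dict[str, list[Placement]] = {}
        self.total_count: int = 0
        self.mapped_count: int = 0

    def add(self, read: ReadRecord, placements: list[Placement]) -> None:
        if read.read_id in self.reads:
            raise ValueError(f"duplicate read id {read.read_id!r}")
        self.reads[read.read_id] = read
        self.placements[read.read_id] = placements
        self.total_count += read.count
        if placements:
            self.mapped_count += read.count

    def weight(self, read_id: str) -> float:
        """Per-placement weight for one read (count / n placements)."""
        n = len(self.placements[read_id])
        return self.reads[read_id].count / n

    def iter_weighted(self) -> Iterable[tuple[ReadRecord, Placement, float]]:
        """Yield (read, placement, weight) for every placement."""
        for rid, places in self.placements.items():
            if not places:
                continue
            read = self.reads[rid]
            w = read.count / len(places)
            for p in places:
                yield read, p, w

    def mapped_weight(self) -> float:
        return float(sum(r.count for rid, r in self.reads.items()
                         if self.placements[rid]))

    def subset(self, read_ids: Iterable[str]) -> "AlignmentSet":
        """A new AlignmentSet restricted to the given read ids."""
        out = AlignmentSet()
        for rid in read_ids:
            out.add(self.reads[rid], self.placements[rid])
        return out


def collapse_reads(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Collapse identical sequences into single records with summed counts.

    Identical sequences have identical placements, so mapping is done once
    per unique sequence.  The collapsed id is ``seq@<first id>``; member ids
    are not retained.
    """
    by_seq: dict[str, ReadRecord] = {}
    order: list[str] = []
    for r in reads:
        if r.seq in by_seq:
            by_seq[r.seq].count += r.count
        else:
            by_seq[r.seq] = ReadRecord(f"u{len(order)}", r.seq, r.count,
                                       r.methylated)
            order.append(r.seq)
    return [by_seq[s] for s in order]


class ExactIndex:
    """Hash index of all genomic seed_len-mers supporting exhaustive
    perfect-match lookup on both strands.

    Only the forward strand is indexed; minus-strand hits are found by
    looking up the reverse complement of the query.
    """

    def __init__(self, genome, seed_len: int = 18) -> None:
        self.genome = genome
        self.seed_len = seed_len
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name in genome.contigs:
            seq = genome.contigs[name]
            k = seed_len
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i:i + k], []).append((name, i))

    def find_all(self, seq: str) -> list[Placement]:
        """All perfect full-length placements of ``seq``, both strands."""
        if len(seq) < self.seed_len:
            raise ValueError(
                f"read length {len(seq)} < seed length {self.seed_len}")
        if set(seq) - set("ACGT"):
            return []
        hits: list[Placement] = []
        L = len(seq)
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            for contig, pos in self._seeds.get(query[:self.seed_len], ()):
                if self.genome.contigs[contig][pos:pos + L] == query:
                    hits.append(Placement(contig, pos, pos + L, strand))
        hits.sort(key=lambda p: (p.contig, p.start, p.strand))
        return hits


def map_reads(reads: Iterable[ReadRecord], index: ExactIndex,
              max_hits: Optional[int] = None) -> AlignmentSet:
    """Place every read at all of its perfect-match loci; reads with zero
    hits are retained as unmapped (they count toward library totals).

    ``max_hits`` optionally discards reads exceeding that many placements
    (they become unmapped), mirroring aligner hit caps; by default all
    placements are kept so apportionment stays exact.
    """
    aln = AlignmentSet()
    for read in reads:
        places = index.find_all(read.seq)
        if max_hits is not None and len(places) > max_hits:
            places = []
        aln.add(read, places)
    return aln


def mapped_fraction(aln: AlignmentSet) -> float:
    """Fraction of reads (by count, not placements) that mapped."""
    if aln.total_count == 0:
        raise ValueError("empty alignment set")
    return aln.mapped_count / aln.total_count


def import_alignments(path: str, fmt: str = "sam") -> AlignmentSet:
    """Import external alignments (SAM/BAM or the internal TSV dialect).

    Only ungapped, full-length, mismatch-free records are kept; gapped or
    soft-clipped records and records with NM>0 are skipped with a warning.
    Multi-mapping groups are reconstituted by read id.
    """
    if fmt in ("sam", "bam"):
        groups: dict[str, tuple[str, int, list[Placement]]] = {}
        dropped = 0
        mode = "rb" if fmt == "bam" else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    seq = rec.query_sequence or ""
                    groups.setdefault(rec.query_name, (seq, 1, []))
                    continue
                cigar = rec.cigartuples or []
                gapless = len(cigar) == 1 and cigar[0][0] == 0
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                if not gapless or nm != 0:
                    dropped += 1
                    groups.setdefault(rec.query_name,
                                      (rec.query_sequence or "", 1, []))
                    continue
                seq = rec.query_sequence or ""
                if rec.is_reverse:
                    seq = revcomp(seq)
                strand = "-" if rec.is_reverse else "+"
                start = rec.reference_start
                entry = groups.setdefault(rec.query_name, (seq, 1, []))
                entry[2].append(Placement(rec.reference_name, start,
                                          start + rec.query_length, strand))
        if dropped:
            log.warning("%d gapped/clipped/mismatched records dropped", dropped)
        aln = AlignmentSet()
        for qname in groups:
            seq, count, places = groups[qname]
            aln.add(ReadRecord(qname, seq, count), places)
        return aln
    if fmt == "tsv":
        return _read_tsv_alignments(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def write_tsv_alignments(aln: AlignmentSet, path: str) -> None:
    """Internal TSV alignment dialect:
    read_id seq count contig start strand n_hits weight (unmapped rows have
    '.' placement fields)."""
    with open(path, "w") as fh:
        fh.write("read_id\tseq\tcount\tcontig\tstart\tstrand\tn_hits\tweight\n")
        for rid, read in aln.reads.items():
            places = aln.placements[rid]
            if not places:
                fh.write(f"{rid}\t{read.seq}\t{read.count}\t.\t.\t.\t0\t0\n")
                continue
            n = len(places)
            w = read.count / n
            for p in places:
                fh.write(f"{rid}\t{read.seq}\t{read.count}\t{p.contig}"
                         f"\t{p.start}\t{p.strand}\t{n}\t{w:.6g}\n")


def _read_tsv_alignments(path: str) -> AlignmentSet:
    aln = AlignmentSet()
    current: Optional[str] = None
    read: Optional[ReadRecord] = None
    places: list[Placement] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("missing TSV alignment header")
        for line in fh:
            rid, seq, count, contig, start, strand, _n, _w = \
                line.rstrip("\n").split("\t")
            if rid != current:
                if read is not None:
                    aln.add(read, places)
                current = rid
                read = ReadRecord(rid, seq, int(count))
                places = []
            if contig != ".":
                s = int(start)
                places.append(Placement(contig, s, s + len(seq), strand))
    if read is not None:
        aln.add(read, places)
    return aln
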