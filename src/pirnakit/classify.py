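"""Adapter trimming, size selection, read annotation, piRNA candidate
selection, and ppm normalisation.

Classification is hierarchical: structural ncRNA (rRNA/tRNA/snRNA/snoRNA/
other) takes priority over miRNA, then transposon, then genic, then
unannotated.  piRNA abundance is quantified in parts per million of the
genome-mapping reads after excluding structural ncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import AlignmentSet, Placement, ReadRecord
from .annotation import FeatureIndex, NCRNA_CLASSES

log = logging.getLogger(__name__)

#: Read classes from highest to lowest annotation priority.
CLASS_PRIORITY = ("other_ncRNA", "miRNA", "transposon", "genic", "unannotated")
_PRIORITY_RANK = {c: i for i, c in enumerate(CLASS_PRIORITY)}

#: Genic feature classes (gene bodies and their sub-features).
_GENIC_CLASSES = {"gene", "five_utr", "cds", "three_utr", "intron"}

MIN_READ_LEN = 18
MAX_READ_LEN = 30
#: Size-partition boundary: reads <= 23 nt are "short", > 23 nt "long".
SHORT_LONG_BOUNDARY = 23


def trim_adapter(reads: Iterable[ReadRecord], adapter: str,
                 min_overlap: int = 6,
                 min_len: int = MIN_READ_LEN,
                 max_len: int = MAX_READ_LEN) -> list[ReadRecord]:
    """Remove a 3' adapter and size-select to [min_len, max_len].

    The longest read suffix exactly matching an adapter prefix of length
    >= ``min_overlap`` is removed.  Reads outside the size window after
    trimming are discarded (counts logged).
    """
    if not adapter:
        log.warning("empty adapter sequence; trimming skipped")
        adapter = ""
    kept: list[ReadRecord] = []
    discarded = 0
    for r in reads:
        seq = r.seq
        if adapter:
            best = 0
            limit = min(len(seq), len(adapter))
            for k in range(limit, min_overlap - 1, -1):
                if seq.endswith(adapter[:k]):
                    best = k
                    break
            if best:
                seq = seq[:-best]
        if min_len <= len(seq) <= max_len:
            kept.append(ReadRecord(r.read_id, seq, r.count, r.methylated))
        else:
            discarded += r.count
    if discarded:
        log.info("size selection discarded %d reads outside %d-%d nt",
                 discarded, min_len, max_len)
    return kept


def _placement_class(placement: Placement, index: FeatureIndex,
                     overlap_frac: float,
                     rank_of: dict[str, int] = _PRIORITY_RANK) -> str:
    """Annotation class of one placement under the majority-overlap rule."""
    read_len = placement.end - placement.start
    need = overlap_frac * read_len
    best = "unannotated"
    for f in index.overlapping(placement.contig, placement.start, placement.end):
        ov = min(placement.end, f.end) - max(placement.start, f.start)
        if ov < need:
            continue
        if f.klass in NCRNA_CLASSES:
            k = "other_ncRNA"
        elif f.klass == "miRNA":
            k = "miRNA"
        elif f.klass == "transposon":
            k = "transposon"
        elif f.klass in _GENIC_CLASSES:
            k = "genic"
        else:
            continue
        if rank_of[k] < rank_of[best]:
            best = k
    return best


@dataclass
class ClassifiedReads:
    """Per-read annotation classes with aggregate weights.

    ``denominator`` is mapped weight minus structural-ncRNA weight: the ppm
    normalisation base.
    """

    alignments: AlignmentSet
    read_class: dict[str, str] = field(default_factory=dict)
    class_weight: dict[str, float] = field(default_factory=dict)

    @property
    def mapped_weight(self) -> float:
        return self.alignments.mapped_weight()

    @property
    def denominator(self) -> float:
        return self.mapped_weight - self.class_weight.get("other_ncRNA", 0.0)

    def read_ids(self, klass: str) -> list[str]:
        return [rid for rid, c in self.read_class.items() if c == klass]

    def size_partition(self, rid: str) -> str:
        return ("short" if len(self.alignments.reads[rid].seq)
                <= SHORT_LONG_BOUNDARY else "long")


def annotate_reads(aln: AlignmentSet, index: FeatureIndex,
                   overlap_frac: float = 0.5,
                   priority: tuple[str, ...] = CLASS_PRIORITY
                   ) -> ClassifiedReads:
    """Assign each mapped read its highest-priority placement class.

    A placement is attributed to a feature only when at least
    ``overlap_frac`` of the read lies inside it.  Unmapped reads get class
    ``unmapped``.  ``priority`` reorders the class hierarchy (it must be a
    permutation of the default).
    """
    if sorted(priority) != sorted(CLASS_PRIORITY):
        raise ValueError("priority must be a permutation of "
                         f"{CLASS_PRIORITY}")
    rank_of = {c: i for i, c in enumerate(priority)}
    cr = ClassifiedReads(aln)
    weights = {c: 0.0 for c in CLASS_PRIORITY}
    for rid, places in aln.placements.items():
        if not places:
            cr.read_class[rid] = "unmapped"
            continue
        klass = min((_placement_class(p, index, overlap_frac, rank_of)
                     for p in places), key=rank_of.__getitem__)
        cr.read_class[rid] = klass
        weights[klass] += aln.reads[rid].count
    cr.class_weight = weights
    return cr


def select_pirna_candidates(cr: ClassifiedReads,
                            min_pirna_len: int = 24) -> AlignmentSet:
    """piRNA candidates: reads of at least ``min_pirna_len`` nt that are
    neither miRNA nor structural ncRNA (nor unmapped).

    The default of 24 nt follows the >23 nt size partition; 23 (reads longer
    than 22 nt) is the permissive alternative.
    """
    keep = [rid for rid, klass in cr.read_class.items()
            if klass not in ("miRNA", "other_ncRNA", "unmapped")
            and len(cr.alignments.reads[rid].seq) >= min_pirna_len]
    return cr.alignments.subset(keep)


def normalize_ppm(cr: ClassifiedReads, subset_weight: float) -> float:
    """Parts-per-million of ``subset_weight`` relative to the library's
    ncRNA-excluded mapped weight."""
    d = cr.denominator
    if d <= 0:
        raise ValueError("ppm denominator is zero")
    return 1e6 * subset_weight / d


def class_ppm_table(cr: ClassifiedReads) -> dict[str, float]:
    """ppm per annotation class (ncRNA reads excluded from the denominator,
    so {miRNA, transposon, genic, unannotated} sum to 1e6)."""
    return {c: normalize_ppm(cr, cr.class_weight.get(c, 0.0))
            for c in ("miRNA", "transposon", "genic", "unannotated")}
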