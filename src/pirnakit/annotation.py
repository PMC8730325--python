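"""Genome and feature-annotation handling.

All coordinates are 0-based half-open internally; GFF3 (1-based closed) and
BED6 (0-based half-open) conventions are converted at the I/O boundary only.
Transposon families use a free-form two-level label ``superfamily/family``
(e.g. ``LTR/Gypsy``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: Feature classes recognised throughout the package.
FEATURE_CLASSES = {
    "gene", "five_utr", "cds", "three_utr", "intron", "transposon",
    "miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA",
}

#: Structural non-coding RNA classes excluded from the ppm denominator.
NCRNA_CLASSES = {"rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA"}

# GFF3 type names mapped onto the internal class vocabulary.
_GFF_TYPE_MAP = {
    "gene": "gene",
    "mrna": "gene",
    "five_prime_utr": "five_utr",
    "5utr": "five_utr",
    "five_utr": "five_utr",
    "cds": "cds",
    "three_prime_utr": "three_utr",
    "3utr": "three_utr",
    "three_utr": "three_utr",
    "intron": "intron",
    "transposon": "transposon",
    "transposable_element": "transposon",
    "mirna": "miRNA",
    "rrna": "rRNA",
    "trna": "tRNA",
    "snrna": "snRNA",
    "snorna": "snoRNA",
    "ncrna": "other_ncRNA",
    "other_ncrna": "other_ncRNA",
}

_ALLOWED_BASES = set("ACGTN")


@dataclass
class Genome:
    """Contig name -> uppercase DNA sequence (alphabet A/C/G/T/N)."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contigs)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Feature:
    """A strand-aware genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    klass: str
    family: Optional[str] = None
    parent: Optional[str] = None
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.klass == "transposon" and not self.family:
            raise ValueError("transposon feature requires a family label")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def superfamily(self) -> Optional[str]:
        if self.family is None:
            return None
        return self.family.split("/", 1)[0]


class FeatureSet:
    """An ordered collection of :class:`Feature` records."""

    def __init__(self, features: Iterable[Feature] = ()) -> None:
        self.features: list[Feature] = list(features)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def add(self, feature: Feature) -> None:
        self.features.append(feature)

    def by_class(self, klass: str) -> list[Feature]:
        return [f for f in self.features if f.klass == klass]

    def transposon_families(self) -> list[str]:
        return sorted({f.family for f in self.features
                       if f.klass == "transposon" and f.family})

    def build_index(self) -> "FeatureIndex":
        return FeatureIndex(self)


class FeatureIndex:
    """Per-contig interval index over features (intervaltree-backed)."""

    def __init__(self, features: Iterable[Feature]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, contig: str, start: int, end: int) -> list[Feature]:
        """All features overlapping [start, end) on ``contig``."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.end, f.klass, f.feature_id or ""))
        return hits


def read_fasta(path: str) -> Genome:
    """Load a multi-record FASTA. Sequences are uppercased (soft-masking is
    discarded); duplicate contig names or an empty file are hard errors."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id!r}")
        bad = set(seq) - _ALLOWED_BASES
        if bad:
            raise ValueError(f"contig {rec.id!r} has non-DNA characters {bad}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records in {path!r}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_annotation(path: str, dialect: str = "gff3") -> FeatureSet:
    """Read a GFF3 or BED6 annotation into a :class:`FeatureSet`.

    Coordinates are normalised to 0-based half-open (a GFF3 record with
    start=10, end=20 becomes start=9, end=20).  Records that are empty after
    normalisation are rejected with a warning; unrecognised types map to
    ``other_ncRNA`` with a warning.
    """
    if dialect not in ("gff3", "bed6"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    fs = FeatureSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) < 9:
                    log.warning("%s:%d: short GFF3 line skipped", path, lineno)
                    continue
                contig, _src, ftype, start1, end1, _score, strand, _phase, attr = cols[:9]
                start, end = int(start1) - 1, int(end1)
                attrs = _parse_gff_attributes(attr)
                klass = _GFF_TYPE_MAP.get(ftype.lower())
                if klass is None:
                    log.warning("%s:%d: unknown feature type %r -> other_ncRNA",
                                path, lineno, ftype)
                    klass = "other_ncRNA"
                family = attrs.get("family")
                parent = attrs.get("Parent") or attrs.get("parent")
                fid = attrs.get("ID") or attrs.get("id")
            else:
                if len(cols) < 6:
                    log.warning("%s:%d: short BED6 line skipped", path, lineno)
                    continue
                contig, start0, end0, name, _score, strand = cols[:6]
                start, end = int(start0), int(end0)
                # BED name field carries "klass[:family[:parent]]"
                bits = name.split(":")
                klass = bits[0] if bits[0] in FEATURE_CLASSES else None
                if klass is None:
                    log.warning("%s:%d: unknown class %r -> other_ncRNA",
                                path, lineno, bits[0])
                    klass = "other_ncRNA"
                family = bits[1] if len(bits) > 1 and bits[1] else None
                parent = bits[2] if len(bits) > 2 and bits[2] else None
                fid = bits[3] if len(bits) > 3 and bits[3] else None
            if strand not in "+-":
                strand = "+"
            if end <= start:
                log.warning("%s:%d: empty interval after normalisation, skipped",
                            path, lineno)
                continue
            if klass == "transposon" and not family:
                family = "Unknown/Unknown"
            fs.add(Feature(contig, start, end, strand, klass,
                           family=family, parent=parent, feature_id=fid))
    return fs


def write_bed6(features: Iterable[Feature], path: str) -> None:
    """Write features as BED6; the name column round-trips class/family/parent."""
    with open(path, "w") as fh:
        for f in features:
            name = ":".join(x or "" for x in
                            (f.klass, f.family, f.parent, f.feature_id)).rstrip(":")
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def write_gff3(features: Iterable[Feature], path: str) -> None:
    _rev = {"gene": "gene", "five_utr": "five_prime_UTR", "cds": "CDS",
            "three_utr": "three_prime_UTR", "intron": "intron",
            "transposon": "transposon", "miRNA": "miRNA", "rRNA": "rRNA",
            "tRNA": "tRNA", "snRNA": "snRNA", "snoRNA": "snoRNA",
            "other_ncRNA": "ncRNA"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.feature_id:
                attrs.append(f"ID={f.feature_id}")
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            if f.family:
                attrs.append(f"family={f.family}")
            fh.write("\t".join([f.contig, "pirnakit", _rev[f.klass],
                                str(f.start + 1), str(f.end), ".", f.strand, ".",
                                ";".join(attrs) or "."]) + "\n")


@dataclass
class GeneModel:
    """A gene with ordered exonic 5'UTR / CDS / 3'UTR blocks and introns.

    Blocks are stored in genomic order; transcript order is obtained by
    reversing for minus-strand genes.  ``L5``/``Lc``/``L3`` are the summed
    region lengths in nucleotides.
    """

    gene_id: str
    contig: str
    strand: str
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def L5(self) -> int:
        return sum(e - s for s, e in self.five_utr)

    @property
    def Lc(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def L3(self) -> int:
        return sum(e - s for s, e in self.three_utr)

    @property
    def span(self) -> tuple[int, int]:
        blocks = self.five_utr + self.cds + self.three_utr
        return min(s for s, _ in blocks), max(e for _, e in blocks)

    def region_blocks(self, region: str) -> list[tuple[int, int]]:
        return {"five_utr": self.five_utr, "cds": self.cds,
                "three_utr": self.three_utr}[region]

    def region_length(self, region: str) -> int:
        return sum(e - s for s, e in self.region_blocks(region))


def _merge_blocks(blocks: list[tuple[int, int]], gene_id: str,
                  klass: str) -> list[tuple[int, int]]:
    """Sort and merge overlapping blocks of one sub-feature class."""
    blocks = sorted(blocks)
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s < merged[-1][1]:
            log.warning("gene %s: overlapping %s blocks merged", gene_id, klass)
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_gene_models(features: FeatureSet) -> list[GeneModel]:
    """Assemble :class:`GeneModel` objects from gene records and their
    five_utr/cds/three_utr children (linked via ``parent``).  Introns are the
    gaps between consecutive exonic blocks."""
    genes: dict[str, Feature] = {}
    for f in features:
        if f.klass == "gene" and f.feature_id:
            genes[f.feature_id] = f
    children: dict[str, dict[str, list[tuple[int, int]]]] = {
        gid: {"five_utr": [], "cds": [], "three_utr": []} for gid in genes}
    for f in features:
        if f.klass in ("five_utr", "cds", "three_utr") and f.parent:
            if f.parent not in children:
                raise ValueError(f"sub-feature parent {f.parent!r} unresolved")
            children[f.parent][f.klass].append((f.start, f.end))
    models: list[GeneModel] = []
    for gid in sorted(genes):
        g = genes[gid]
        parts = children[gid]
        m = GeneModel(
            gene_id=gid, contig=g.contig, strand=g.strand,
            five_utr=_merge_blocks(parts["five_utr"], gid, "five_utr"),
            cds=_merge_blocks(parts["cds"], gid, "cds"),
            three_utr=_merge_blocks(parts["three_utr"], gid, "three_utr"),
        )
        if not (m.five_utr or m.cds or m.three_utr):
            continue
        exonic = sorted(m.five_utr + m.cds + m.three_utr)
        m.introns = [(a[1], b[0]) for a, b in zip(exonic, exonic[1:])
                     if b[0] > a[1]]
        models.append(m)
    return models


#: Region lengths (5'UTR, CDS, 3'UTR) used when no gene models are supplied.
DEFAULT_REGION_LENGTHS = (350, 1000, 800)


def median_region_lengths(models: list[GeneModel]) -> tuple[float, float, float]:
    """Median 5'UTR/CDS/3'UTR lengths over gene models; zero-length regions
    are excluded from each median.  Falls back to the documented defaults
    (350, 1000, 800) when no nonzero regions exist."""

    def _median(values: list[int], default: float) -> float:
        values = [v for v in values if v > 0]
        if not values:
            log.warning("no nonzero region lengths; using default %s", default)
            return float(default)
        values.sort()
        n = len(values)
        mid = n // 2
        if n % 2:
            return float(values[mid])
        return (values[mid - 1] + values[mid]) / 2.0

    m5 = _median([m.L5 for m in models], DEFAULT_REGION_LENGTHS[0])
    mc = _median([m.Lc for m in models], DEFAULT_REGION_LENGTHS[1])
    m3 = _median([m.L3 for m in models], DEFAULT_REGION_LENGTHS[2])
    return (m5, mc, m3)
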