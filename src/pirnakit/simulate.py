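"""Synthetic genome, annotation and small-RNA library generator.

Emulates the statistical structure the analysis assumes: a bimodal read
length distribution (miRNA-like ~22 nt, piRNA-like ~27 nt), a strong 5'-U
bias and weaker 10-A signal, antisense bias toward transposon copies,
planted ping-pong pairs with exact 10-nt 5'-5' overlaps, genic piRNAs
enriched in 5'UTRs, multi-mapping reads from near-identical transposon
copies, and a periodate-oxidation treatment that removes species lacking a
3' 2'-O-methyl group.

Every read carries a truth row, and every read is an exact substring of the
genome (the 5'-U bias is realised by sampling start positions whose genomic
5' base is T, never by editing the read), so planted reads always re-map to
their origin under the perfect-match mapper.  All randomness flows from a
single seeded generator; a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .align import ReadRecord, revcomp
from .annotation import Feature, FeatureSet, Genome, write_fasta, write_gff3, \
    write_bed6

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_DEFAULT_FAMILIES = (
    "LTR/Gypsy", "LTR/Copia", "LINE/R1", "SINE/tRNA-like",
    "DNA/PIF-Harbinger", "DNA/Tc1-Mariner", "LINE/CR1", "LTR/Pao",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic library.

    Defaults target the observed features of somatic piRNA libraries:
    ~27 nt methylated piRNAs with p1U=0.85 first-uridine bias, 80% antisense
    to transposons, 30% participating in ping-pong pairs, genic piRNAs
    8-fold enriched per-nt in 5'UTRs, ~22 nt unmethylated miRNAs, and an
    oxidation step that removes 99% of unmethylated species.
    """

    seed: int = 0
    # genome
    genome_len: int = 500_000
    n_transposon_families: int = 6
    copies_per_family: int = 20
    copy_mutation_rate: float = 0.02
    consensus_len_range: tuple[int, int] = (600, 1500)
    n_genes: int = 60
    region_medians: tuple[int, int, int] = (350, 1000, 800)
    region_log_sigma: float = 0.5
    n_mirna_loci: int = 40
    n_rrna_loci: int = 3
    rrna_len: int = 1200
    # reads
    n_pirna: int = 50_000
    n_mirna: int = 20_000
    n_degradation: int = 5_000
    genic_frac: float = 0.55
    pingpong_frac: float = 0.3
    p1U: float = 0.85
    p10A_secondary: float = 0.7
    antisense_frac: float = 0.8
    pirna_len_mean: float = 27.0
    pirna_len_sd: float = 1.5
    pirna_len_range: tuple[int, int] = (24, 30)
    mirna_len_mean: float = 22.0
    mirna_len_sd: float = 0.8
    mirna_len_range: tuple[int, int] = (20, 23)
    utr5_enrichment: float = 8.0
    ox_kill_prob: float = 0.99
    #: per-read probability of one random substitution (plants unmappable
    #: reads for the mapped-fraction path); off by default.
    seq_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("genic_frac", "pingpong_frac", "p1U", "p10A_secondary",
                     "antisense_frac", "ox_kill_prob", "seq_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


_CONTIG = "sim1"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


class _Layout:
    """Non-overlapping interval placement with bounded rejection retries."""

    def __init__(self, genome_len: int, margin: int = 20) -> None:
        self.genome_len = genome_len
        self.margin = margin
        self._starts: list[int] = []
        self._ends: list[int] = []

    def place(self, rng: np.random.Generator, length: int,
              retries: int = 500) -> int:
        for _ in range(retries):
            s = int(rng.integers(0, self.genome_len - length))
            e = s + length
            i = bisect_left(self._starts, e + self.margin)
            if i > 0 and self._ends[i - 1] + self.margin > s:
                continue
            self._starts.insert(i, s)
            self._ends.insert(i, e)
            return s
        raise ValueError(
            "could not place features without overlap; increase genome_len")


def simulate_genome(config: SimConfig):
    """Build the synthetic genome and its annotation.

    Background sequence is i.i.d. uniform; transposon copies are mutated
    family consensus sequences inserted at non-overlapping positions on
    random strands (near-identical copies make their reads multi-map);
    genes (contiguous 5'UTR/CDS/3'UTR), miRNA loci and rRNA loci occupy
    transposon-free intervals.

    Returns ``(genome, features)``.
    """
    rng = np.random.default_rng(config.seed)
    seq = bytearray(_random_seq(rng, config.genome_len).encode())
    layout = _Layout(config.genome_len)
    features = FeatureSet()

    # genes are the largest features; placing them first keeps the free
    # space from fragmenting before they fit
    med5, medc, med3 = config.region_medians
    sig = config.region_log_sigma
    for gi in range(config.n_genes):
        L5 = max(30, int(round(rng.lognormal(np.log(med5), sig))))
        Lc = max(60, int(round(rng.lognormal(np.log(medc), sig))))
        L3 = max(30, int(round(rng.lognormal(np.log(med3), sig))))
        strand = "+" if rng.random() < 0.5 else "-"
        total = L5 + Lc + L3
        s = layout.place(rng, total)
        gid = f"g{gi:03d}"
        if strand == "+":
            blocks = [("five_utr", s, s + L5), ("cds", s + L5, s + L5 + Lc),
                      ("three_utr", s + L5 + Lc, s + total)]
        else:
            blocks = [("three_utr", s, s + L3), ("cds", s + L3, s + L3 + Lc),
                      ("five_utr", s + L3 + Lc, s + total)]
        features.add(Feature(_CONTIG, s, s + total, strand, "gene",
                             feature_id=gid))
        for klass, bs, be in blocks:
            features.add(Feature(_CONTIG, bs, be, strand, klass, parent=gid,
                                 feature_id=f"{gid}_{klass}"))

    fams = list(_DEFAULT_FAMILIES)
    while len(fams) < config.n_transposon_families:
        fams.append(f"Unknown/Fam{len(fams)}")
    fams = fams[:config.n_transposon_families]
    lo, hi = config.consensus_len_range
    for fi, fam in enumerate(fams):
        consensus = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for ci in range(config.copies_per_family):
            copy = _mutate(rng, consensus, config.copy_mutation_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            ins = copy if strand == "+" else revcomp(copy)
            s = layout.place(rng, len(ins))
            seq[s:s + len(ins)] = ins.encode()
            features.add(Feature(_CONTIG, s, s + len(ins), strand,
                                 "transposon", family=fam,
                                 feature_id=f"te{fi:02d}_{ci:03d}"))

    lo_m, hi_m = config.mirna_len_range
    for mi in range(config.n_mirna_loci):
        L = int(np.clip(round(rng.normal(config.mirna_len_mean,
                                         config.mirna_len_sd)), lo_m, hi_m))
        strand = "+" if rng.random() < 0.5 else "-"
        s = layout.place(rng, L)
        features.add(Feature(_CONTIG, s, s + L, strand, "miRNA",
                             feature_id=f"mir{mi:03d}"))
    for ri in range(config.n_rrna_loci):
        s = layout.place(rng, config.rrna_len)
        features.add(Feature(_CONTIG, s, s + config.rrna_len, "+", "rRNA",
                             feature_id=f"rrna{ri:02d}"))

    genome = Genome({_CONTIG: seq.decode()})
    return genome, features


_COMP = str.maketrans("ACGTN", "TGCAN")


def _read_seq(genome: Genome, contig: str, start: int, end: int,
              strand: str) -> str:
    s = genome.contigs[contig][start:end]
    return s if strand == "+" else revcomp(s)


def _five_prime_base(genome: Genome, contig: str, start: int, end: int,
                     strand: str) -> str:
    g = genome.contigs[contig]
    return g[start] if strand == "+" else g[end - 1].translate(_COMP)


def _draw_len(rng, mean, sd, lo, hi) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def simulate_reads(config: SimConfig, genome: Genome, features: FeatureSet):
    """Draw the small-RNA library and its truth table.

    Returns ``(reads, truth)`` where ``truth`` is a DataFrame with one row
    per read (label, source feature, coordinates, methylation, ping-pong
    partner).  Transposon piRNAs are drawn antisense with probability
    ``antisense_frac``; their 5' base is genomic T with probability exactly
    ``p1U`` (rejection-sampled positions).  A planted secondary partner —
    opposite strand, exact 10-nt 5'-5' overlap, inheriting the primary's
    cut site — accompanies a fraction ``pingpong_frac`` of primaries,
    chosen so that the secondaries' position-10 A frequency equals
    ``p10A_secondary``.  Genic piRNAs are sense reads with per-nt region
    weights utr5_enrichment:1:1 over 5'UTR:CDS:3'UTR.  miRNA reads copy
    their locus exactly; degradation fragments are uniform over gene spans;
    only piRNA-class reads are 2'-O-methylated.
    """
    rng = np.random.default_rng(config.seed + 1)
    copies = [f for f in features if f.klass == "transposon"]
    mirna_loci = [f for f in features if f.klass == "miRNA"]
    genes = [f for f in features if f.klass == "gene"]
    regions: dict[str, dict[str, Feature]] = {}
    for f in features:
        if f.klass in ("five_utr", "cds", "three_utr") and f.parent:
            regions.setdefault(f.parent, {})[f.klass] = f

    n_genic = int(round(config.n_pirna * config.genic_frac))
    n_tp = config.n_pirna - n_genic
    if n_tp and not copies:
        raise ValueError("transposon piRNAs requested but no copies present")
    if n_genic and not genes:
        raise ValueError("genic piRNAs requested but no genes present")
    if config.n_mirna and not mirna_loci:
        raise ValueError("miRNA reads requested but no miRNA loci present")

    reads: list[ReadRecord] = []
    rows: list[dict] = []
    counter = 0

    def _emit(seq, label, source, contig, start, end, strand, methylated,
              partner=None):
        nonlocal counter
        rid = f"r{counter:06d}"
        counter += 1
        if config.seq_error_rate and rng.random() < config.seq_error_rate:
            i = int(rng.integers(0, len(seq)))
            alt = [b for b in "ACGT" if b != seq[i]][rng.integers(0, 3)]
            seq = seq[:i] + alt + seq[i + 1:]
        reads.append(ReadRecord(rid, seq, 1, methylated))
        rows.append({"read_id": rid, "label": label, "source": source,
                     "contig": contig, "start": start, "end": end,
                     "strand": strand, "length": len(seq),
                     "methylated": methylated,
                     "partner": partner if partner else "."})
        return rid

    plo, phi = config.pirna_len_range
    f_pp, p1u, p10a = config.pingpong_frac, config.p1U, config.p10A_secondary
    contig_len = {c: len(s) for c, s in genome.contigs.items()}

    # transposon primaries (+ planted secondaries)
    for _ in range(n_tp):
        copy = copies[int(rng.integers(0, len(copies)))]
        antisense = rng.random() < config.antisense_frac
        strand = copy.strand if not antisense else ("-" if copy.strand == "+"
                                                    else "+")
        L = _draw_len(rng, config.pirna_len_mean, config.pirna_len_sd,
                      plo, phi)
        want_t = rng.random() < p1u
        start = None
        for _try in range(60):
            s = int(rng.integers(copy.start, copy.end - L + 1))
            if (_five_prime_base(genome, copy.contig, s, s + L, strand)
                    == "T") == want_t:
                start = s
                break
        if start is None:
            start = s
        end = start + L
        seq = _read_seq(genome, copy.contig, start, end, strand)
        pid = _emit(seq, "pirna_primary", copy.feature_id, copy.contig,
                    start, end, strand, True)
        # partner probability tilted by the primary's 5' base so that the
        # realised secondary 10-A frequency equals p10A_secondary
        if 0.0 < p1u < 1.0:
            p_pair = f_pp * (p10a / p1u if seq[0] == "T"
                             else (1 - p10a) / (1 - p1u))
        else:
            p_pair = f_pp
        if rng.random() < min(p_pair, 1.0):
            L2 = _draw_len(rng, config.pirna_len_mean, config.pirna_len_sd,
                           plo, phi)
            if strand == "+":
                s2, e2, strand2 = start + 10 - L2, start + 10, "-"
            else:
                s2, e2, strand2 = end - 10, end - 10 + L2, "+"
            if 0 <= s2 and e2 <= contig_len[copy.contig]:
                seq2 = _read_seq(genome, copy.contig, s2, e2, strand2)
                _emit(seq2, "pirna_secondary", copy.feature_id, copy.contig,
                      s2, e2, strand2, True, partner=pid)

    # genic piRNAs (sense, 5'UTR-enriched)
    e5 = config.utr5_enrichment
    for _ in range(n_genic):
        gene = genes[int(rng.integers(0, len(genes)))]
        regs = regions.get(gene.feature_id, {})
        names = [r for r in ("five_utr", "cds", "three_utr") if r in regs]
        wts = np.array([(e5 if r == "five_utr" else 1.0) * regs[r].length
                        for r in names])
        region = regs[names[int(rng.choice(len(names), p=wts / wts.sum()))]]
        L = _draw_len(rng, config.pirna_len_mean, config.pirna_len_sd,
                      plo, phi)
        want_t = rng.random() < p1u
        start = None
        for _try in range(60):
            g5 = int(rng.integers(region.start, region.end))
            s = g5 if gene.strand == "+" else g5 - L + 1
            if s < 0 or s + L > contig_len[gene.contig]:
                continue
            if (_five_prime_base(genome, gene.contig, s, s + L, gene.strand)
                    == "T") == want_t:
                start = s
                break
        if start is None:
            start = max(0, min(s, contig_len[gene.contig] - L))
        seq = _read_seq(genome, gene.contig, start, start + L, gene.strand)
        _emit(seq, "pirna_genic", gene.feature_id, gene.contig, start,
              start + L, gene.strand, True)

    # miRNAs: exact locus copies, unmethylated
    for _ in range(config.n_mirna):
        locus = mirna_loci[int(rng.integers(0, len(mirna_loci)))]
        seq = _read_seq(genome, locus.contig, locus.start, locus.end,
                        locus.strand)
        _emit(seq, "mirna", locus.feature_id, locus.contig, locus.start,
              locus.end, locus.strand, False)

    # mRNA degradation fragments: uniform over gene spans, unmethylated
    for _ in range(config.n_degradation):
        gene = genes[int(rng.integers(0, len(genes)))]
        L = int(rng.integers(18, 31))
        s = int(rng.integers(gene.start, max(gene.start + 1, gene.end - L)))
        seq = _read_seq(genome, gene.contig, s, s + L, gene.strand)
        _emit(seq, "degradation", gene.feature_id, gene.contig, s, s + L,
              gene.strand, False)

    truth = pd.DataFrame(rows)
    return reads, truth


def simulate_oxidation(reads: list[ReadRecord], ox_kill_prob: float,
                       seed: int) -> list[ReadRecord]:
    """Periodate-oxidation model: each unmethylated read is dropped
    independently with probability ``ox_kill_prob``; 2'-O-methylated reads
    always survive."""
    rng = np.random.default_rng(seed)
    out = []
    for r in reads:
        if r.methylated or rng.random() >= ox_kill_prob:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# FASTQ / bundle I/O

def write_fastq(reads, path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fastq(path: str) -> list[ReadRecord]:
    return [ReadRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(path, "fastq")]


@dataclass
class SimBundle:
    """File paths of one simulated data set."""

    genome: str
    gff3: str
    bed: str
    reads: str
    reads_ox: str
    truth: str
    config: str


def simulate_to_dir(config: SimConfig, outdir: str) -> SimBundle:
    """Run the full generator and write genome.fa / features.gff3 /
    features.bed / reads.fastq / reads_ox.fastq / truth.tsv /
    simconfig.yaml into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    genome, features = simulate_genome(config)
    reads, truth = simulate_reads(config, genome, features)
    ox = simulate_oxidation(reads, config.ox_kill_prob, config.seed + 2)
    b = SimBundle(
        genome=os.path.join(outdir, "genome.fa"),
        gff3=os.path.join(outdir, "features.gff3"),
        bed=os.path.join(outdir, "features.bed"),
        reads=os.path.join(outdir, "reads.fastq"),
        reads_ox=os.path.join(outdir, "reads_ox.fastq"),
        truth=os.path.join(outdir, "truth.tsv"),
        config=os.path.join(outdir, "simconfig.yaml"),
    )
    write_fasta(genome, b.genome)
    write_gff3(features, b.gff3)
    write_bed6(features, b.bed)
    write_fastq(reads, b.reads)
    write_fastq(ox, b.reads_ox)
    truth.to_csv(b.truth, sep="\t", index=False)
    with open(b.config, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return b
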