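"""End-to-end pipeline: trim -> map -> classify -> signatures -> metagene ->
quantify, driven by a single validated config, writing stage TSVs and an
aggregated ``report.json``.

The pipeline is a pure function of (inputs, config, seed): rerunning on the
same inputs produces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import math
import os
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import align, classify, expression, metagene, signatures
from .annotation import build_gene_models, read_annotation, read_fasta
from .simulate import read_fastq

log = logging.getLogger(__name__)


class SampleConfig(BaseModel):
    label: str
    fastq: str
    treatment: Literal["untreated", "oxidized"] = "untreated"


class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable)."""

    genome: str
    annotation: str
    annotation_dialect: Literal["gff3", "bed6"] = "gff3"
    samples: list[SampleConfig] = Field(min_length=1)
    outdir: str = "pirnakit_out"
    seed: int = 0
    adapter: Optional[str] = None
    seed_len: int = 18
    min_pirna_len: int = 24
    overlap_frac: float = 0.5
    pair_weight: Literal["product", "min"] = "product"
    metagene_bins: tuple[int, int, int] = (350, 1000, 800)

    @field_validator("genome", "annotation")
    @classmethod
    def _exists(cls, v: str) -> str:
        if not os.path.exists(v):
            raise ValueError(f"input path does not exist: {v}")
        return v

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _round(x: float, nd: int = 6) -> float:
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return x
    return round(float(x), nd)


def _process_sample(sample: SampleConfig, index, feat_index, features,
                    models, cfg: RunConfig, outdir: str) -> dict:
    os.makedirs(outdir, exist_ok=True)
    reads = read_fastq(sample.fastq)
    log.info("[%s] %d raw reads", sample.label, len(reads))
    if cfg.adapter:
        reads = classify.trim_adapter(reads, cfg.adapter)
        log.info("[%s] %d reads after trimming/size selection",
                 sample.label, len(reads))
    collapsed = align.collapse_reads(reads)
    aln = align.map_reads(collapsed, index)
    log.info("[%s] mapped %d/%d reads", sample.label, aln.mapped_count,
             aln.total_count)
    cr = classify.annotate_reads(aln, feat_index, cfg.overlap_frac)
    ppm = classify.class_ppm_table(cr)
    pirna = classify.select_pirna_candidates(cr, cfg.min_pirna_len)
    log.info("[%s] %d piRNA candidate sequences", sample.label,
             len(pirna.reads))

    spectrum = signatures.length_spectrum(cr)
    pirna_reads = list(pirna.reads.values())
    if pirna_reads:
        _mat, first_u, tenth_a = signatures.base_composition(pirna_reads)
    else:
        first_u = tenth_a = float("nan")
    pp = signatures.pingpong_by_family(pirna, features, feat_index,
                                       pair_weight=cfg.pair_weight)
    sb = signatures.strand_bias(pirna, features, feat_index)
    hist = signatures.overlap_histogram(
        signatures.alignment_five_prime_map(pirna),
        pair_weight=cfg.pair_weight)

    mapped_w = aln.mapped_weight()
    profile = metagene.scaled_profile(pirna, models, mapped_w,
                                      cfg.metagene_bins)
    rpkm = metagene.region_rpkm(pirna, models, mapped_w)
    tests = metagene.region_enrichment_tests(rpkm)
    expr = expression.quantify(aln, features, feat_index, cfg.overlap_frac)

    # stage TSVs
    pd.DataFrame(
        [{"class": c, "length": ln, "weight": w}
         for c, row in sorted(spectrum.table.items())
         for ln, w in sorted(row.items())]
    ).to_csv(os.path.join(outdir, "length_spectrum.tsv"), sep="\t",
             index=False)
    pd.DataFrame(
        [{"d": d, "pair_mass": _round(m)} for d, m in sorted(hist.counts.items())]
    ).to_csv(os.path.join(outdir, "overlap_histogram.tsv"), sep="\t",
             index=False)
    pd.DataFrame(
        [{"scope": fam, "z": _round(r.z), "c10": _round(r.c10),
          "mu": _round(r.bg_mean), "sigma": _round(r.bg_sd),
          "valid": r.valid} for fam, r in sorted(pp.items())]
    ).to_csv(os.path.join(outdir, "pingpong.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"family": fam, "sense": _round(sb.sense.get(fam, 0.0)),
          "antisense": _round(sb.antisense.get(fam, 0.0)),
          "antisense_fraction": _round(sb.antisense_fraction(fam))}
         for fam in sorted(set(sb.sense) | set(sb.antisense))]
    ).to_csv(os.path.join(outdir, "strand_bias.tsv"), sep="\t", index=False)
    profile.to_frame().to_csv(os.path.join(outdir, "metagene_profile.tsv"),
                              sep="\t", index=False, float_format="%.6g")
    rpkm.to_csv(os.path.join(outdir, "region_rpkm.tsv"), sep="\t",
                index=False, float_format="%.6g")
    tests.to_csv(os.path.join(outdir, "ranksum.tsv"), sep="\t", index=False,
                 float_format="%.6g")
    expr.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t",
                float_format="%.6g")

    peak_bin, peak_region, peak_orient = profile.peak()
    overall = pp["overall"]
    summary = {
        "raw_reads": len(reads),
        "mapped_fraction": _round(align.mapped_fraction(aln)),
        "class_ppm": {c: _round(v) for c, v in sorted(ppm.items())},
        "pirna_candidates": len(pirna.reads),
        "first_u": _round(first_u),
        "tenth_a": _round(tenth_a),
        "length_mode_mirna": spectrum.mode("miRNA"),
        "length_mode_pirna_long": spectrum.mode("transposon"),
        "long_fraction": _round(spectrum.long_fraction()),
        "pingpong_z_overall": _round(overall.z),
        "pingpong_z_by_family": {fam: _round(r.z) for fam, r in
                                 sorted(pp.items()) if fam != "overall"},
        "antisense_fraction_overall": _round(sb.overall_antisense_fraction()),
        "metagene_peak": {"bin": peak_bin, "region": peak_region,
                          "orientation": peak_orient},
        "utr5_vs_cds_p": _round(float(tests[tests.comparison ==
                                            "five_utr_vs_cds"]["p"].iloc[0]))
        if len(tests) else None,
    }
    return {"summary": summary, "classified": cr}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for every sample and write ``report.json``.

    When the sample set contains both an untreated and an oxidized library,
    oxidation enrichment is computed between the first of each.
    """
    os.makedirs(config.outdir, exist_ok=True)
    genome = read_fasta(config.genome)
    features = read_annotation(config.annotation, config.annotation_dialect)
    feat_index = features.build_index()
    models = build_gene_models(features)
    index = align.ExactIndex(genome, config.seed_len)

    report: dict = {"samples": {}}
    classified: dict[str, classify.ClassifiedReads] = {}
    for sample in config.samples:
        res = _process_sample(sample, index, feat_index, features, models,
                              config, os.path.join(config.outdir,
                                                   sample.label))
        report["samples"][sample.label] = res["summary"]
        classified[sample.label] = res["classified"]

    untreated = [s for s in config.samples if s.treatment == "untreated"]
    oxidized = [s for s in config.samples if s.treatment == "oxidized"]
    if untreated and oxidized:
        ox = signatures.oxidation_enrichment(
            classified[untreated[0].label], classified[oxidized[0].label])
        report["oxidation"] = {
            "untreated": untreated[0].label,
            "oxidized": oxidized[0].label,
            "class_ratio": {c: (_round(v) if math.isfinite(v) else str(v))
                            for c, v in sorted(ox.class_ratio.items())},
            "oxidized_long_fraction": _round(ox.oxidized_long_fraction),
            "untreated_long_fraction": _round(ox.untreated_long_fraction),
        }
    path = os.path.join(config.outdir, "report.json")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", path)
    return report
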