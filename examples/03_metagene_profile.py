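"""Scaled metagene profile of genic piRNAs.

Each gene's 5'UTR/CDS/3'UTR is rescaled to 350/1000/800 bins; genic piRNA
5' ends are placed into the scaled bins, normalised per gene, and averaged.
With the default 8-fold per-nt 5'UTR enrichment, the profile peaks in the
5'UTR in the sense orientation, and the Wilcoxon rank-sum test on per-gene
region RPKM confirms the enrichment.
"""

import pirnakit as pk
from pirnakit.simulate import SimConfig, simulate_genome, simulate_reads

cfg = SimConfig(seed=3, genome_len=150_000, n_transposon_families=2,
                copies_per_family=6, n_genes=20, n_pirna=8_000,
                n_mirna=500, n_degradation=200, utr5_enrichment=8.0)
genome, features = simulate_genome(cfg)
reads, _truth = simulate_reads(cfg, genome, features)

aln = pk.map_reads(pk.collapse_reads(reads), pk.ExactIndex(genome, 18))
cr = pk.annotate_reads(aln, features.build_index())
pirna = pk.select_pirna_candidates(cr)
models = pk.build_gene_models(features)

profile = pk.scaled_profile(pirna, models, aln.mapped_weight())
peak_bin, region, orient = profile.peak()
print(f"profile over {profile.n_genes} genes; "
      f"peak at bin {peak_bin} ({region}, {orient})")
print("mean scaled density per region (sense):")
for reg, mean in profile.region_means("sense").items():
    print(f"  {reg:10s} {mean:10.2f}")

rpkm = pk.region_rpkm(pirna, models, aln.mapped_weight())
tests = pk.region_enrichment_tests(rpkm)
print("\nrank-sum tests on per-gene region RPKM:")
print(tests.to_string(index=False))
top = pk.top_quartile_genes(rpkm)
print(f"\ntop-quartile piRNA-producing genes: {', '.join(top)}")
print("A peak inside bins 0-349 with a small five_utr_vs_cds p-value shows "
      "the sense-strand 5'UTR bias of genic piRNAs.")
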