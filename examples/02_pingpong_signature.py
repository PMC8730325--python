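"""Measure the ping-pong amplification signature.

Selects piRNA candidates (>23 nt, not miRNA/ncRNA), builds the 5'-5'
overlap histogram between opposite-strand read pairs, and reports the
Z-score of the 10-nt overlap — the footprint of reciprocal PIWI cleavage —
overall and per transposon family.
"""

import pirnakit as pk
from pirnakit.simulate import SimConfig, simulate_genome, simulate_reads

cfg = SimConfig(seed=2, genome_len=150_000, n_transposon_families=3,
                copies_per_family=8, n_genes=15, n_pirna=6_000,
                n_mirna=1_000, n_degradation=200, pingpong_frac=0.3)
genome, features = simulate_genome(cfg)
reads, _truth = simulate_reads(cfg, genome, features)

aln = pk.map_reads(pk.collapse_reads(reads), pk.ExactIndex(genome, 18))
cr = pk.annotate_reads(aln, features.build_index())
pirna = pk.select_pirna_candidates(cr)

hist = pk.overlap_histogram(pk.alignment_five_prime_map(pirna))
print("5'-5' overlap histogram (pair mass per distance):")
for d in range(1, 21):
    bar = "#" * int(60 * hist[d] / max(hist.counts.values()))
    print(f"  d={d:2d} {hist[d]:10.1f} {bar}")

for scope, res in sorted(pk.pingpong_by_family(pirna, features).items()):
    flag = "significant" if res.significant else "not significant"
    print(f"z({scope}) = {res.z:7.2f}  (c10={res.c10:.0f}, "
          f"bg {res.bg_mean:.1f}±{res.bg_sd:.1f}; {flag})")
print("\nA spike at d=10 and a large Z-score indicate that 30% of the "
      "planted piRNAs carry an exact-10-nt opposite-strand partner.")
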