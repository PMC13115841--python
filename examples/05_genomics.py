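"""Genomic annotation: band enrichment, 0.5 cM linkage windows, HAR overlap."""

import socionet as sn
from socionet import pipeline
from socionet.genomics import band_enrichment, har_overlap, linkage_neighbors

bench = sn.generate_benchmark(sn.BenchmarkConfig(seed=1))
inter = bench.build_interactome()
res = pipeline.analyze(inter, bench.seeds, bench.disease, n_perm=200, seed=1)
network = set(res.selected.genes)

bands = band_enrichment(network, bench.loci, set(inter.genes))
print("top cytogenetic bands:")
print(bands.head(3).to_string(index=False))
print(f"planted band was {bench.truth.expected_band}")

linked = linkage_neighbors(network, bench.disease, bench.loci,
                           window_bp=500_000)
print(f"\nnetwork genes within 0.5 cM of a disease gene: "
      f"{linked['network_gene'].nunique()}")

rep = har_overlap(network, bench.har, bench.disease)
in_har, in_har_not_disease, in_both = rep.counts
print(f"network genes in HARs: {in_har} "
      f"({in_har_not_disease} not already in the disease list)")
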