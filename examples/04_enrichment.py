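"""Pathway over-representation and meta-pathway clustering.

ORA: one hypergeometric test per pathway, BH-corrected. Meta-pathways:
significant pathways become nodes, edges connect pathways whose overlap
coefficient clears a threshold chosen to maximise fastgreedy modularity.
"""

import socionet as sn
from socionet import pipeline
from socionet.enrichment import meta_pathways, pathway_ora

bench = sn.generate_benchmark(sn.BenchmarkConfig(seed=1))
inter = bench.build_interactome()
res = pipeline.analyze(inter, bench.seeds, bench.disease, n_perm=200, seed=1)

table = pathway_ora(
    set(res.selected.genes), bench.pathways, set(inter.genes)
)
print(table.head(8)[["name", "k", "K", "p", "fdr"]].to_string(index=False))

meta = meta_pathways(table, bench.pathways)
print(f"\nmeta-pathways at threshold {meta.threshold:.2f} "
      f"(Q = {meta.pathway_network_q:.3f}):")
for name, cluster in sorted(meta.clusters.items()):
    print(f"  {name} -> meta {cluster}")
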