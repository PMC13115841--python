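"""Network diffusion on a toy graph, with the closed form checked by hand.

On a single edge a-b with seed x0 = (1, 0) and restart alpha, the resolvent
(1 - a)(I - aW)^(-1) x0 has the closed form (1-a)/(1-a^2) * (1, a).
"""

import numpy as np

import socionet as sn
from socionet.diffusion import diffuse, permutation_adjusted_index, seed_vector
from socionet.interactome import normalize_adjacency

inter = sn.Interactome(genes=("a", "b"), edges={("a", "b"): 900})
W = normalize_adjacency(inter)
alpha = 0.7

xs = diffuse(W, np.array([1.0, 0.0]), alpha)
closed = (1 - alpha) / (1 - alpha**2) * np.array([1.0, alpha])
print("solver :", np.round(xs, 6))
print("closed :", np.round(closed, 6))

# The same on a benchmark graph, now with the permutation-adjusted index.
bench = sn.generate_benchmark(sn.BenchmarkConfig(seed=1))
big = bench.build_interactome()
x0, dropped = seed_vector(big, bench.seeds)
res = permutation_adjusted_index(
    normalize_adjacency(big), big.genes, x0, n_perm=200, seed=1
)
table = res.to_frame().sort_values("S_tilde", ascending=False)
print("\ntop 5 genes by adjusted smoothing index:")
print(table.head(5).to_string(index=False))
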