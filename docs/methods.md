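# Methods

Mathematical definitions, conventions and defaults for every stage of the
socionet pipeline. Symbols: genes are nodes, `n` the number of genes, `A`
the adjacency matrix, `D` the diagonal degree matrix.

## 1. Interactome construction (`socionet.interactome`)

**Channel recombination.** Link confidence arrives as per-channel scores
`s_c` in 0–1000 that each already include a prior `p = 0.041`. Excluded
channels (text mining by default, because it circularly rewards genes that
are talked about) are dropped; the rest are de-priored, combined as
independent evidence, and re-priored:

```
s'_c = max(0, (s_c/1000 − p) / (1 − p))
c    = 1 − Π_c (1 − s'_c)
t    = c·(1 − p) + p            score = round(1000·t)
```

Worked example: `{a: 500, b: 500}` → `s' = 0.4786` twice, `c = 0.7281`,
`t = 0.7393`, score `739`. A single channel at the prior (or all channels
excluded) recombines to `41 = round(1000·0.041)`.

**Confidence filtering.** An edge is retained if its recombined score is
high confidence (≥ 700), or if it is medium confidence (≥ 400, < 700) and
ranks among the top `k = 3` medium edges of *either* endpoint (ties broken
by higher score, then lexicographic partner). The union-over-endpoints rule
means a gene can end up with more than `k` medium edges — its own top-3
plus edges kept on behalf of partners. Proteins are mapped to genes before
filtering; multiple protein pairs collapsing onto one gene pair keep the
maximum score; self-loops and unmapped proteins are dropped.

**Normalisation.** `W = D^(−1/2) A D^(−1/2)`, symmetric, spectral radius
≤ 1. Weighting is binary by default (`A_ij ∈ {0,1}`); `weighting="score"`
uses `score/1000`. Isolated genes get zero rows/columns (0/0 → 0).

## 2. Diffusion and smoothing index (`socionet.diffusion`)

**Diffusion.** With restart parameter `α ∈ [0, 1)` and seed indicator
`x0`,

```
xs = (1 − α)(I − αW)^(−1) x0
```

solved by sparse LU (`method="solve"`) or by the geometric power series
`(1 − α)·Σ_k (αW)^k x0` to tolerance 1e-10 (`method="series"`); the two
agree to ~1e-10 on random graphs. Default `α = 0.7`.

*Note on the source formula.* The resolvent is sometimes printed as
`(I − W)^(−1)` with `α` only multiplying `W` inside the propagation — but
`I − W` is exactly singular for any graph (`D^(1/2)·1` is an eigenvector of
`W` with eigenvalue 1), so that operator does not exist. We implement the
standard random-walk-with-restart resolvent `(1 − α)(I − αW)^(−1)`, which
reduces to `x0` at `α = 0` and concentrates mass on the seed neighbourhood
as `α → 1`.

*Conservation.* Plain mass `Σ xs` is **not** conserved in general; the
exact invariant is the degree-weighted mass `Σ_i √d_i · xs_i = Σ_i √d_i ·
x0_i` (because `D^(1/2)·1` is a fixed left eigenvector of `W`). Tests
assert the exact weighted law and only a 5 %-tolerance plain-mass bound.

**Smoothing index.** `S_i = xs_i / (x0_i + ε)` with `ε > 0` damping the
trivial self-signal of seeds; default `ε = 50` on the raw scale used here
(chosen by `select_epsilon`, which picks the smallest grid value whose
top-k genes induce the most connected seed subgraph; the objective is flat
across `{1, 10, 50, 100, 500}` on the benchmark).

**Permutation adjustment.** `n_perm` (default 1000) uniform relabelings of
the seed set preserve the seed count; for each gene

```
p_i = (1 + #{S_i^perm ≥ S_i^obs}) / (n_perm + 1)
S̃_i = −S_i · log10(p_i)
```

The `+1` pseudocount floors `p` at `1/(n_perm+1)`. When every gene is a
seed the permutation is a no-op and `p = 1`, `S̃ = 0` everywhere. Per-
permutation gene rankings are stored (int32) for the resampling test below.

*Calibration.* Under a null with no planted wiring, `p` is uniform.
p-values from one run share the same permutation set and are therefore
cross-correlated, so calibration is checked on the **pooled** p-values of
four independent null runs against the DKW band for one run's worth of iid
draws (`sup |ECDF − U| ≤ √(ln(2/α)/(2·500)) ≈ 0.087` at `α = 0.001`);
measured deviation ≈ 0.014–0.044.

## 3. Top-network extraction (`socionet.extraction`)

Genes are ordered by `S̃` (ties by `xs`, then index). For each `r` in a
grid (default 50 to 500 step 10 → 46 candidates, nested by construction),
the top-`r` induced subgraph is scored on four criteria:

1. **Modularity Q** of its multilevel (Louvain) partition; edgeless → 0.
2. **n_sig**: number of its genes with `p < 0.01`.
3. **p_resampling**: fraction of stored permutations whose own top-`r`
   genes induce at least as many edges, with the `+1` pseudocount; zero
   observed links → `p = 1`, and `p` is monotone non-increasing in the
   observed link count.
4. **p_disease**: hypergeometric enrichment of the independent disease
   list in the candidate, against the full gene universe.

Each criterion is rank-transformed (average ranks on ties; `Q` and `n_sig`
descending, the two p-values ascending) and the candidate with the smallest
rank sum wins; ties go to the smaller `r`. Selection is invariant to the
order in which candidates are supplied.

## 4. Cartography (`socionet.cartography`)

Communities by igraph `multilevel` (default) or `fastgreedy`, seeded
through igraph's RNG for determinism; an edgeless graph yields singleton
communities and `Q = 0`. For gene `i` in community `s_i` with `k_i` total
and `k_{i,s}` within-community links:

```
z_i = (k_{i,s_i} − mean_s) / sd_s        (population sd; sd = 0 → z = 0)
P_i = 1 − Σ_s (k_{i,s} / k_i)^2          (isolated gene → P = 0)
```

Roles (strict inequalities): non-hubs (`z < 2.5`) are R1 ultra-peripheral
(`P < 0.05`), R2 peripheral (`P < 0.62`), R3 non-hub connector
(`P < 0.80`), R4 non-hub kinless; hubs (`z ≥ 2.5`) are R5 provincial
(`P < 0.30`), R6 connector (`P < 0.75`), R7 kinless.

## 5. Enrichment (`socionet.enrichment`)

**ORA.** One upper-tail hypergeometric test per pathway,
`p = P(X ≥ k)` with `k` = overlap, `K` = pathway∩universe size, `n` =
query size, `N` = universe size (`scipy.stats.hypergeom.sf(k−1, N, K, n)`,
verified against brute-force enumeration for all universes `N ≤ 12`).
Pathways are restricted to the universe **before** the size filter
(default 3 ≤ K ≤ 200). Benjamini–Hochberg FDR across all tested pathways.

**Meta-pathways.** Pathways with `fdr < 0.05` and `k ≥ 3` become nodes;
edges connect pairs whose overlap coefficient `|A∩B|/min(|A|,|B|)` clears a
threshold. The threshold is swept over 0.05–0.95 (step 0.05) and the value
maximising fastgreedy modularity of the pathway network is kept (smallest
on ties). Fewer than two eligible pathways → trivial clustering with a
warning.

## 6. Genomic annotation (`socionet.genomics`)

**Band enrichment.** Per-cytogenetic-band hypergeometric test of the
network genes against the annotated universe, BH-corrected; `fdr < 0.25`
flags a band as significant (a deliberately permissive screen, as band
hits are descriptive).

**Linkage windows.** Two genes are linked if they sit on the same
chromosome with span gap ≤ `window_bp` (inclusive; overlapping spans have
gap 0). The default window of 500 000 bp encodes the 0.5 cM criterion
under the standard coarse conversion 1 cM ≈ 1 Mb; the conversion constant
(`BP_PER_CM = 1e6`) and the window are both configurable, since real
recombination rates vary severalfold along the genome.

**HAR overlap.** Pure set algebra: network genes in human-accelerated
regions, split by disease-list membership.

**Overlap reports.** `overlap_report(a, b, universe)` returns the overlap
count, its percentage of `|a|` (rounded half-up, so 78/240 → 33), and the
hypergeometric p-value.

## 7. Synthetic benchmark (`socionet.synthetic_data`)

`generate_benchmark(BenchmarkConfig(...))` emulates all five inputs with
known ground truth (`truth.json`):

- **Interactome**: Barabási–Albert (`m = 2`) or Erdős–Rényi background on
  500 genes; a planted 40-gene module wired at `p_intra = 0.30`; channel
  scores constructed so recombination recovers the target edge score; 30 %
  of kept edges downscored into the medium band; 5 % noise edges scored
  150–399 (below every threshold); a text-mining channel that must be
  ignored and that inflates the raw `combined_score` column.
- **Seeds**: 24 inside the module, 16 background.
- **Disease list**: 30 genes, 15 inside the module.
- **Pathways**: 20 gene sets, 5 derived from the module.
- **Loci**: 5 chromosomes × 4 bands; half the module placed in one band.
- **HARs / DEG list**: fixed-size gene samples with controlled module
  overlap.

`null_benchmark` zeroes the planted wiring and band clustering while
keeping all cardinalities, for calibration tests. Generation is fully
deterministic per seed (byte-identical files).

*Limits.* The generator reproduces the pipeline-relevant structure
(confidence channels, a diffusion-recoverable module, partially
overlapping evidence lists), not biology: degree distributions, pathway
co-membership correlations and recombination-rate variation are all
simplified, and problem sizes (500 genes vs. ~17 000 in a real
interactome) are chosen for test-time tractability. Measured behaviour on
defaults: recall of the planted module ≥ 80 % at `p_intra = 0.30`,
monotone in `p_intra`, and at `p_intra = 0` non-seed module genes are
recovered at chance level.

## 8. Defaults at a glance

| parameter | default | where |
| --- | --- | --- |
| prior `p` | 0.041 | recombination |
| high / medium threshold | 700 / 400 | filtering |
| top-k medium | 3 | filtering |
| α | 0.7 | diffusion |
| ε | 50 | smoothing index |
| n_perm | 1000 | permutation null |
| r grid | 50–500 step 10 | extraction |
| significance cut for n_sig | p < 0.01 | extraction |
| ORA size filter / FDR | 3–200 / 0.05 | enrichment |
| band FDR | 0.25 | genomics |
| linkage window | 500 000 bp (0.5 cM) | genomics |
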