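"""Network diffusion, the smoothing index and its permutation null.

Seed genes are encoded as a 0/1 vector x0 over the interactome. Diffusion
propagates the seed signal to the damped steady state

    xs = (1 - alpha) (I - alpha W)^(-1) x0,

where W is the symmetrically normalized adjacency matrix and alpha in (0, 1)
weighs network structure against the initial condition. The smoothing index

    Si(eps) = xs_i / (x0_i + eps)

de-emphasizes seeds that receive little network support. Significance is
assessed by uniformly permuting the seed labels over the interactome genes,
and the adjusted index S~_i = -Si * log10(p_i) combines effect size with
permutation significance; genes are ranked by decreasing S~.

Note on the steady state: the closed form is sometimes printed as
(1 - alpha)(I - W)^(-1) x0, which is singular whenever a connected component
has a unit eigenvalue of W; the damped resolvent (I - alpha W)^(-1) is the
well-posed operator actually iterated by the power series
(1 - alpha) sum_k alpha^k W^k x0 and is what this module computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from socionet.interactome import Interactome


def seed_vector(
    interactome: Interactome, seeds: Iterable[str]
) -> tuple[np.ndarray, list[str]]:
    """Binary seed vector over interactome genes.

    Returns (x0, dropped) where ``dropped`` lists seed identifiers absent
    from the interactome (reported to the caller, not an error).
    """
    seeds = set(seeds)
    x0 = np.zeros(interactome.n_genes)
    dropped = sorted(s for s in seeds if s not in interactome._index)
    for s in seeds - set(dropped):
        x0[interactome.index(s)] = 1.0
    if x0.sum() < 1:
        raise ValueError("no seed gene is present in the interactome")
    return x0, dropped


def _resolvent(W: sp.spmatrix, alpha: float) -> spla.SuperLU:
    n = W.shape[0]
    system = (sp.identity(n, format="csc") - alpha * W.tocsc()).tocsc()
    return spla.splu(system)


def diffuse(
    W: sp.spmatrix,
    x0: np.ndarray,
    alpha: float,
    method: str = "solve",
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Steady-state diffusion values xs = (1-alpha)(I - alpha W)^(-1) x0.

    ``method="solve"`` uses a sparse LU factorization; ``method="series"``
    iterates the power series (1-alpha) sum_k alpha^k W^k x0 to a max-norm
    tolerance on the increment. Both agree for alpha in [0, 1) because the
    spectral radius of W is at most 1.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    x0 = np.asarray(x0, dtype=float)
    if method == "solve":
        if alpha == 0.0:
            return x0.copy()
        return (1.0 - alpha) * _resolvent(W, alpha).solve(x0)
    if method == "series":
        acc = x0.copy()
        term = x0.copy()
        for _ in range(max_iter):
            term = alpha * (W @ term)
            acc += term
            if np.max(np.abs(term)) < tol:
                break
        else:
            raise RuntimeError("power series did not converge")
        return (1.0 - alpha) * acc
    raise ValueError(f"unknown method {method!r}")


def smoothing_index(xs: np.ndarray, x0: np.ndarray, epsilon: float) -> np.ndarray:
    """Smoothing index Si = xs / (x0 + epsilon), elementwise."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    return np.asarray(xs, dtype=float) / (np.asarray(x0, dtype=float) + epsilon)


def _ranking(primary: np.ndarray, *tiebreak: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing primary key, then decreasing tiebreak
    keys, then increasing index (lexicographic gene order, since interactome
    genes are stored sorted)."""
    n = len(primary)
    keys = [np.arange(n)] + [-np.asarray(t) for t in reversed(tiebreak)]
    keys.append(-np.asarray(primary))
    return np.lexsort(tuple(keys))


@dataclass
class DiffusionResult:
    """Per-gene diffusion scores with their permutation null.

    ``order`` ranks gene indices by decreasing adjusted index S~ (ties
    broken by higher xs then lexicographic gene id). ``perm_rankings`` holds,
    for each permutation, the gene indices ranked by decreasing permuted Si;
    it feeds the network-resampling statistic during extraction.
    """

    genes: tuple[str, ...]
    x0: np.ndarray
    xs: np.ndarray
    si: np.ndarray
    pi: np.ndarray
    s_tilde: np.ndarray
    order: np.ndarray
    alpha: float
    epsilon: float
    n_perm: int
    seed: int
    perm_rankings: np.ndarray | None = field(default=None, repr=False)

    def ranked_genes(self, r: int | None = None) -> list[str]:
        idx = self.order if r is None else self.order[:r]
        return [self.genes[i] for i in idx]

    def to_frame(self) -> pd.DataFrame:
        """Gene table sorted by the ranking (gene, x0, xs, Si, p, S_tilde)."""
        df = pd.DataFrame(
            {
                "gene": list(self.genes),
                "x0": self.x0,
                "xs": self.xs,
                "Si": self.si,
                "p": self.pi,
                "S_tilde": self.s_tilde,
            }
        )
        return df.iloc[self.order].reset_index(drop=True)


def permutation_adjusted_index(
    W: sp.spmatrix,
    genes: Sequence[str],
    x0: np.ndarray,
    alpha: float = 0.7,
    epsilon: float = 50.0,
    n_perm: int = 1000,
    seed: int = 0,
    keep_rankings: bool = True,
) -> DiffusionResult:
    """Diffusion with a permutation null for every gene.

    For each of ``n_perm`` permutations the seed labels are uniformly
    shuffled over all interactome genes (seed count preserved) and the
    smoothing index recomputed; then

        p_i = (1 + #{perm : Si_perm(i) >= Si_obs(i)}) / (n_perm + 1)
        S~_i = -Si_obs(i) * log10(p_i)

    The +1 pseudocount keeps p away from zero, which S~ requires. Identical
    ``seed`` gives bit-identical results.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    rng = np.random.default_rng(seed)
    lu = _resolvent(W, alpha)
    scale = 1.0 - alpha

    xs = scale * lu.solve(x0)
    si = smoothing_index(xs, x0, epsilon)

    exceed = np.zeros(n, dtype=np.int64)
    perm_rankings = (
        np.empty((n_perm, n), dtype=np.int32) if keep_rankings else None
    )
    for t in range(n_perm):
        xp = x0[rng.permutation(n)]
        sip = smoothing_index(scale * lu.solve(xp), xp, epsilon)
        exceed += sip >= si
        if perm_rankings is not None:
            perm_rankings[t] = _ranking(sip).astype(np.int32)

    pi = (1.0 + exceed) / (n_perm + 1.0)
    s_tilde = -si * np.log10(pi)
    order = _ranking(s_tilde, xs)
    return DiffusionResult(
        genes=tuple(genes),
        x0=x0,
        xs=xs,
        si=si,
        pi=pi,
        s_tilde=s_tilde,
        order=order,
        alpha=alpha,
        epsilon=epsilon,
        n_perm=n_perm,
        seed=seed,
        perm_rankings=perm_rankings,
    )


def select_epsilon(
    W: sp.spmatrix,
    x0: np.ndarray,
    alpha: float,
    eps_grid: Sequence[float],
    top_k: int = 500,
) -> float:
    """Choose epsilon maximizing seed connectivity among top-ranking genes.

    For each candidate epsilon, genes are ranked by decreasing Si(eps); the
    objective is the number of seed genes (x0 = 1) within the top ``top_k``
    that are non-isolated in the subgraph induced by those top genes. The
    epsilon with the highest objective wins; ties go to the smallest.
    """
    if len(eps_grid) == 0:
        raise ValueError("eps_grid must be non-empty")
    x0 = np.asarray(x0, dtype=float)
    if top_k > len(x0):
        raise ValueError("top_k exceeds the number of genes")
    xs = diffuse(W, x0, alpha)
    Wc = W.tocsr()
    best_eps, best_obj = None, -1
    for eps in sorted(eps_grid):
        si = smoothing_index(xs, x0, eps)
        top = _ranking(si)[:top_k]
        sub = Wc[top][:, top]
        connected = np.asarray((sub != 0).sum(axis=1)).ravel() > 0
        obj = int(np.sum((x0[top] == 1) & connected))
        if obj > best_obj:
            best_eps, best_obj = eps, obj
    return float(best_eps)


def epsilon_objective(
    W: sp.spmatrix,
    x0: np.ndarray,
    alpha: float,
    eps_grid: Sequence[float],
    top_k: int = 500,
) -> dict[float, int]:
    """The select_epsilon objective evaluated over the whole grid."""
    x0 = np.asarray(x0, dtype=float)
    xs = diffuse(W, x0, alpha)
    Wc = W.tocsr()
    out: dict[float, int] = {}
    for eps in eps_grid:
        si = smoothing_index(xs, x0, eps)
        top = _ranking(si)[:top_k]
        sub = Wc[top][:, top]
        connected = np.asarray((sub != 0).sum(axis=1)).ravel() > 0
        out[float(eps)] = int(np.sum((x0[top] == 1) & connected))
    return out


def write_diffusion(result: DiffusionResult, path) -> None:
    """Write the per-gene diffusion table as TSV."""
    result.to_frame().to_csv(path, sep="\t", index=False)
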