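"""Random walk with restart on the heterogeneous disease-gene network.

The walker lives on ``m`` disease vertices plus ``n`` gene vertices.
Within-network moves follow the row-normalized phenotype similarity
matrix ``U`` and gene similarity matrix ``V``; cross-network jumps follow
the row-normalized association matrix ``R`` (disease -> gene) and its
transpose ``S`` (gene -> disease), taken with probability ``lambda``.
At every step the walker restarts with probability ``gamma`` to its
start distribution: the query disease with probability ``eta``, a
uniformly chosen seed gene with probability ``1 - eta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def row_normalize(matrix: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows stay all-zero."""
    matrix = np.asarray(matrix, dtype=float)
    if (matrix < 0).any():
        raise ValueError("matrix has negative entries")
    sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, matrix / sums, 0.0)
    return out


@dataclass
class WalkConfig:
    """Walk parameters.

    gamma   restart probability per step
    eta     probability of restarting on the disease side
    lambda_ cross-network jump probability
    epsilon L1 convergence tolerance
    """

    gamma: float = 0.5
    eta: float = 0.5
    lambda_: float = 0.7
    epsilon: float = 1e-4
    max_iter: int = 1000

    def __post_init__(self) -> None:
        for name in ("gamma", "eta", "lambda_"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class HeterogeneousSystem:
    """Assembled transition structure of the disease-gene network."""

    diseases: list[str]
    genes: list[str]
    D: np.ndarray
    G: np.ndarray
    A: np.ndarray
    U: np.ndarray = field(repr=False, default=None)
    V: np.ndarray = field(repr=False, default=None)
    R: np.ndarray = field(repr=False, default=None)
    S: np.ndarray = field(repr=False, default=None)
    W: np.ndarray = field(repr=False, default=None)
    lambda_: float = 0.7

    def __post_init__(self) -> None:
        self.disease_index = {d: i for i, d in enumerate(self.diseases)}
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def m(self) -> int:
        return len(self.diseases)

    @property
    def n(self) -> int:
        return len(self.genes)

    def seed_genes(self, disease: str) -> list[str]:
        """Genes associated with ``disease`` in A."""
        i = self.disease_index[disease]
        return [self.genes[j] for j in np.flatnonzero(self.A[i])]


def assemble_system(
    D: np.ndarray,
    G: np.ndarray,
    A: np.ndarray,
    lambda_: float = 0.7,
    diseases: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
) -> HeterogeneousSystem:
    """Build the combined row-stochastic transition matrix W.

    ``M = [(1-λ)U, λR; λS, (1-λ)V]`` with U, V, R, S the row-normalized
    D, G, A and Aᵀ; W is M row-normalized again.  A disease with no known
    gene has an all-zero R row, so its W row renormalizes onto disease
    vertices only.  A vertex isolated in every block receives a self-loop
    so W stays row-stochastic.
    """
    D, G, A = (np.asarray(x, dtype=float) for x in (D, G, A))
    m, n = A.shape
    if D.shape != (m, m) or G.shape != (n, n):
        raise ValueError("inconsistent block dimensions")
    if not np.isin(A, (0.0, 1.0)).all():
        raise ValueError("association matrix must be binary")
    if diseases is None:
        diseases = [f"d{i:04d}" for i in range(m)]
    if genes is None:
        genes = [f"g{i:06d}" for i in range(n)]
    U = row_normalize(D)
    V = row_normalize(G)
    R = row_normalize(A)
    S = row_normalize(A.T)
    M = np.block(
        [
            [(1.0 - lambda_) * U, lambda_ * R],
            [lambda_ * S, (1.0 - lambda_) * V],
        ]
    )
    W = row_normalize(M)
    isolated = W.sum(axis=1) == 0
    W[isolated, isolated] = 1.0
    return HeterogeneousSystem(
        diseases=list(diseases), genes=list(genes),
        D=D, G=G, A=A, U=U, V=V, R=R, S=S, W=W, lambda_=lambda_,
    )


def initial_vector(
    system: HeterogeneousSystem, query: str, seeds: Sequence[str], eta: float = 0.5
) -> np.ndarray:
    """Restart distribution over the m + n vertices.

    Mass ``eta`` on the query disease; ``1 - eta`` spread uniformly over
    the seed genes.  With no seeds all mass goes to the disease side.
    """
    p0 = np.zeros(system.m + system.n)
    qi = system.disease_index[query]
    if seeds:
        p0[qi] = eta
        for g in seeds:
            p0[system.m + system.gene_index[g]] = (1.0 - eta) / len(seeds)
    else:
        p0[qi] = 1.0
    return p0


@dataclass
class PrioritizationResult:
    query_disease: str
    steady_state: np.ndarray
    gene_scores: dict[str, float]
    iterations: int
    converged: bool


def walk(
    system: HeterogeneousSystem,
    p0: np.ndarray,
    config: WalkConfig | None = None,
    query: str = "",
) -> PrioritizationResult:
    """Iterate ``p <- (1-γ) Wᵀ p + γ p0`` to the steady state.

    Convergence when the L1 change drops below epsilon.  Probability mass
    is conserved at every iterate because W is row-stochastic; this is
    asserted to 1e-10 as a safeguard against assembly bugs.
    """
    config = config or WalkConfig()
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("initial vector must sum to 1")
    Wt = system.W.T
    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        p_next = (1.0 - config.gamma) * (Wt @ p) + config.gamma * p0
        assert abs(p_next.sum() - 1.0) < 1e-10, "probability mass leaked"
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < config.epsilon:
            converged = True
            break
    gene_scores = {g: float(p[system.m + j]) for j, g in enumerate(system.genes)}
    return PrioritizationResult(
        query_disease=query,
        steady_state=p,
        gene_scores=gene_scores,
        iterations=iterations,
        converged=converged,
    )


def rank_candidates(
    result: PrioritizationResult,
    candidates: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, int]]:
    """Rank candidates by descending steady-state score, ties at random.

    Returns ``(gene, rank)`` pairs, rank starting at 1.  Tied scores are
    ordered by a uniform random permutation drawn from ``rng``, so every
    tied gene is equally likely to take any rank in the tied span.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    missing = [c for c in candidates if c not in result.gene_scores]
    if missing:
        raise KeyError(f"candidates outside the walk universe: {missing[:5]}")
    rng = np.random.default_rng(rng)
    scores = np.array([result.gene_scores[c] for c in candidates])
    tiebreak = rng.permutation(len(candidates))
    order = np.lexsort((tiebreak, -scores))
    return [(candidates[j], rank + 1) for rank, j in enumerate(order)]
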