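"""Gene-gene semantic similarity and the kappa-nearest-neighbor network.

Term similarities are lifted to gene pairs by the best-match-average
rule: a term's similarity to a term set is its best match inside the
set, and two sets are compared by averaging best matches in both
directions.  The dense gene similarity matrix is then sparsified by
keeping each gene's kappa strongest neighbors (union-symmetrized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from phenowalk.ontology import AnnotationCorpus
from phenowalk.termsim import TermSimilarityMatrix

logger = logging.getLogger(__name__)


def term_to_set(term: str, terms: Iterable[str], sim: TermSimilarityMatrix) -> float:
    """Best-match similarity of ``term`` against a non-empty term set."""
    terms = list(terms)
    if not terms:
        raise ValueError("term set is empty")
    return max(sim.sim(term, t) for t in terms)


def set_to_set(
    t1: Iterable[str], t2: Iterable[str], sim: TermSimilarityMatrix
) -> float:
    """Best-match-average similarity between two non-empty term sets.

    ``(Σ_{t∈T1} sim(t, T2) + Σ_{t∈T2} sim(t, T1)) / (|T1| + |T2|)``
    """
    t1, t2 = list(t1), list(t2)
    if not t1 or not t2:
        raise ValueError("term set is empty")
    total = sum(term_to_set(t, t2, sim) for t in t1)
    total += sum(term_to_set(t, t1, sim) for t in t2)
    return total / (len(t1) + len(t2))


def gene_similarity(
    g1: str, g2: str, corpus: AnnotationCorpus, sim: TermSimilarityMatrix
) -> float:
    """Similarity of two genes' annotation term sets."""
    for g in (g1, g2):
        if g not in corpus.gene_terms:
            raise KeyError(f"gene {g!r} has no annotations")
    return set_to_set(corpus.gene_terms[g1], corpus.gene_terms[g2], sim)


def gene_similarity_matrix(
    corpus: AnnotationCorpus, sim: TermSimilarityMatrix
) -> tuple[list[str], np.ndarray]:
    """Dense pairwise gene similarity with a zero diagonal.

    Genes annotated only to terms outside the similarity universe (e.g.
    unannotated under an IC measure) are dropped with a warning.
    """
    genes = []
    term_idx: list[np.ndarray] = []
    for g in corpus.genes:
        idx = [sim.index[t] for t in corpus.gene_terms[g] if t in sim.index]
        if not idx:
            logger.warning("gene %s has no terms in the similarity universe", g)
            continue
        genes.append(g)
        term_idx.append(np.asarray(sorted(idx)))
    n = len(genes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = sim.values[np.ix_(term_idx[i], term_idx[j])]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                len(term_idx[i]) + len(term_idx[j])
            )
            values[i, j] = values[j, i] = score
    return genes, values


@dataclass
class GeneSimilarityNetwork:
    """Weighted gene graph after kappa-NN filtering; matrix ``G``."""

    genes: list[str]
    weights: np.ndarray
    kappa: int
    measure: str = "unknown"

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_edges(self) -> int:
        """Undirected edges with positive weight."""
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            n = len(self.genes)
            for i in range(n):
                for j in range(i + 1, n):
                    w = self.weights[i, j]
                    if w > 0:
                        fh.write(f"{self.genes[i]}\t{self.genes[j]}\t{w:.10g}\n")

    @classmethod
    def from_edge_tsv(cls, path, kappa: int = 0, measure: str = "unknown"):
        edges = []
        genes: set[str] = set()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b, w = line.rstrip("\n").split("\t")[:3]
                edges.append((a, b, float(w)))
                genes |= {a, b}
        order = sorted(genes)
        idx = {g: i for i, g in enumerate(order)}
        weights = np.zeros((len(order), len(order)))
        for a, b, w in edges:
            weights[idx[a], idx[b]] = weights[idx[b], idx[a]] = w
        return cls(genes=order, weights=weights, kappa=kappa, measure=measure)


def _knn_mask(weights: np.ndarray, ids: Sequence[str], kappa: int) -> np.ndarray:
    """Row-wise boolean mask of each row's kappa strongest off-diagonal
    entries; value ties at the cut broken lexicographically by identifier."""
    n = weights.shape[0]
    order_key = np.argsort([str(i) for i in ids], kind="stable")
    lex_rank = np.empty(n, dtype=int)
    lex_rank[order_key] = np.arange(n)
    mask = np.zeros_like(weights, dtype=bool)
    for i in range(n):
        row = weights[i].copy()
        row[i] = -np.inf
        # sort by (-weight, lexicographic id): stable and deterministic
        order = np.lexsort((lex_rank, -row))
        keep = [j for j in order[:kappa] if row[j] > 0]
        mask[i, keep] = True
    return mask


def knn_filter(
    full: np.ndarray,
    kappa: int,
    genes: Sequence[str] | None = None,
    measure: str = "unknown",
) -> GeneSimilarityNetwork:
    """Keep each gene's kappa strongest neighbors; union-symmetrize.

    An edge survives if either endpoint selects it; surviving edges keep
    their original weight.  ``kappa >= n - 1`` is a no-op.  Zero-weight
    entries are never promoted to edges.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    full = np.asarray(full, dtype=float)
    if full.shape[0] != full.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = full.shape[0]
    if genes is None:
        genes = [f"g{i:06d}" for i in range(n)]
    weights = full.copy()
    np.fill_diagonal(weights, 0.0)
    if kappa >= n - 1:
        return GeneSimilarityNetwork(list(genes), weights, kappa, measure)
    mask = _knn_mask(weights, genes, kappa)
    mask |= mask.T  # union symmetrization
    return GeneSimilarityNetwork(list(genes), np.where(mask, weights, 0.0), kappa, measure)
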