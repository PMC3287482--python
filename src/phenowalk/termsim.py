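"""Pairwise term semantic similarity.

Four measures are provided.  Three are information-content based:

* ``resnik``    — IC of the most concrete common ancestor (MICA),
  ``-log p_ms``; optionally normalized by the corpus maximum IC.
* ``lin``       — ``2 * IC(MICA) / (IC(a) + IC(b))``.
* ``schlicker`` — Lin's score weighted by ``1 - p_ms``, down-weighting
  pairs whose MICA is frequent.

The fourth, ``wang``, is structure-based: each ancestor ``a`` of a term
``t`` receives an s-value ``S_t(a)``, the maximum product of edge weights
(0.8 per is_a edge, 0.6 per part_of edge) along a path from ``t`` up to
``a``; similarity is the shared-ancestor s-value mass over the two terms'
total semantic values.

Logarithms are natural throughout; the base cancels in Lin and Schlicker
and only rescales Resnik.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from phenowalk.ontology import AnnotationCorpus, OntologyDAG

MEASURES = ("resnik", "lin", "schlicker", "wang")

#: Edge weights of the structure-based measure.
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def mica_probability(
    dag: OntologyDAG, corpus: AnnotationCorpus, a: str, b: str
) -> float:
    """Occurrence probability of the most concrete common ancestor.

    ``p_ms(a, b) = min_{c in anc(a) ∩ anc(b)} p(c)``.  In a multi-rooted
    DAG two terms may share no ancestor; the probability then floors at 1
    (zero information content).
    """
    common = dag.ancestors(a) & dag.ancestors(b)
    if not common:
        return 1.0
    return min(corpus.probability(c) for c in common)


def max_information_content(corpus: AnnotationCorpus) -> float:
    """Largest ``-log p(t)`` over annotated terms; 0 for a trivial corpus."""
    probs = [corpus.probability(t) for t in corpus.used_terms]
    probs = [p for p in probs if p > 0]
    if not probs:
        return 0.0
    return max(-math.log(p) for p in probs)


def resnik(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    a: str,
    b: str,
    normalize: bool = True,
    ic_max: float | None = None,
) -> float:
    """Resnik similarity ``-log p_ms(a, b)``.

    With ``normalize=True`` (the default) the score is divided by the
    corpus maximum IC so that it lies in [0, 1] like the other measures.
    """
    score = -math.log(mica_probability(dag, corpus, a, b))
    if not normalize:
        return score
    if ic_max is None:
        ic_max = max_information_content(corpus)
    return score / ic_max if ic_max > 0 else 0.0


def lin(dag: OntologyDAG, corpus: AnnotationCorpus, a: str, b: str) -> float:
    """Lin similarity: MICA IC normalized by the mean IC of the pair."""
    ic_sum = -math.log(corpus.probability(a)) - math.log(corpus.probability(b))
    if ic_sum <= 0:
        return 0.0
    return 2.0 * -math.log(mica_probability(dag, corpus, a, b)) / ic_sum


def schlicker(dag: OntologyDAG, corpus: AnnotationCorpus, a: str, b: str) -> float:
    """Schlicker (relevance) similarity: ``lin(a, b) * (1 - p_ms(a, b))``."""
    p_ms = mica_probability(dag, corpus, a, b)
    ic_sum = -math.log(corpus.probability(a)) - math.log(corpus.probability(b))
    if ic_sum <= 0:
        return 0.0
    return 2.0 * -math.log(p_ms) / ic_sum * (1.0 - p_ms)


@dataclass
class SValueTable:
    """S-values of one term's ancestor closure and their sum SV(t)."""

    target: str
    svalue: dict[str, float]
    semantic_value: float


def wang_svalues(dag: OntologyDAG, t: str) -> SValueTable:
    """Compute ``S_t(a)`` for every ancestor ``a`` of ``t``.

    ``S_t(t) = 1``; otherwise ``S_t(a)`` is the maximum over children
    ``x`` of ``a`` inside the closure of ``w_e(x -> a) * S_t(x)``.  The
    recursion is evaluated by dynamic programming in a topological order
    of the closure, children before parents.
    """
    closure = dag.ancestors(t)
    svalue: dict[str, float] = {}
    for term in dag.topological_order():
        if term not in closure:
            continue
        if term == t:
            svalue[term] = 1.0
            continue
        best = 0.0
        for child, rel in dag.children(term).items():
            if child in svalue:
                best = max(best, WANG_WEIGHTS[rel] * svalue[child])
        svalue[term] = best
    return SValueTable(target=t, svalue=svalue, semantic_value=sum(svalue.values()))


def wang(
    dag: OntologyDAG,
    a: str,
    b: str,
    tables: dict[str, SValueTable] | None = None,
) -> float:
    """Structure-based similarity of two terms.

    ``sim = Σ_{t ∈ T_a ∩ T_b} (S_a(t) + S_b(t)) / (SV(a) + SV(b))``;
    0 when the closures are disjoint (multi-rooted DAG).
    """
    ta = tables[a] if tables else wang_svalues(dag, a)
    tb = tables[b] if tables else wang_svalues(dag, b)
    shared = ta.svalue.keys() & tb.svalue.keys()
    if not shared:
        return 0.0
    num = sum(ta.svalue[t] + tb.svalue[t] for t in shared)
    return num / (ta.semantic_value + tb.semantic_value)


@dataclass
class TermSimilarityMatrix:
    """Symmetric term-by-term similarity scores under one measure."""

    measure: str
    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def to_tsv(self, path) -> None:
        """Dense TSV with term-id header row and column."""
        with open(path, "w") as fh:
            fh.write("term\t" + "\t".join(self.terms) + "\n")
            for term, row in zip(self.terms, self.values):
                fh.write(term + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, measure: str = "unknown") -> "TermSimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [
                [float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh
            ]
        return cls(measure=measure, terms=header, values=np.asarray(rows))

    def to_long_tsv(self, path, threshold: float = 0.0) -> None:
        """Sparse long-format TSV ``term_a term_b score`` (upper triangle)."""
        with open(path, "w") as fh:
            for i, a in enumerate(self.terms):
                for j in range(i + 1, len(self.terms)):
                    v = self.values[i, j]
                    if v > threshold:
                        fh.write(f"{a}\t{self.terms[j]}\t{v:.10g}\n")


def term_similarity_matrix(
    dag: OntologyDAG,
    corpus: AnnotationCorpus,
    measure: str,
    normalize_resnik: bool = True,
) -> TermSimilarityMatrix:
    """All-pairs similarity over the terms used in the corpus.

    The universe is the corpus' used terms — computing over the full
    ontology would waste quadratic space on terms no gene is annotated
    with.  Terms with ``p = 0`` cannot occur among used terms, so the IC
    universe equals the used-term set.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    terms = sorted(corpus.used_terms)
    n = len(terms)
    if measure == "wang":
        tables = {t: wang_svalues(dag, t) for t in terms}
        universe = sorted({a for t in terms for a in tables[t].svalue})
        uindex = {u: i for i, u in enumerate(universe)}
        smat = np.zeros((n, len(universe)))
        for i, t in enumerate(terms):
            for a, s in tables[t].svalue.items():
                smat[i, uindex[a]] = s
        sv = np.array([tables[t].semantic_value for t in terms])
        present = smat > 0
        values = np.zeros((n, n))
        for i in range(n):
            mask = present & present[i]
            num = np.where(mask, smat + smat[i], 0.0).sum(axis=1)
            values[i] = num / (sv + sv[i])
        return TermSimilarityMatrix("wang", terms, values)

    # IC measures share p_ms; compute it once over the ancestor closure
    universe = sorted({a for t in terms for a in dag.ancestors(t)})
    uindex = {u: i for i, u in enumerate(universe)}
    p = np.array([corpus.probability(u) for u in universe])
    anc = np.zeros((n, len(universe)), dtype=bool)
    for i, t in enumerate(terms):
        for a in dag.ancestors(t):
            anc[i, uindex[a]] = True
    p_ms = np.ones((n, n))
    for i in range(n):
        masked = np.where(anc & anc[i], p, np.inf)
        row_min = masked.min(axis=1)
        p_ms[i] = np.where(np.isfinite(row_min), row_min, 1.0)
    ic_ms = -np.log(p_ms)
    if measure == "resnik":
        if normalize_resnik:
            ic_max = max_information_content(corpus)
            values = ic_ms / ic_max if ic_max > 0 else np.zeros_like(ic_ms)
        else:
            values = ic_ms
        return TermSimilarityMatrix("resnik", terms, values)
    ic_terms = -np.log([corpus.probability(t) for t in terms])
    ic_sum = ic_terms[:, None] + ic_terms[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        lin_vals = np.where(ic_sum > 0, 2.0 * ic_ms / ic_sum, 0.0)
    if measure == "lin":
        return TermSimilarityMatrix("lin", terms, lin_vals)
    return TermSimilarityMatrix("schlicker", terms, lin_vals * (1.0 - p_ms))
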