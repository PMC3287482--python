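"""Ontology DAG and annotation corpus.

The ontology is a directed acyclic graph of terms connected by ``is_a``
and ``part_of`` edges (child -> parent).  An annotation corpus maps genes
to term sets and defines the occurrence probability ``p(t)``: the number
of annotation records falling on ``t`` or any of its descendants divided
by the total number of annotation records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Relations traversed when computing ancestor closures.  Only these two
#: carry semantic edge weights in the structure-based (Wang) measure.
SUPPORTED_RELATIONS = frozenset({"is_a", "part_of"})


class CyclicOntologyError(ValueError):
    """Raised when the input ontology contains a directed cycle."""


@dataclass
class OntologyDAG:
    """A rooted (possibly multi-rooted) ontology DAG.

    Parameters
    ----------
    terms:
        Canonical term identifiers (obsolete terms excluded).
    edges:
        ``(child, parent, relation)`` triples, relation in
        ``{"is_a", "part_of"}``.
    alt_ids:
        Map from alternative identifier to canonical term.
    """

    terms: frozenset[str]
    edges: frozenset[tuple[str, str, str]]
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._parents: dict[str, dict[str, str]] = {t: {} for t in self.terms}
        self._children: dict[str, dict[str, str]] = {t: {} for t in self.terms}
        for child, parent, rel in self.edges:
            if rel not in SUPPORTED_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child}, {parent}) references unknown term")
            # is_a dominates part_of if both relations connect the same pair
            prev = self._parents[child].get(parent)
            if prev != "is_a":
                self._parents[child][parent] = rel
                self._children[parent][child] = rel
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph((c, p) for c, p, _ in self.edges)
        g.add_nodes_from(self.terms)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
        raise CyclicOntologyError(f"ontology contains a cycle: {path}")

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parent edge."""
        return frozenset(t for t in self.terms if not self._parents[t])

    def resolve(self, term: str) -> str:
        """Map an alt-id to its canonical term; canonical ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term {term!r}")

    def parents(self, term: str) -> dict[str, str]:
        """Direct parents of ``term`` mapped to the connecting relation."""
        return dict(self._parents[self._require(term)])

    def children(self, term: str) -> dict[str, str]:
        return dict(self._children[self._require(term)])

    def ancestors(self, term: str) -> frozenset[str]:
        """The ancestor closure of ``term``, including the term itself."""
        term = self._require(term)
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        closure = {term}
        for parent in self._parents[term]:
            closure |= self.ancestors(parent)
        result = frozenset(closure)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """The descendant closure of ``term``, including the term itself."""
        term = self._require(term)
        cached = self._descendant_cache.get(term)
        if cached is not None:
            return cached
        closure = {term}
        for child in self._children[term]:
            closure |= self.descendants(child)
        result = frozenset(closure)
        self._descendant_cache[term] = result
        return result

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        g = nx.DiGraph((c, p) for c, p, _ in self.edges)
        g.add_nodes_from(self.terms)
        return list(nx.topological_sort(g))

    def _require(self, term: str) -> str:
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        return term

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def ancestors(dag: OntologyDAG, term: str) -> frozenset[str]:
    """Module-level alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term)


@dataclass
class AnnotationCorpus:
    """Gene -> term-set annotations plus per-term usage counts.

    ``propagated_count(t)`` sums direct counts over ``t`` and all its
    descendants, so the count of a parent is always at least the count of
    any child, and in a single-rooted DAG the root count equals the total
    number of annotation records.
    """

    gene_terms: dict[str, frozenset[str]]
    direct_count: dict[str, int]
    propagated_count: dict[str, int]
    total_annotations: int

    @classmethod
    def from_annotations(
        cls, dag: OntologyDAG, pairs: Iterable[tuple[str, str]]
    ) -> "AnnotationCorpus":
        """Build a corpus from (gene, term) records.

        Records are de-duplicated: a gene annotated twice to the same term
        counts once.  Alt-ids are resolved; records naming terms absent
        from the DAG are dropped with a warning.
        """
        gene_terms: dict[str, set[str]] = {}
        dropped = 0
        for gene, term in pairs:
            try:
                term = dag.resolve(term)
            except KeyError:
                dropped += 1
                continue
            gene_terms.setdefault(gene, set()).add(term)
        if dropped:
            logger.warning("dropped %d annotations naming unknown terms", dropped)
        gene_terms = {g: ts for g, ts in gene_terms.items() if ts}
        direct: dict[str, int] = {t: 0 for t in dag.terms}
        for terms in gene_terms.values():
            for t in terms:
                direct[t] += 1
        total = sum(direct.values())
        # per-edge accumulation double-counts through diamonds, so the
        # subtree total is taken over the descendant closure
        propagated = {
            t: sum(direct[d] for d in dag.descendants(t)) for t in dag.terms
        }
        return cls(
            gene_terms={g: frozenset(ts) for g, ts in sorted(gene_terms.items())},
            direct_count=direct,
            propagated_count=propagated,
            total_annotations=total,
        )

    def probability(self, term: str) -> float:
        """Occurrence probability ``p(t)`` in ``[0, 1]``."""
        if self.total_annotations <= 0:
            raise ValueError("corpus has no annotations")
        return self.propagated_count[term] / self.total_annotations

    @property
    def used_terms(self) -> frozenset[str]:
        """Terms appearing in at least one gene's annotation set."""
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return frozenset(out)

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_terms)


def term_probability(corpus: AnnotationCorpus, term: str) -> float:
    """Module-level alias for :meth:`AnnotationCorpus.probability`."""
    return corpus.probability(term)


def load_obo(
    path,
    relations: Iterable[str] = ("is_a", "part_of"),
    namespace: str | None = None,
) -> OntologyDAG:
    """Read an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Obsolete terms are dropped and alt-ids recorded.  Only the requested
    relations are kept as edges; ``namespace`` optionally restricts the
    DAG to one ontology domain (e.g. ``biological_process``).
    """
    relations = frozenset(relations)
    unknown = relations - SUPPORTED_RELATIONS
    if unknown:
        raise ValueError(f"unsupported relations: {sorted(unknown)}")
    graph = obonet.read_obo(path, ignore_obsolete=True)
    nodes = {
        n
        for n, data in graph.nodes(data=True)
        if namespace is None or data.get("namespace") == namespace
    }
    edges = frozenset(
        (c, p, rel)
        for c, p, rel in graph.edges(keys=True)
        if rel in relations and c in nodes and p in nodes
    )
    alt_ids = {
        alt: n
        for n, data in graph.nodes(data=True)
        if n in nodes
        for alt in data.get("alt_id", [])
    }
    return OntologyDAG(terms=frozenset(nodes), edges=edges, alt_ids=alt_ids)


def read_gaf(path) -> list[tuple[str, str]]:
    """Read (gene, term) pairs from a GAF 2.1/2.2 file.

    Uses DB_Object_Symbol (column 3) and GO_ID (column 5); rows whose
    qualifier contains ``NOT`` are skipped.  Evidence codes, taxa and
    aspects are not filtered.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            symbol = cols[2] or cols[1]
            pairs.append((symbol, cols[4]))
    return pairs


def read_annotation_tsv(path) -> list[tuple[str, str]]:
    """Read (gene, term) pairs from a two-column TSV."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            pairs.append((gene, term))
    return pairs


def write_annotation_tsv(path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for gene, term in pairs:
            fh.write(f"{gene}\t{term}\n")
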