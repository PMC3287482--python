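import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phenowalk.ontology import AnnotationCorpus, OntologyDAG
from phenowalk.synthetic import FixtureSpec, generate_ontology


@pytest.fixture
def chain_dag():
    """A is_a B is_a C: a three-term chain rooted at C."""
    return OntologyDAG(
        terms=frozenset({"A", "B", "C"}),
        edges=frozenset({("A", "B", "is_a"), ("B", "C", "is_a")}),
    )


@pytest.fixture
def diamond_dag():
    """X, Y both children of B and C, which are children of root R."""
    return OntologyDAG(
        terms=frozenset({"R", "B", "C", "X", "Y"}),
        edges=frozenset(
            {
                ("B", "R", "is_a"),
                ("C", "R", "is_a"),
                ("X", "B", "is_a"),
                ("X", "C", "is_a"),
                ("Y", "B", "is_a"),
                ("Y", "C", "is_a"),
            }
        ),
    )


@pytest.fixture
def diamond_corpus(diamond_dag):
    """Counts hand-picked so that p(B) = 0.5, p(C) = 0.7, p(X) = 0.2.

    10 annotation records: X twice, Y three times, C twice, R three times.
    Subtree sums: B -> 0+2+3 = 5, C -> 2+2+3 = 7, root -> 10.
    """
    pairs = (
        [(f"gx{i}", "X") for i in range(2)]
        + [(f"gy{i}", "Y") for i in range(3)]
        + [(f"gc{i}", "C") for i in range(2)]
        + [(f"gr{i}", "R") for i in range(3)]
    )
    return AnnotationCorpus.from_annotations(diamond_dag, pairs)


def random_dag_and_counts(seed: int, n_terms: int = 15, n_genes: int = 12):
    """A random single-rooted DAG plus a random annotation corpus.

    Returns (dag, corpus, edge set) — the edge set feeds the brute-force
    oracles, which work on raw triples.
    """
    spec = FixtureSpec(
        n_terms=n_terms,
        part_of_fraction=0.3,
        seed=seed,
        n_modules=1,
        n_genes=max(n_genes, 1),
        n_diseases=1,
    )
    dag = generate_ontology(spec)
    rng = np.random.default_rng(seed + 1)
    terms = sorted(dag.terms)
    pairs = []
    for g in range(n_genes):
        for t in rng.choice(terms, size=rng.integers(1, 4), replace=False):
            pairs.append((f"g{g:03d}", str(t)))
    corpus = AnnotationCorpus.from_annotations(dag, pairs)
    return dag, corpus, set(dag.edges)
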