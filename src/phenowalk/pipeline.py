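"""End-to-end convenience wrappers: world -> network -> walk -> validation."""

from __future__ import annotations

import numpy as np

from phenowalk.evaluation import ValidationSummary, loocv
from phenowalk.gene_network import (
    GeneSimilarityNetwork,
    gene_similarity_matrix,
    knn_filter,
)
from phenowalk.ontology import AnnotationCorpus
from phenowalk.rwr import WalkConfig
from phenowalk.synthetic import FixtureSpec, World, generate_world
from phenowalk.termsim import term_similarity_matrix


def build_network(
    world: World, measure: str = "resnik", kappa: int = 100
) -> GeneSimilarityNetwork:
    """Annotation corpus -> term similarity -> gene similarity -> kappa-NN."""
    corpus = AnnotationCorpus.from_annotations(world.dag, world.annotations)
    tsm = term_similarity_matrix(world.dag, corpus, measure)
    genes, sims = gene_similarity_matrix(corpus, tsm)
    return knn_filter(sims, kappa, genes, measure)


def run_benchmark(
    spec: FixtureSpec | None = None,
    measure: str = "resnik",
    design: str = "genome_wide",
    kappa: int = 100,
    n_controls: int = 99,
    config: WalkConfig | None = None,
    rng_seed: int = 0,
) -> ValidationSummary:
    """Generate a synthetic world and cross-validate the prioritizer on it."""
    spec = spec or FixtureSpec()
    world = generate_world(spec)
    net = build_network(world, measure=measure, kappa=kappa)
    A, diseases, genes = world.association_matrix(net.genes)
    if not A.any():
        raise ValueError("no associations fall inside the gene network")
    return loocv(
        world.phenotype,
        net.weights,
        A,
        diseases,
        genes,
        design=design,
        n_controls=n_controls,
        positions=world.positions,
        config=config,
        rng_seed=rng_seed,
    )
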