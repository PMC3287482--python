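"""Self-contained synthetic inputs with a planted disease-gene signal.

The generator emulates the five inputs of the pipeline — an ontology
DAG, gene annotations, a disease phenotype similarity matrix, known
disease-gene associations, and gene genomic positions — at desk scale.
Genes and diseases are partitioned into modules; each module owns a
disjoint subtree of the ontology.  A module gene draws each annotation
from its module's subtree with probability ``signal_strength`` and
uniformly from the whole ontology otherwise, so the strength parameter
moves the world continuously between a perfectly modular one (1.0) and
a null world with no functional signal (0.0).  Same-module disease
pairs receive high phenotype similarity, cross-module pairs low, and
each disease's associated genes come from its own module — so diseases
with similar phenotypes are associated with functionally similar genes,
the premise the prioritizer exploits.

Generation is a pure function of the spec: the same spec yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phenowalk.gene_network import knn_filter
from phenowalk.ontology import OntologyDAG

PHENOTYPE_KAPPA = 5  # nearest neighbors kept per disease
SAME_MODULE_SIM = (0.6, 0.9)
CROSS_MODULE_SIM = (0.0, 0.2)
N_CHROMOSOMES = 5
CHROM_LENGTH = 10_000_000


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults describe the standard benchmark: 300 terms, 400 genes, 60
    diseases in 8 modules with signal strength 0.9.
    """

    n_terms: int = 300
    branching: float = 2.0
    part_of_fraction: float = 0.2
    n_genes: int = 400
    terms_per_gene: tuple[int, int] = (3, 6)
    n_modules: int = 8
    n_diseases: int = 60
    assoc_per_disease: int = 3
    signal_strength: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_terms", "n_genes", "n_modules", "n_diseases", "assoc_per_disease"
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.n_modules > min(self.n_genes, self.n_diseases):
            raise ValueError("more modules than genes or diseases")


def _term_id(i: int) -> str:
    return f"T{i:05d}"


def generate_ontology(spec: FixtureSpec) -> OntologyDAG:
    """A single-rooted random DAG.

    The first term is the root; every later term attaches to 1-2 parents
    among earlier terms, each edge part_of with probability
    ``part_of_fraction`` and is_a otherwise.
    """
    if spec.n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(spec.seed)
    edges = set()
    for i in range(1, spec.n_terms):
        n_parents = int(rng.integers(1, 3)) if i > 1 else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
            edges.add((_term_id(i), _term_id(int(p)), rel))
    terms = frozenset(_term_id(i) for i in range(spec.n_terms))
    return OntologyDAG(terms=terms, edges=frozenset(edges))


def _modular_ontology(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[OntologyDAG, list[list[str]]]:
    """Single-rooted DAG whose module subtrees are disjoint.

    Term 0 is the root; terms 1..n_modules are module roots (children of
    the root); every later term attaches to 1-2 earlier terms of its own
    module block, so the descendant closure of each module root stays
    inside its block.
    """
    n_inner = spec.n_terms - 1 - spec.n_modules
    if n_inner < spec.n_modules:
        raise ValueError("n_terms too small for the requested modules")
    blocks: list[list[int]] = [[m + 1] for m in range(spec.n_modules)]
    for k in range(n_inner):
        blocks[k % spec.n_modules].append(1 + spec.n_modules + k)
    edges: set[tuple[str, str, str]] = set()
    for m in range(spec.n_modules):
        edges.add((_term_id(m + 1), _term_id(0), "is_a"))
        block = blocks[m]
        for pos in range(1, len(block)):
            n_parents = int(rng.integers(1, 3))
            parents = rng.choice(pos, size=min(n_parents, pos), replace=False)
            for p in parents:
                rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                edges.add((_term_id(block[pos]), _term_id(block[int(p)]), rel))
    terms = frozenset(_term_id(i) for i in range(spec.n_terms))
    dag = OntologyDAG(terms=terms, edges=frozenset(edges))
    return dag, [[_term_id(i) for i in b] for b in blocks]


@dataclass
class World:
    """One generated bundle of pipeline inputs."""

    spec: FixtureSpec
    dag: OntologyDAG
    annotations: list[tuple[str, str]]
    diseases: list[str]
    phenotype: np.ndarray
    associations: list[tuple[str, str]]
    positions: dict[str, tuple[str, int]]
    gene_module: dict[str, int] = field(default_factory=dict)
    disease_module: dict[str, int] = field(default_factory=dict)
    module_terms: list[list[str]] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.annotations})

    def association_matrix(
        self, genes: list[str] | None = None
    ) -> tuple[np.ndarray, list[str], list[str]]:
        """Binary A over (diseases x genes); associations to genes outside
        the given universe are dropped."""
        genes = self.genes if genes is None else list(genes)
        gidx = {g: j for j, g in enumerate(genes)}
        didx = {d: i for i, d in enumerate(self.diseases)}
        A = np.zeros((len(self.diseases), len(genes)))
        for d, g in self.associations:
            if g in gidx:
                A[didx[d], gidx[g]] = 1.0
        return A, list(self.diseases), genes

    def write(self, out_dir) -> dict[str, Path]:
        """Serialize the bundle as plain-text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "obo": out / "ontology.obo",
            "annotations": out / "annotations.tsv",
            "phenotype": out / "phenotype.tsv",
            "associations": out / "associations.tsv",
            "positions": out / "positions.tsv",
        }
        write_obo(paths["obo"], self.dag)
        with open(paths["annotations"], "w") as fh:
            for g, t in sorted(self.annotations):
                fh.write(f"{g}\t{t}\n")
        with open(paths["phenotype"], "w") as fh:
            fh.write("disease\t" + "\t".join(self.diseases) + "\n")
            for d, row in zip(self.diseases, self.phenotype):
                fh.write(d + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        with open(paths["associations"], "w") as fh:
            for d, g in sorted(self.associations):
                fh.write(f"{d}\t{g}\n")
        with open(paths["positions"], "w") as fh:
            for g in sorted(self.positions):
                chrom, start = self.positions[g]
                fh.write(f"{g}\t{chrom}\t{start}\t{start + 1000}\n")
        return paths


def write_obo(path, dag: OntologyDAG) -> None:
    """Minimal OBO 1.2 serialization of a DAG."""
    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in dag.terms}
    for c, p, rel in dag.edges:
        parents[c].append((p, rel))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            for p, rel in sorted(parents[t]):
                if rel == "is_a":
                    fh.write(f"is_a: {p}\n")
                else:
                    fh.write(f"relationship: part_of {p}\n")


def read_phenotype_tsv(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [[float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh]
    return header, np.asarray(rows)


def read_associations_tsv(path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            d, g = line.rstrip("\n").split("\t")[:2]
            pairs.append((d, g))
    return pairs


def generate_world(spec: FixtureSpec) -> World:
    """Generate the full input bundle with a planted modular signal."""
    lo, hi = spec.terms_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("invalid terms_per_gene range")
    rng = np.random.default_rng(spec.seed)
    dag, module_terms = _modular_ontology(spec, rng)
    smallest_block = min(len(b) for b in module_terms)
    if hi > smallest_block:
        raise ValueError(
            f"terms_per_gene upper bound {hi} exceeds smallest module "
            f"subtree ({smallest_block} terms)"
        )
    all_terms = sorted(dag.terms - dag.roots)

    genes = [f"g{i:04d}" for i in range(spec.n_genes)]
    gene_module = {g: i % spec.n_modules for i, g in enumerate(genes)}
    annotations: list[tuple[str, str]] = []
    for g in genes:
        block = module_terms[gene_module[g]]
        n_ann = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < n_ann:
            if rng.random() < spec.signal_strength:
                chosen.add(block[int(rng.integers(len(block)))])
            else:
                chosen.add(all_terms[int(rng.integers(len(all_terms)))])
        annotations.extend((g, t) for t in sorted(chosen))

    diseases = [f"d{i:03d}" for i in range(spec.n_diseases)]
    disease_module = {d: i % spec.n_modules for i, d in enumerate(diseases)}
    m = spec.n_diseases
    phenotype = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            same = disease_module[diseases[i]] == disease_module[diseases[j]]
            band = SAME_MODULE_SIM if same else CROSS_MODULE_SIM
            phenotype[i, j] = phenotype[j, i] = rng.uniform(*band)
    phenotype = knn_filter(phenotype, PHENOTYPE_KAPPA, diseases).weights

    # signal_strength also governs association modularity: each of a
    # disease's genes comes from its own module with that probability and
    # from the whole genome otherwise.  At strength 0 gene-disease links
    # are uniform with reuse, so a held-out gene's residual association
    # count matches a control's (size-biased Poisson minus the masked
    # link) and leave-one-out validation sits at chance by construction.
    module_genes = [[g for g in genes if gene_module[g] == mdl]
                    for mdl in range(spec.n_modules)]
    if spec.assoc_per_disease > min(len(b) for b in module_genes):
        raise ValueError("assoc_per_disease exceeds the smallest module size")
    associations: list[tuple[str, str]] = []
    for d in diseases:
        block = module_genes[disease_module[d]]
        chosen: set[str] = set()
        while len(chosen) < spec.assoc_per_disease:
            if rng.random() < spec.signal_strength:
                chosen.add(block[int(rng.integers(len(block)))])
            else:
                chosen.add(genes[int(rng.integers(len(genes)))])
        associations.extend((d, g) for g in sorted(chosen))

    positions = {
        g: (f"chr{1 + i % N_CHROMOSOMES}", int(rng.integers(1, CHROM_LENGTH)))
        for i, g in enumerate(genes)
    }
    return World(
        spec=spec,
        dag=dag,
        annotations=annotations,
        diseases=diseases,
        phenotype=phenotype,
        associations=associations,
        positions=positions,
        gene_module=gene_module,
        disease_module=disease_module,
        module_terms=module_terms,
    )
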