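# Methods

## Model overview

`phenowalk` infers disease genes by guilt-by-indirect-association: a
candidate gene is scored by how strongly a random walker, started at a
query disease and its known seed genes, concentrates on that gene in
the steady state of a heterogeneous network. The network couples a
disease phenotype similarity network and a gene functional similarity
network through known disease-gene associations. Because the gene
network is derived from ontology annotations rather than physical
interactions, any annotated gene is scorable — the motivation for the
whole construction.

## Term occurrence probability and the IC measures

The annotation corpus de-duplicates (gene, term) records — a gene
annotated twice to the same term counts once — and defines
`p(t) = propagated_count(t) / total`, where the propagated count sums
direct counts over `t`'s descendant closure. Summing over the closure
(rather than pushing counts edge-by-edge) avoids double counting
through diamond motifs; it guarantees `p(parent) ≥ p(child)` and
`p(root) = 1` in a single-rooted DAG.

The most-concrete-common-ancestor probability is
`p_ms(a,b) = min{p(c)}` over common ancestors `c`. Ties among equally
probable ancestors are value ties and need no resolution. In a
multi-rooted DAG two terms may share no ancestor; `p_ms` then floors at
1, i.e. zero shared information. Logarithms are natural: the base
cancels in Lin and Schlicker and only rescales Resnik.

**Resnik normalization.** Raw Resnik scores live on an unbounded IC
scale; by default they are divided by the corpus maximum IC so that all
four measures share [0, 1] and downstream κ-NN filtering is
scale-independent. A flag restores the raw scale. Terms with `p = 0`
cannot occur among annotated terms, and only annotated terms enter the
pairwise matrix, so the IC measures never see an undefined `−log 0`.

## The structure-based (Wang) measure

S-values are computed by dynamic programming over the ancestor closure
in topological order (children before parents):
`S_t(t) = 1, S_t(a) = max over children x of a in the closure of
w_e(x→a) · S_t(x)` with `w_e` 0.8 for `is_a` and 0.6 for `part_of`.
If both relations connect the same pair of terms the `is_a` weight is
used. The DP is exact: the recursion is acyclic, and tests verify it
against exhaustive path-product enumeration.

## Gene similarity and κ-NN filtering

Gene pairs use best-match-average aggregation over their annotation
sets. The pairwise matrix is computed only over terms actually used in
annotations, which bounds memory on real ontologies. Each gene's κ
strongest neighbors are kept (κ = 100 by default; the prioritizer is
insensitive to κ in the 100-300 range), value ties at the cut broken
lexicographically by gene identifier so results are reproducible.
Symmetrization is by union — an edge survives if either endpoint
selected it — which makes the filter idempotent and bounds the
undirected edge count in [κn/2, κn]. The diagonal is excluded:
self-similarity is maximal and uninformative for a walk. An absolute
weight threshold was deliberately not offered as the sparsifier, as it
tends to disconnect the network.

## Random walk with restart

The phenotype matrix D is pre-sparsified with the same κ-NN filter at
κ = 5. Blocks U, V (within-network) and R, S (cross-network) are
row-normalized, combined as `[(1−λ)U, λR; λS, (1−λ)V]`, and
row-normalized again into W. A disease with no known gene has an
all-zero R row and its mass renormalizes onto the disease side; a fully
isolated vertex receives a self-loop so W stays row-stochastic and no
probability leaks. The update is `p ← (1−γ)·Wᵀp + γ·p⁰` — the only
orientation that conserves probability with a row-stochastic W — and
the iteration is a contraction with factor 1−γ, so for γ > 0 it
converges geometrically; with the defaults (γ = 0.5, ε = 1e−4)
convergence takes well under 50 iterations, and the `max_iter = 1000`
cap only guards degenerate configurations. Mass conservation is
asserted at every iterate.

Restart mass: η to the query disease, (1−η)/s to each of the s seed
genes; with no seeds, everything to the disease side. Candidate ranks
break score ties uniformly at random under a caller-supplied seed.

## Validation designs

One association is masked per run — the gene keeps its other diseases,
the disease its other genes. Controls always exclude the query's
remaining seed genes (they carry restart mass and would be unbeatable),
so the genome-wide candidate set has n − s genes. Linkage controls are
the n nearest genes by start-coordinate distance on the hidden gene's
chromosome; if the chromosome is short, all available genes are taken
with a warning; genes without positions skip the run. "Ranked above the
threshold" means rank ratio ≤ threshold, consistent with
smaller-is-better MRR. The sweep AUC equals Mann-Whitney pair counting
with ties half-weighted (tested to 1e−9). Per-run tie-break seeds
derive deterministically from one master seed and the run index.

## Synthetic worlds

The generator emulates the five real inputs at desk scale. Defaults:
300 terms, 400 genes, 60 diseases, 8 modules, 3 associations per
disease, 3-6 annotation terms per gene, 20% `part_of` edges, signal
strength 0.9. Each module owns a disjoint rooted subtree of the
ontology (module roots are children of the global root), making the
within-module similarity contrast sharp. Phenotype similarity is drawn
from uniform bands — [0.6, 0.9] within modules, [0, 0.2] across — since
only the ordinal structure survives κ-NN filtering; the bands are not
calibrated to any real phenotype-mining score distribution.

`signal_strength` governs both annotation and association modularity:
with probability `signal_strength` a gene's annotation term comes from
its module subtree (else uniform over all terms), and a disease's
associated gene comes from its module (else uniform over all genes,
with reuse across diseases). Coupling the two is what makes the null
world truly null: if associations stayed module-confined while
annotations were random, a held-out gene would either be the unique
association-free candidate (and rank below chance) or be betrayed by
its residual in-module associations (and rank above chance). With
uniform-with-reuse sampling the held-out gene's residual association
count is distributed like any control's — a size-biased Poisson count
minus the masked link is again Poisson — so leave-one-out validation
sits at chance by construction when the signal is off.

Generation is a pure function of the spec; identical specs produce
byte-identical files.

**What the synthetic worlds do not capture:** real GO's depth and
fan-out statistics, annotation-count heavy tails, evidence codes,
phenotype-score calibration, and linkage disequilibrium structure in
gene positions. Passing the planted-signal benchmark shows the pipeline
recovers a modular functional signal end to end; it does not predict
absolute performance on real ontology and association data.

## Benchmark scales and expected results

The planted benchmark (defaults above, Resnik measure, κ = 100,
genome-wide design, 180 runs) reaches AUC ≈ 0.87-0.92 depending on the
seed, against the 0.5 chance baseline; the null benchmark
(signal 0) averages AUC ≈ 0.49 over ten seeds, with per-seed values
fluctuating by about ±0.05 at 180 runs each. The random-score baseline
(10,000 runs of 100 candidates) reproduces MRR = AUC = 50% within one
point. These are the quantities `scripts/acceptance.py` recomputes.

## Known limitations

- A single annotation corpus drives both `p(t)` and the gene sets;
  corpus-specific annotation bias propagates into every IC measure.
- The walk treats the phenotype matrix as fixed ground truth; noisy
  phenotype similarities propagate directly into rankings.
- Only `is_a` and `part_of` are traversed; other ontology relations
  (e.g. `regulates`) are ignored because the structure-based measure
  defines no weights for them.
- Multi-ontology integration and fusion of semantic with physical
  interaction networks are out of scope.
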