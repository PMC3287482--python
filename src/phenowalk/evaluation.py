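"""Leave-one-out cross-validation and rank-based evaluation.

Each validation run hides one known disease-gene association, re-runs
the walk for that disease, and ranks the hidden gene inside a candidate
set whose composition depends on the design:

* ``linkage``     — the hidden gene plus the ``n_controls`` genes nearest
  to it on the same chromosome (a simulated linkage interval).
* ``random``      — the hidden gene plus ``n_controls`` genes sampled at
  random from the network.
* ``genome_wide`` — every gene in the network.

A run's quality is its rank ratio (rank of the hidden gene divided by
the candidate count; smaller is better).  Summaries report the mean rank
ratio (MRR) and the area under the rank-ROC curve (AUC), where the curve
sweeps a rank-ratio threshold: sensitivity is the fraction of hidden
disease genes at or below the threshold, 1 - specificity the fraction of
control genes at or below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from phenowalk.rwr import (
    HeterogeneousSystem,
    WalkConfig,
    assemble_system,
    initial_vector,
    rank_candidates,
    walk,
)

logger = logging.getLogger(__name__)

DESIGNS = ("linkage", "random", "genome_wide")


@dataclass
class ValidationRun:
    """One held-out association and the resulting ranking."""

    disease: str
    gene: str
    rank: int
    n_candidates: int
    rank_ratio: float
    control_ratios: np.ndarray = field(repr=False)


@dataclass
class ValidationSummary:
    """Aggregate of validation runs: MRR, ROC points, AUC."""

    runs: list[ValidationRun]
    mrr: float
    roc: np.ndarray
    auc: float

    @classmethod
    def from_runs(cls, runs: Sequence[ValidationRun]) -> "ValidationSummary":
        runs = list(runs)
        roc, auc = roc_auc(runs)
        return cls(runs=runs, mrr=mean_rank_ratio(runs), roc=roc, auc=auc)


def mean_rank_ratio(runs: Sequence[ValidationRun]) -> float:
    """Arithmetic mean of the hidden genes' rank ratios."""
    if not runs:
        raise ValueError("no validation runs")
    return float(np.mean([r.rank_ratio for r in runs]))


def roc_auc(runs: Sequence[ValidationRun]) -> tuple[np.ndarray, float]:
    """Rank-ROC curve and its area by threshold sweep.

    The threshold ranges over every observed rank ratio; sensitivity
    counts hidden genes with ratio <= threshold, the false-positive rate
    counts control genes with ratio <= threshold.  The area equals the
    Mann-Whitney probability that a random hidden gene out-ranks a random
    control (ties half-weighted).
    """
    if not runs:
        raise ValueError("no validation runs")
    pos = np.array([r.rank_ratio for r in runs])
    neg = np.concatenate([r.control_ratios for r in runs]) if runs else np.array([])
    if neg.size == 0:
        raise ValueError("runs carry no control ratios")
    thresholds = np.unique(np.concatenate([pos, neg, [0.0, 1.0]]))
    sens = (pos[None, :] <= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    roc = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return roc, auc


def rank_distribution(
    runs: Sequence[ValidationRun], top_k: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of hidden-gene ranks within ``top_k``.

    Returns ``(per_rank, per_decade)``: counts at each exact rank
    1..top_k and counts per block of ten ranks.
    """
    ranks = np.array([r.rank for r in runs])
    per_rank = np.array([(ranks == k).sum() for k in range(1, top_k + 1)])
    n_decades = (top_k + 9) // 10
    per_decade = np.array(
        [per_rank[10 * d : 10 * (d + 1)].sum() for d in range(n_decades)]
    )
    return per_rank, per_decade


def read_positions_tsv(path) -> dict[str, tuple[str, int]]:
    """Gene genomic positions from a 4-column TSV (gene, chrom, start, end)."""
    out: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, chrom, start = line.rstrip("\n").split("\t")[:3]
            out[gene] = (chrom, int(start))
    return out


def _linkage_controls(
    gene: str,
    n_controls: int,
    positions: Mapping[str, tuple[str, int]],
    universe: Sequence[str],
    excluded: set[str],
) -> list[str] | None:
    """The ``n_controls`` genes nearest to ``gene`` on its chromosome."""
    if gene not in positions:
        return None
    chrom, start = positions[gene]
    pool = [
        (abs(positions[g][1] - start), g)
        for g in universe
        if g != gene and g not in excluded
        and g in positions and positions[g][0] == chrom
    ]
    pool.sort()
    if len(pool) < n_controls:
        logger.warning(
            "chromosome %s has only %d controls for %s (wanted %d)",
            chrom, len(pool), gene, n_controls,
        )
    return [g for _, g in pool[:n_controls]]


def loocv(
    D: np.ndarray,
    G: np.ndarray,
    A: np.ndarray,
    diseases: Sequence[str],
    genes: Sequence[str],
    design: str = "genome_wide",
    n_controls: int = 99,
    positions: Mapping[str, tuple[str, int]] | None = None,
    config: WalkConfig | None = None,
    rng_seed: int = 0,
) -> ValidationSummary:
    """Run one full leave-one-out cross-validation.

    For every association ``(disease, gene)`` only that entry of A is
    masked; the disease keeps its other seed genes and the gene keeps its
    other diseases.  Control genes never include the query disease's
    remaining seeds.  Tie-breaking is reproducible: each run draws its
    random state from ``rng_seed`` and its run index.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    if design == "linkage" and positions is None:
        raise ValueError("linkage design requires gene positions")
    config = config or WalkConfig()
    A = np.asarray(A, dtype=float)
    diseases, genes = list(diseases), list(genes)
    runs: list[ValidationRun] = []
    assoc = list(zip(*np.nonzero(A)))
    for run_idx, (di, gj) in enumerate(assoc):
        disease, gene = diseases[di], genes[gj]
        rng = np.random.default_rng([rng_seed, run_idx])
        A_masked = A.copy()
        A_masked[di, gj] = 0.0
        system = assemble_system(
            D, G, A_masked, config.lambda_, diseases=diseases, genes=genes
        )
        seeds = system.seed_genes(disease)
        excluded = set(seeds)
        if design == "genome_wide":
            controls = [g for g in genes if g != gene and g not in excluded]
        elif design == "random":
            pool = [g for g in genes if g != gene and g not in excluded]
            take = min(n_controls, len(pool))
            controls = list(rng.choice(pool, size=take, replace=False))
        else:
            controls = _linkage_controls(gene, n_controls, positions, genes, excluded)
            if controls is None:
                logger.warning("no position for %s; run skipped", gene)
                continue
        candidates = [gene] + controls
        p0 = initial_vector(system, disease, seeds, config.eta)
        result = walk(system, p0, config, query=disease)
        ranking = rank_candidates(result, candidates, rng)
        n_cand = len(candidates)
        rank_of = {g: r for g, r in ranking}
        runs.append(
            ValidationRun(
                disease=disease,
                gene=gene,
                rank=rank_of[gene],
                n_candidates=n_cand,
                rank_ratio=rank_of[gene] / n_cand,
                control_ratios=np.array(
                    [rank_of[g] / n_cand for g in controls]
                ),
            )
        )
    if not runs:
        raise ValueError("no validation runs could be performed")
    return ValidationSummary.from_runs(runs)


def random_score_baseline(
    n_runs: int = 10_000, n_candidates: int = 100, rng_seed: int = 0
) -> ValidationSummary:
    """Validation summary of a prioritizer assigning i.i.d. random scores.

    One hidden gene plus ``n_candidates - 1`` controls per run; ranks are
    determined purely by uniform random scores.  The expected MRR and AUC
    are both 0.5 — the chance baseline every informative prioritizer must
    beat.
    """
    rng = np.random.default_rng(rng_seed)
    scores = rng.random((n_runs, n_candidates))
    # rank = 1 + number of higher scores (ties have probability zero)
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(n_runs)[:, None]
    ranks[rows, order] = np.arange(1, n_candidates + 1)
    ratios = ranks / n_candidates
    runs = [
        ValidationRun(
            disease=f"d{i}",
            gene="hidden",
            rank=int(ranks[i, 0]),
            n_candidates=n_candidates,
            rank_ratio=float(ratios[i, 0]),
            control_ratios=ratios[i, 1:],
        )
        for i in range(n_runs)
    ]
    return ValidationSummary.from_runs(runs)
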