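"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the definitions alone — exhaustive set
enumeration and path enumeration — and deliberately shares no code with
the package internals it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

WEIGHT = {"is_a": 0.8, "part_of": 0.6}


def bf_ancestors(edges: set[tuple[str, str, str]], term: str) -> set[str]:
    """Transitive ancestor closure by repeated one-step expansion."""
    closure = {term}
    changed = True
    while changed:
        changed = False
        for c, p, _ in edges:
            if c in closure and p not in closure:
                closure.add(p)
                changed = True
    return closure


def bf_descendants(edges, term):
    closure = {term}
    changed = True
    while changed:
        changed = False
        for c, p, _ in edges:
            if p in closure and c not in closure:
                closure.add(c)
                changed = True
    return closure


def bf_probability(edges, direct: dict[str, int], term: str) -> float:
    total = sum(direct.values())
    return sum(direct.get(d, 0) for d in bf_descendants(edges, term)) / total


def bf_mica_probability(edges, direct, a, b) -> float:
    common = bf_ancestors(edges, a) & bf_ancestors(edges, b)
    if not common:
        return 1.0
    return min(bf_probability(edges, direct, c) for c in common)


def bf_resnik(edges, direct, a, b, ic_max=None) -> float:
    score = -math.log(bf_mica_probability(edges, direct, a, b))
    return score / ic_max if ic_max else score


def bf_lin(edges, direct, a, b) -> float:
    denom = -math.log(bf_probability(edges, direct, a)) - math.log(
        bf_probability(edges, direct, b)
    )
    if denom <= 0:
        return 0.0
    return 2.0 * -math.log(bf_mica_probability(edges, direct, a, b)) / denom


def bf_schlicker(edges, direct, a, b) -> float:
    return bf_lin(edges, direct, a, b) * (
        1.0 - bf_mica_probability(edges, direct, a, b)
    )


def bf_wang_svalues(edges, t) -> dict[str, float]:
    """S-values by exhaustive enumeration of all upward paths from t."""
    parents: dict[str, list[tuple[str, str]]] = {}
    for c, p, rel in edges:
        parents.setdefault(c, []).append((p, rel))
    best = {t: 1.0}

    def explore(node: str, product: float) -> None:
        for p, rel in parents.get(node, []):
            value = product * WEIGHT[rel]
            if value > best.get(p, 0.0):
                best[p] = value
            explore(p, value)

    explore(t, 1.0)
    return best


def bf_wang(edges, a, b) -> float:
    sa, sb = bf_wang_svalues(edges, a), bf_wang_svalues(edges, b)
    shared = sa.keys() & sb.keys()
    if not shared:
        return 0.0
    return sum(sa[t] + sb[t] for t in shared) / (
        sum(sa.values()) + sum(sb.values())
    )


def bf_set_to_set(t1, t2, pair_sim) -> float:
    """Best-match-average from a pairwise-similarity callable."""
    fwd = sum(max(pair_sim(x, y) for y in t2) for x in t1)
    bwd = sum(max(pair_sim(y, x) for x in t1) for y in t2)
    return (fwd + bwd) / (len(list(t1)) + len(list(t2)))


def bf_pair_auc(pos, neg) -> float:
    """Mann-Whitney AUC by exhaustive pair counting, ties half-weighted.

    Smaller rank ratios are better, so a positive below a negative
    counts as a correctly ordered pair.
    """
    wins = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
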