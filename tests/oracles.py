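"""Independent brute-force oracles for the scoring, spanning and
statistics code.

Everything here is written as plainly as possible — naive loops over all
genes and links, exact rational arithmetic, exhaustive enumeration — and
deliberately shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from coopmod.network import WpiNetwork
from coopmod.scoring import Seed


def _mult(net: WpiNetwork, i: str, j: str) -> int:
    m = 0
    if net.ppi.has_edge(i, j):
        m += 1
    if net.reg.has_edge(i, j):
        m += 1
    if net.reg.has_edge(j, i):
        m += 1
    return m


def naive_nl(net: WpiNetwork, i: str) -> int:
    return sum(_mult(net, i, j) for j in net.genes if j != i)


def naive_module_links(net: WpiNetwork, i: str, module: Iterable[str]) -> int:
    return sum(_mult(net, i, j) for j in module if j != i)


def naive_consistency(net: WpiNetwork, m1: Iterable[str], m2: Iterable[str]) -> float:
    set1, set2 = set(m1), set(m2)
    n = len(net.genes)
    score = 0.0
    for i in net.genes:
        if i in set1 or i in set2:
            continue
        nl = naive_nl(net, i)
        n1 = naive_module_links(net, i, set1)
        n2 = naive_module_links(net, i, set2)
        over1 = n1 > (len(set1) / n) * nl
        over2 = n2 > (len(set2) / n) * nl
        if over1 and over2:
            score += net.weights[i]
        elif over1 or over2:
            score -= net.weights[i]
    return score


def naive_neighbors(net: WpiNetwork, i: str) -> Set[str]:
    return {j for j in net.genes if j != i and _mult(net, i, j) > 0}


def naive_cmratio(net: WpiNetwork, i: str, j: str) -> float:
    ni, nj = naive_neighbors(net, i), naive_neighbors(net, j)
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def naive_mediation(net: WpiNetwork, j: str, module: Iterable[str], seed: Seed,
                    R: float = 0.9) -> float:
    members = [g for g in module if g != j]
    if not members:
        return 0.0
    opposite = seed.t if (seed.s in members or seed.s == j) else seed.s
    best = 0.0
    for i in members:
        product = naive_cmratio(net, i, j) * naive_consistency(net, [i], [opposite])
        best = max(best, product)
    return R * best if best > 0 else 0.0


def naive_mcoop(net: WpiNetwork, m1: Sequence[str], m2: Sequence[str], seed: Seed,
                R: float = 0.9) -> float:
    total = seed.ct_score
    for u in m1:
        if u == seed.s:
            continue
        total += max(naive_consistency(net, [u], [seed.t]),
                     naive_mediation(net, u, m1, seed, R))
    for v in m2:
        if v == seed.t:
            continue
        total += max(naive_consistency(net, [v], [seed.s]),
                     naive_mediation(net, v, m2, seed, R))
    return total


def _connected(net: WpiNetwork, genes: Set[str]) -> bool:
    if not genes:
        return False
    seen = {next(iter(sorted(genes)))}
    frontier = list(seen)
    while frontier:
        g = frontier.pop()
        for h in genes:
            if h not in seen and _mult(net, g, h) > 0:
                seen.add(h)
                frontier.append(h)
    return seen == genes


def exhaustive_best_pair(net: WpiNetwork, seed: Seed, R: float = 0.9) -> float:
    """Maximum cooperation score over all disjoint connected extensions of a seed.

    Every gene other than s and t is assigned to m1, m2, or neither; both
    modules must stay connected and contain their anchor.  Feasible only
    for networks of ~10 genes.
    """
    rest = [g for g in net.genes if g not in (seed.s, seed.t)]
    best = naive_mcoop(net, [seed.s], [seed.t], seed, R)
    for assignment in itertools.product((0, 1, 2), repeat=len(rest)):
        m1 = {seed.s} | {g for g, a in zip(rest, assignment) if a == 1}
        m2 = {seed.t} | {g for g, a in zip(rest, assignment) if a == 2}
        if not (_connected(net, m1) and _connected(net, m2)):
            continue
        best = max(best, naive_mcoop(net, sorted(m1), sorted(m2), seed, R))
    return best


def exhaustive_best_pair_fast(net: WpiNetwork, seed: Seed, R: float = 0.9) -> float:
    """Same optimum as :func:`exhaustive_best_pair`, from precomputed tables.

    Singleton consistency scores and CMRatios are tabulated once with
    the naive loops above, then every assignment of the remaining genes
    to (m1, m2, neither) is scored from the tables.  Still exhaustive
    and still independent of the package's incremental scorer.
    """
    genes = list(net.genes)
    ct = {
        g: {a: naive_consistency(net, [g], [a]) for a in (seed.s, seed.t) if a != g}
        for g in genes
    }
    cmr = {
        (a, b): naive_cmratio(net, a, b)
        for a in genes for b in genes if a != b
    }
    adj = {g: naive_neighbors(net, g) for g in genes}

    def connected(members: Set[str]) -> bool:
        start = next(iter(members))
        seen = {start}
        frontier = [start]
        while frontier:
            g = frontier.pop()
            for h in adj[g] & members:
                if h not in seen:
                    seen.add(h)
                    frontier.append(h)
        return seen == members

    def mcoop(m1: Sequence[str], m2: Sequence[str]) -> float:
        total = seed.ct_score
        for module, anchor, opp in ((m1, seed.s, seed.t), (m2, seed.t, seed.s)):
            for u in module:
                if u == anchor:
                    continue
                best = 0.0
                for i in module:
                    if i == u:
                        continue
                    prod = cmr[(i, u)] * ct[i][opp]
                    best = max(best, prod)
                mediated = R * best if best > 0 else 0.0
                total += max(ct[u][opp], mediated)
        return total

    rest = [g for g in genes if g not in (seed.s, seed.t)]
    best = seed.ct_score
    for assignment in itertools.product((0, 1, 2), repeat=len(rest)):
        m1 = {seed.s} | {g for g, a in zip(rest, assignment) if a == 1}
        m2 = {seed.t} | {g for g, a in zip(rest, assignment) if a == 2}
        if not (connected(m1) and connected(m2)):
            continue
        best = max(best, mcoop(sorted(m1), sorted(m2)))
    return best


def exact_hypergeom_tail(G: int, B: int, C: int, b: int) -> Fraction:
    """P(X >= b) by direct summation in exact rational arithmetic."""
    total = Fraction(0)
    for k in range(b, min(B, C) + 1):
        if C - k > G - B:
            continue
        total += Fraction(comb(B, k) * comb(G - B, C - k), comb(G, C))
    return total


def enumerate_simple_graphs_with_degrees(
    nodes: Sequence[str], degrees: Dict[str, int]
) -> List[frozenset]:
    """All simple undirected graphs on ``nodes`` matching a degree sequence.

    Returns a list of edge sets (frozensets of frozenset pairs); only
    usable for a handful of nodes.
    """
    possible = [frozenset(e) for e in itertools.combinations(nodes, 2)]
    out = []
    for r in range(len(possible) + 1):
        for subset in itertools.combinations(possible, r):
            deg = {v: 0 for v in nodes}
            for e in subset:
                for v in e:
                    deg[v] += 1
            if deg == degrees:
                out.append(frozenset(subset))
    return out
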