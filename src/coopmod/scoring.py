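"""The four scores driving cooperative module-pair discovery.

All four operate on a :class:`~coopmod.network.WpiNetwork` whose node
weights (CopL) come from co-expression degree:

* **consistency score** (CT_score) of a module pair — the summed weight of
  outside genes linked *above expectation* to both modules, minus the
  summed weight of genes linked above expectation to exactly one of them.
  The expected number of links from a module of size M to gene i is
  ``(M / N) * NL_i``; "above expectation" is a strict inequality.
* **CMRatio** of two genes — the Jaccard ratio of their physical-link
  neighbourhoods (shared partners over all distinct partners).
* **mediation score** (CoopMed) of a candidate gene j for a module m — the
  best single-mediator product ``CMRatio(i, j) * CT({i}, {opposite
  anchor})`` over module members i, attenuated by the link-reliability
  factor R (default 0.9) and clamped at zero.
* **cooperation score** (MCoop_score) of a module pair — the seed's
  consistency score plus, for every non-anchor member, the larger of its
  direct consistency with the opposite anchor and its mediation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .network import WpiNetwork

DEFAULT_R = 0.9


@dataclass(frozen=True)
class Seed:
    """An initial module pair: two genes with a top-percentile consistency score."""

    s: str
    t: str
    ct_score: float

    def __post_init__(self) -> None:
        if self.s == self.t:
            raise ValueError("seed genes must differ")


@dataclass
class Module:
    """A gene set grown from one anchor gene; insertion order = spanning order."""

    id: int
    genes: List[str]
    anchor: str

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("module must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in module")
        if self.anchor not in self.genes:
            raise ValueError("anchor must be a module member")

    @property
    def gene_set(self) -> Set[str]:
        return set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModulePair:
    m1: Module
    m2: Module
    seed: Seed
    mcoop_score: float = 0.0
    merged: bool = False

    def modules(self) -> Tuple[Module, Module]:
        return self.m1, self.m2


def module_link_count(net: WpiNetwork, i: str, module: Iterable[str]) -> int:
    """Number of physical links between gene i and members of ``module``.

    Links to i itself are never counted.
    """
    links_i = net.links[i]
    return sum(links_i.get(g, 0) for g in module if g != i)


def consistency_score(
    net: WpiNetwork, m1: Iterable[str], m2: Iterable[str]
) -> float:
    """CT_score of two disjoint modules (symmetric in its arguments)."""
    set1 = set(m1)
    set2 = set(m2)
    if set1 & set2:
        raise ValueError("modules overlap")
    if not set1 or not set2:
        raise ValueError("modules must be non-empty")
    members = set1 | set2
    size1 = len(set1)
    size2 = len(set2)
    n = net.n
    # only genes physically linked to either module can contribute
    candidates: Set[str] = set()
    for g in members:
        candidates.update(net.links[g])
    candidates -= members
    score = 0.0
    for i in candidates:
        w = net.weights[i]
        if w == 0:
            continue
        nl_i = net.nl[i]
        links_i = net.links[i]
        n1 = sum(links_i.get(g, 0) for g in set1)
        n2 = sum(links_i.get(g, 0) for g in set2)
        over1 = n1 > (size1 / n) * nl_i
        over2 = n2 > (size2 / n) * nl_i
        if over1 and over2:
            score += w
        elif over1 or over2:
            score -= w
    return score


def cmratio(net: WpiNetwork, i: str, j: str) -> float:
    """Shared-partner (Jaccard) ratio of the link-neighbourhoods of i and j."""
    if i == j:
        raise ValueError("cmratio needs two distinct genes")
    ni = net.neighbors(i)
    nj = net.neighbors(j)
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def mediation_score_with_mediator(
    net: WpiNetwork,
    j: str,
    module: Iterable[str],
    seed: Seed,
    R: float = DEFAULT_R,
) -> Tuple[float, Optional[str]]:
    """CoopMed of gene j for ``module``, plus the maximizing mediator.

    ``module`` is the module being extended; the opposite anchor is the
    seed gene of the other module (t when extending the module containing
    s, and vice versa).  Returns ``(0.0, None)`` when no mediator yields a
    positive product.
    """
    members = [g for g in module if g != j]
    if not members:
        return 0.0, None
    if seed.s in members or seed.s == j:
        opposite = seed.t
    else:
        opposite = seed.s
    best = 0.0
    best_mediator: Optional[str] = None
    for i in sorted(members):
        ratio = cmratio(net, i, j)
        if ratio == 0.0:
            continue
        ct = consistency_score(net, [i], [opposite])
        product = ratio * ct
        if product > best:
            best = product
            best_mediator = i
    if best <= 0.0:
        return 0.0, None
    return R * best, best_mediator


def mediation_score(
    net: WpiNetwork,
    j: str,
    module: Iterable[str],
    seed: Seed,
    R: float = DEFAULT_R,
) -> float:
    """CoopMed score of gene j for ``module`` (see module docstring)."""
    score, _ = mediation_score_with_mediator(net, j, module, seed, R=R)
    return score


def cooperation_score(
    net: WpiNetwork,
    m1_genes: Sequence[str],
    m2_genes: Sequence[str],
    seed: Seed,
    R: float = DEFAULT_R,
) -> float:
    """MCoop_score of a module pair anchored on ``seed``.

    Equals the seed consistency score when both modules are singletons.
    """
    set1 = set(m1_genes)
    set2 = set(m2_genes)
    if seed.s not in set1 or seed.t not in set2:
        raise ValueError("seed anchors must belong to their modules")
    if set1 & set2:
        raise ValueError("modules overlap")
    total = seed.ct_score
    for u in m1_genes:
        if u == seed.s:
            continue
        direct = consistency_score(net, [u], [seed.t])
        med = mediation_score(net, u, m1_genes, seed, R=R)
        total += max(direct, med)
    for v in m2_genes:
        if v == seed.t:
            continue
        direct = consistency_score(net, [v], [seed.s])
        med = mediation_score(net, v, m2_genes, seed, R=R)
        total += max(direct, med)
    return total


def pair_cooperation_score(net: WpiNetwork, pair: ModulePair, R: float = DEFAULT_R) -> float:
    """MCoop_score of an assembled :class:`ModulePair`."""
    return cooperation_score(net, pair.m1.genes, pair.m2.genes, pair.seed, R=R)
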