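"""Cooperative module-pair discovery.

Pipeline: score all candidate gene pairs with the consistency score, keep
the pairs strictly above the 99th percentile of the non-zero score
distribution as seeds, grow each seed into a module pair with the greedy
spanning algorithm, then iteratively merge highly overlapped modules
(> 2/3 of one module contained in the other) and drop pairs whose modules
merged together or are too small.

The spanning algorithm is a faithful rendering of the published
pseudo-code: from the current gene it takes the single unvisited
neighbour with the largest CMRatio, adds it if the pair's cooperation
score stays at or above the running maximum, and continues the chain only
while the new gene's consistency with the opposite anchor does not
decrease.  A gene whose addition lowers the score is removed from the
module but stays consumed from the visit list (intentional pruning).
Recursion is realized iteratively; the running maximum is shared between
the two module extensions of one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .network import WpiNetwork
from .scoring import (
    DEFAULT_R,
    Module,
    ModulePair,
    Seed,
    cmratio,
    consistency_score,
)

logger = logging.getLogger(__name__)


@dataclass
class DiscoveryConfig:
    seed_percentile: float = 99.0
    R: float = DEFAULT_R
    overlap_fraction: float = 2.0 / 3.0
    min_module_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.seed_percentile < 100.0:
            raise ValueError("seed_percentile must be in (0, 100)")
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must be in [0, 1]")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in (0, 1]")


@dataclass
class DiscoveryResult:
    modules: List[Module]
    pairs: List[ModulePair]
    merge_map: Dict[int, int]
    provenance: List[dict] = field(default_factory=list)


def enumerate_seed_candidates(net: WpiNetwork) -> List[Tuple[str, str]]:
    """Unordered gene pairs that can have a non-zero consistency score.

    For single-gene modules the expected-link threshold is ``NL_i / N``;
    a weighted gene i therefore contributes to pair (s, t) iff it is
    linked to s or t above that threshold.  Any pair with at least one
    endpoint carrying such a contributor can score non-zero; all other
    pairs score exactly 0 and are skipped.
    """
    bridged: Set[str] = set()
    n = net.n
    for i in net.genes:
        if net.weights[i] == 0:
            continue
        nl_i = net.nl[i]
        if nl_i == 0:
            continue
        thresh = nl_i / n
        for g, mult in net.links[i].items():
            if mult > thresh:
                bridged.add(g)
    genes = list(net.genes)
    out: List[Tuple[str, str]] = []
    bridged_sorted = sorted(bridged)
    others = [g for g in genes if g not in bridged]
    # pairs within the bridged set
    for a_idx, a in enumerate(bridged_sorted):
        for b in bridged_sorted[a_idx + 1 :]:
            out.append((a, b))
    # pairs with exactly one bridged endpoint
    for a in bridged_sorted:
        for b in others:
            out.append(tuple(sorted((a, b))))  # type: ignore[arg-type]
    return out


def _seed_score_index(net: WpiNetwork) -> Dict[str, Dict[str, int]]:
    """For each gene g: weighted contributors {i: CopL_i} with i linked to g
    above the single-gene expectation."""
    n = net.n
    contrib: Dict[str, Dict[str, int]] = {g: {} for g in net.genes}
    for i in net.genes:
        w = net.weights[i]
        if w == 0:
            continue
        nl_i = net.nl[i]
        if nl_i == 0:
            continue
        thresh = nl_i / n
        for g, mult in net.links[i].items():
            if mult > thresh:
                contrib[g][i] = w
    return contrib


def score_seed_pairs(net: WpiNetwork) -> Dict[Tuple[str, str], float]:
    """Consistency score for every candidate pair, non-zero scores only."""
    contrib = _seed_score_index(net)
    scores: Dict[Tuple[str, str], float] = {}
    for s, t in enumerate_seed_candidates(net):
        cs = contrib[s]
        ct = contrib[t]
        both = 0.0
        single = 0.0
        for i, w in cs.items():
            if i == s or i == t:
                continue
            if i in ct:
                both += w
            else:
                single += w
        for i, w in ct.items():
            if i == s or i == t or i in cs:
                continue
            single += w
        value = both - single
        if value != 0.0:
            scores[(s, t)] = value
    return scores


def select_seeds(net: WpiNetwork, cfg: DiscoveryConfig) -> List[Seed]:
    """Seeds = pairs strictly above the ``seed_percentile`` of non-zero scores."""
    scores = score_seed_pairs(net)
    if not scores:
        logger.warning("all consistency scores are zero: no seeds")
        return []
    values = np.fromiter(scores.values(), dtype=float)
    cutoff = float(np.percentile(values, cfg.seed_percentile))
    chosen = [
        Seed(s=p[0], t=p[1], ct_score=v) for p, v in scores.items() if v > cutoff
    ]
    chosen.sort(key=lambda sd: (-sd.ct_score, sd.s, sd.t))
    return chosen


class _SeedContext:
    """Per-seed caches for spanning: singleton consistency scores and CMRatios.

    The spanning algorithm re-reads CT({g}, {anchor}) and CMRatio(i, j)
    many times while a chain grows; caching them (and maintaining module
    scores incrementally) keeps each addition linear in module size
    without changing any computed value.
    """

    def __init__(self, net: WpiNetwork, seed: Seed, R: float):
        self.net = net
        self.seed = seed
        self.R = R
        self._ct: Dict[Tuple[str, str], float] = {}
        self._cmr: Dict[Tuple[str, str], float] = {}

    def ct(self, gene: str, anchor: str) -> float:
        key = (gene, anchor)
        if key not in self._ct:
            self._ct[key] = consistency_score(self.net, [gene], [anchor])
        return self._ct[key]

    def cmr(self, a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in self._cmr:
            self._cmr[key] = cmratio(self.net, a, b)
        return self._cmr[key]


class _ModuleState:
    """One growing module with its summed per-member cooperation terms."""

    def __init__(self, ctx: _SeedContext, anchor: str, opposite: str):
        self.ctx = ctx
        self.anchor = anchor
        self.opposite = opposite
        self.members: List[str] = [anchor]
        self.best_prod: Dict[str, float] = {}
        self.terms: Dict[str, float] = {}
        self.total = 0.0
        self._undo: List[Tuple[str, List[Tuple[str, float, float]], float]] = []

    def _term(self, direct: float, best_prod: float) -> float:
        mediated = self.ctx.R * best_prod if best_prod > 0.0 else 0.0
        return max(direct, mediated)

    def add(self, g: str) -> None:
        ctx = self.ctx
        ct_g = ctx.ct(g, self.opposite)
        best_g = 0.0
        for m in self.members:
            prod = ctx.cmr(m, g) * ctx.ct(m, self.opposite)
            if prod > best_g:
                best_g = prod
        term_g = self._term(ct_g, best_g)
        delta = term_g
        touched: List[Tuple[str, float, float]] = []
        for u in self.members:
            if u == self.anchor:
                continue
            cand = ctx.cmr(g, u) * ct_g
            if cand > self.best_prod[u]:
                new_term = self._term(ctx.ct(u, self.opposite), cand)
                touched.append((u, self.best_prod[u], self.terms[u]))
                delta += new_term - self.terms[u]
                self.best_prod[u] = cand
                self.terms[u] = new_term
        self.members.append(g)
        self.best_prod[g] = best_g
        self.terms[g] = term_g
        self.total += delta
        self._undo.append((g, touched, delta))

    def pop(self) -> None:
        g, touched, delta = self._undo.pop()
        self.members.pop()
        del self.best_prod[g]
        del self.terms[g]
        for u, bp, term in touched:
            self.best_prod[u] = bp
            self.terms[u] = term
        self.total -= delta


def _state_from_genes(ctx: _SeedContext, genes: Sequence[str], anchor: str,
                      opposite: str) -> _ModuleState:
    state = _ModuleState(ctx, anchor, opposite)
    for g in genes:
        if g != anchor:
            state.add(g)
    return state


def _best_neighbor(ctx: _SeedContext, y: str, visit: Set[str]) -> Optional[str]:
    """y's unvisited neighbour with the largest CMRatio (lexicographic ties)."""
    candidates = [g for g in ctx.net.links[y] if g in visit]
    if not candidates:
        return None
    best = None
    best_ratio = -1.0
    for g in sorted(candidates):
        ratio = ctx.cmr(y, g)
        if ratio > best_ratio:
            best_ratio = ratio
            best = g
    return best


def _extend(
    ctx: _SeedContext,
    grow: _ModuleState,
    other: _ModuleState,
    cooper_center: str,
    max_score: float,
    start: str,
    visit: Set[str],
) -> float:
    """Iterative rendering of the recursive Module_extend sub-function.

    ``grow`` is mutated in place; returns the updated shared max score.
    """
    y = start
    while True:
        i = _best_neighbor(ctx, y, visit)
        if i is None:
            return max_score
        visit.discard(i)
        grow.add(i)
        score = ctx.seed.ct_score + grow.total + other.total
        if score >= max_score:
            max_score = score
            if ctx.ct(i, cooper_center) >= ctx.ct(y, cooper_center):
                y = i
                continue
            return max_score  # gene kept, chain stops
        grow.pop()  # gene rejected, but stays consumed from the visit list
        return max_score


def module_extend(
    net: WpiNetwork,
    cooper_center: str,
    pair: ModulePair,
    max_score: float,
    y: str,
    visit: Set[str],
    R: float = DEFAULT_R,
) -> float:
    """Public wrapper: extend the module of ``pair`` that contains ``y``."""
    ctx = _SeedContext(net, pair.seed, R)
    seed = pair.seed
    if y in pair.m1.gene_set:
        grow_genes, other_genes = pair.m1.genes, pair.m2.genes
        grow_anchor, other_anchor = seed.s, seed.t
    elif y in pair.m2.gene_set:
        grow_genes, other_genes = pair.m2.genes, pair.m1.genes
        grow_anchor, other_anchor = seed.t, seed.s
    else:
        raise ValueError("start gene must belong to one of the pair's modules")
    grow = _state_from_genes(ctx, grow_genes, grow_anchor, other_anchor)
    other = _state_from_genes(ctx, other_genes, other_anchor, grow_anchor)
    out = _extend(ctx, grow, other, cooper_center, max_score, y, visit)
    grow_genes[:] = grow.members
    return out


def span_module_pair(
    net: WpiNetwork, seed: Seed, cfg: DiscoveryConfig, module_id_start: int = 0
) -> ModulePair:
    """Grow a seed into a module pair with the greedy spanning algorithm."""
    if seed.s not in net.links or seed.t not in net.links:
        raise ValueError("seed genes missing from network")
    visit = set(net.genes) - {seed.s, seed.t}
    ctx = _SeedContext(net, seed, cfg.R)
    state1 = _ModuleState(ctx, seed.s, seed.t)
    state2 = _ModuleState(ctx, seed.t, seed.s)
    max_score = seed.ct_score
    max_score = _extend(ctx, state1, state2, seed.t, max_score, seed.s, visit)
    max_score = _extend(ctx, state2, state1, seed.s, max_score, seed.t, visit)
    m1 = Module(id=module_id_start, genes=list(state1.members), anchor=seed.s)
    m2 = Module(id=module_id_start + 1, genes=list(state2.members), anchor=seed.t)
    final = seed.ct_score + state1.total + state2.total
    return ModulePair(m1=m1, m2=m2, seed=seed, mcoop_score=final)


def _overlap_merges(a: Set[str], b: Set[str], fraction: float) -> bool:
    """True when more than ``fraction`` of either module lies in the other."""
    inter = len(a & b)
    return inter > fraction * len(a) or inter > fraction * len(b)


def merge_overlapping_modules(
    modules: Sequence[Module], cfg: DiscoveryConfig
) -> Tuple[List[Module], Dict[int, int]]:
    """Iteratively union highly overlapped modules until a fixpoint.

    Merge order: highest overlap ratio (intersection over the smaller
    module) first, ties by lexicographic module-id pair.  The merged
    module keeps the smaller id and its anchor.
    """
    import heapq

    current: Dict[int, Set[str]] = {m.id: set(m.genes) for m in modules}
    anchors: Dict[int, str] = {m.id: m.anchor for m in modules}
    order: Dict[int, List[str]] = {m.id: list(m.genes) for m in modules}
    merge_map: Dict[int, int] = {m.id: m.id for m in modules}
    version: Dict[int, int] = {m.id: 0 for m in modules}

    gene_index: Dict[str, Set[int]] = {}
    for mid, genes in current.items():
        for g in genes:
            gene_index.setdefault(g, set()).add(mid)

    def qualifying_entry(a: int, b: int) -> Optional[Tuple[float, int, int, int, int]]:
        sa, sb = current[a], current[b]
        if not _overlap_merges(sa, sb, cfg.overlap_fraction):
            return None
        ratio = len(sa & sb) / min(len(sa), len(sb))
        return (-ratio, a, b, version[a], version[b])

    def push_pairs_for(a: int) -> None:
        partners: Set[int] = set()
        for g in current[a]:
            partners |= gene_index[g]
        partners.discard(a)
        for p in partners:
            lo, hi = (a, p) if a < p else (p, a)
            entry = qualifying_entry(lo, hi)
            if entry is not None:
                heapq.heappush(heap, entry)

    heap: List[Tuple[float, int, int, int, int]] = []
    for mid in sorted(current):
        for g in current[mid]:
            for other in gene_index[g]:
                if other > mid:
                    entry = qualifying_entry(mid, other)
                    if entry is not None:
                        heapq.heappush(heap, entry)

    while heap:
        neg_ratio, a, b, va, vb = heapq.heappop(heap)
        if a not in current or b not in current:
            continue
        if version[a] != va or version[b] != vb:
            continue  # stale entry; a fresh one was pushed on modification
        merged_genes = order[a] + [g for g in order[b] if g not in current[a]]
        for g in current[b]:
            gene_index[g].discard(b)
            gene_index[g].add(a)
        current[a] = current[a] | current[b]
        order[a] = merged_genes
        del current[b], order[b]
        version[a] += 1
        for orig, tgt in merge_map.items():
            if tgt == b:
                merge_map[orig] = a
        push_pairs_for(a)

    merged = [
        Module(id=mid, genes=order[mid], anchor=anchors[mid]) for mid in sorted(current)
    ]
    return merged, merge_map


def filter_pairs(
    pairs: Sequence[ModulePair],
    merged_modules: Sequence[Module],
    merge_map: Mapping[int, int],
    cfg: DiscoveryConfig,
) -> List[ModulePair]:
    """Drop self-pairs, still-overlapping pairs, undersized pairs; deduplicate."""
    by_id = {m.id: m for m in merged_modules}
    kept: Dict[FrozenSet[int], ModulePair] = {}
    for pair in pairs:
        a = merge_map[pair.m1.id]
        b = merge_map[pair.m2.id]
        if a == b:
            continue
        ma, mb = by_id[a], by_id[b]
        if _overlap_merges(ma.gene_set, mb.gene_set, cfg.overlap_fraction):
            continue
        if len(ma) < cfg.min_module_size or len(mb) < cfg.min_module_size:
            continue
        merged_flag = (ma.gene_set != pair.m1.gene_set) or (
            mb.gene_set != pair.m2.gene_set
        )
        mapped = ModulePair(
            m1=ma, m2=mb, seed=pair.seed, mcoop_score=pair.mcoop_score,
            merged=merged_flag,
        )
        key = frozenset((a, b))
        old = kept.get(key)
        if old is None or mapped.mcoop_score > old.mcoop_score:
            kept[key] = mapped
    out = list(kept.values())
    out.sort(key=lambda p: (min(p.m1.id, p.m2.id), max(p.m1.id, p.m2.id)))
    return out


def discover(net: WpiNetwork, cfg: Optional[DiscoveryConfig] = None) -> DiscoveryResult:
    """Full discovery stage: seeds -> spanning -> merge -> filter."""
    cfg = cfg or DiscoveryConfig()
    seeds = select_seeds(net, cfg)
    raw_pairs: List[ModulePair] = []
    provenance: List[dict] = []
    next_id = 0
    for seed in seeds:
        pair = span_module_pair(net, seed, cfg, module_id_start=next_id)
        next_id += 2
        raw_pairs.append(pair)
        provenance.append(
            {
                "seed": [seed.s, seed.t],
                "seed_ct_score": seed.ct_score,
                "m1": list(pair.m1.genes),
                "m2": list(pair.m2.genes),
                "mcoop_score": pair.mcoop_score,
            }
        )
    all_modules = [m for p in raw_pairs for m in p.modules()]
    merged, merge_map = merge_overlapping_modules(all_modules, cfg)
    pairs = filter_pairs(raw_pairs, merged, merge_map, cfg)
    used_ids = {m.id for p in pairs for m in p.modules()}
    result_modules = [m for m in merged if m.id in used_ids]
    return DiscoveryResult(
        modules=result_modules, pairs=pairs, merge_map=merge_map, provenance=provenance
    )
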