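"""Statistical evaluation of cooperative module pairs.

Two families of tests:

* **Gene-set association** — for a module pair with C correlated genes in
  a universe of G genes, and a reference gene set of size B of which b
  are among the correlated genes, the upper-tail hypergeometric
  probability P(X >= b) measures how surprising the overlap is.  Pairs
  with p < alpha (default 0.05, strict) are significant for the set — a
  cell-cycle-related set or one phase-regulated group.  Phase-significant
  pairs are then ranked by b (ties by p, then pair id) and the top k kept
  per phase.

* **Within/between-module correlation** — the number of physical links
  within a module (or between the modules of a pair) is compared with
  degree-preserving rewired networks, and the number of strongly
  co-expressed gene pairs (|r| >= 0.683) with expression matrices in
  which every gene's profile is independently permuted across
  conditions.  Both use add-one empirical p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .correlated import CorrelatedGene, NullModelConfig, rewire_degree_preserving
from .network import DEFAULT_COEXPR_THRESHOLD, ExpressionMatrix, WpiNetwork
from .scoring import Module, ModulePair

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    pair_id: int
    set_name: str
    G: int
    C: int
    B: int
    b: int
    p_value: float
    significant: bool
    note: str = ""


def hypergeom_tail(G: int, B: int, C: int, b: int) -> float:
    """Upper tail P(X >= b), X ~ Hypergeometric(population G, successes B, draws C)."""
    if not (0 <= b <= min(B, C) and B <= G and C <= G):
        raise ValueError(f"invalid hypergeometric parameters G={G} B={B} C={C} b={b}")
    if b == 0:
        return 1.0
    # scipy's sf is computed in log space internally and is stable for G ~ 1e4
    return float(stats.hypergeom.sf(b - 1, G, B, C))


def pair_geneset_significance(
    correlated_genes: Iterable[str],
    gene_set: GeneSet,
    universe: int,
    pair_id: int = 0,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric association of a pair's correlated genes with a gene set."""
    correlated = set(correlated_genes)
    C = len(correlated)
    B = len(gene_set.genes)
    if C == 0:
        return EnrichmentResult(
            pair_id=pair_id, set_name=gene_set.name, G=universe, C=0, B=B, b=0,
            p_value=1.0, significant=False, note="no correlated genes",
        )
    b = len(correlated & gene_set.genes)
    p = hypergeom_tail(universe, B, C, b)
    return EnrichmentResult(
        pair_id=pair_id, set_name=gene_set.name, G=universe, C=C, B=B, b=b,
        p_value=p, significant=p < alpha,
    )


def rank_phase_pairs(
    results: Sequence[EnrichmentResult], top_k: int = 3
) -> Dict[str, List[EnrichmentResult]]:
    """Top-k significant pairs per phase, ranked by overlap count b.

    Ties are broken by ascending p-value, then pair id.
    """
    by_phase: Dict[str, List[EnrichmentResult]] = {}
    for res in results:
        by_phase.setdefault(res.set_name, []).append(res)
    ranked: Dict[str, List[EnrichmentResult]] = {}
    for phase, rows in by_phase.items():
        sig = [r for r in rows if r.significant]
        sig.sort(key=lambda r: (-r.b, r.p_value, r.pair_id))
        ranked[phase] = sig[:top_k]
    return ranked


def _physical_link_sum(net_links: Mapping[str, Mapping[str, int]],
                       a: Set[str], b: Optional[Set[str]] = None) -> int:
    """Total link multiplicity within set a (b is None) or between a and b."""
    if b is None:
        total = 0
        for i in a:
            row = net_links[i]
            for j, mult in row.items():
                if j in a:
                    total += mult
        return total // 2
    total = 0
    for i in a:
        row = net_links[i]
        for j, mult in row.items():
            if j in b:
                total += mult
    return total


def _coexpr_pair_count(values: np.ndarray, rows_a: np.ndarray,
                       rows_b: Optional[np.ndarray], threshold: float) -> int:
    """Number of gene pairs with |r| >= threshold, within or between row sets."""
    def unit(rows: np.ndarray) -> np.ndarray:
        sub = values[rows]
        centered = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        norms[norms == 0] = np.inf  # constant profiles correlate with nothing
        return centered / norms[:, None]

    ua = unit(rows_a)
    if rows_b is None:
        corr = np.abs(ua @ ua.T)
        return int(np.triu(corr >= threshold, k=1).sum())
    ub = unit(rows_b)
    return int((np.abs(ua @ ub.T) >= threshold).sum())


def module_correlation_significance(
    net: WpiNetwork,
    expr: ExpressionMatrix,
    modules: Sequence[Module],
    pairs: Sequence[ModulePair],
    cfg: NullModelConfig,
    threshold: float = DEFAULT_COEXPR_THRESHOLD,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[int, Dict[str, float]], Dict[Tuple[int, int], Dict[str, float]]]:
    """Empirical p-values for within/between-module physical and co-expression links.

    Returns ``(per_module, per_pair)`` dicts with keys
    ``within_physical_p`` / ``within_coexpr_p`` and
    ``between_physical_p`` / ``between_coexpr_p``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    mod_sets = {m.id: m.gene_set for m in modules}
    pair_keys = [(p.m1.id, p.m2.id) for p in pairs]

    obs_within = {mid: _physical_link_sum(net.links, s) for mid, s in mod_sets.items()}
    obs_between = {
        (a, b): _physical_link_sum(net.links, mod_sets[a], mod_sets[b])
        for a, b in pair_keys
    }
    ge_within = {mid: 0 for mid in mod_sets}
    ge_between = {k: 0 for k in pair_keys}
    for _ in range(cfg.n_random):
        null_net = rewire_degree_preserving(net, rng, cfg.swaps_per_edge)
        for mid, s in mod_sets.items():
            if _physical_link_sum(null_net.links, s) >= obs_within[mid]:
                ge_within[mid] += 1
        for a, b in pair_keys:
            if _physical_link_sum(null_net.links, mod_sets[a], mod_sets[b]) >= obs_between[(a, b)]:
                ge_between[(a, b)] += 1

    # co-expression: per-gene independent permutation of conditions
    gene_row = {g: i for i, g in enumerate(expr.gene_ids)}
    values = expr.data.to_numpy(dtype=float)

    def rows_for(s: Set[str]) -> np.ndarray:
        return np.array(sorted(gene_row[g] for g in s if g in gene_row), dtype=int)

    mod_rows = {mid: rows_for(s) for mid, s in mod_sets.items()}
    obs_cx_within = {
        mid: _coexpr_pair_count(values, rows, None, threshold)
        for mid, rows in mod_rows.items() if rows.size >= 2
    }
    obs_cx_between = {
        (a, b): _coexpr_pair_count(values, mod_rows[a], mod_rows[b], threshold)
        for a, b in pair_keys if mod_rows[a].size and mod_rows[b].size
    }
    ge_cx_within = {mid: 0 for mid in obs_cx_within}
    ge_cx_between = {k: 0 for k in obs_cx_between}
    n_cond = values.shape[1]
    needed_rows = sorted({r for rows in mod_rows.values() for r in rows})
    for _ in range(cfg.n_random):
        permuted = values.copy()
        for r in needed_rows:  # independent permutation per gene
            permuted[r] = values[r, rng.permutation(n_cond)]
        for mid, rows in mod_rows.items():
            if mid in obs_cx_within:
                if _coexpr_pair_count(permuted, rows, None, threshold) >= obs_cx_within[mid]:
                    ge_cx_within[mid] += 1
        for key in obs_cx_between:
            a, b = key
            if _coexpr_pair_count(permuted, mod_rows[a], mod_rows[b], threshold) >= obs_cx_between[key]:
                ge_cx_between[key] += 1

    denom = 1.0 + cfg.n_random
    per_module: Dict[int, Dict[str, float]] = {}
    for mid in mod_sets:
        per_module[mid] = {
            "within_physical_p": (1 + ge_within[mid]) / denom,
            "within_coexpr_p": (1 + ge_cx_within.get(mid, cfg.n_random)) / denom,
        }
    per_pair: Dict[Tuple[int, int], Dict[str, float]] = {}
    for key in pair_keys:
        per_pair[key] = {
            "between_physical_p": (1 + ge_between[key]) / denom,
            "between_coexpr_p": (1 + ge_cx_between.get(key, cfg.n_random)) / denom,
        }
    return per_module, per_pair
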