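"""Correlated genes of a module pair: randomization nulls and typing.

A *correlated gene* of a cooperative module pair has significantly many
direct physical links to both modules.  Significance of an observed link
count is judged against an ensemble of degree-preserving randomized
networks: undirected protein edges are rewired by double-edge swaps that
preserve every gene's protein degree exactly; directed regulatory edges
by directed swaps preserving every in- and out-degree.  Empirical
p-values use the add-one rule, ``p = (1 + #{null >= observed}) / (1 +
n_random)``, so they can never be zero.

Each correlated gene is typed by which link kinds are significant:

==== =============================================================
type significant evidence pattern
==== =============================================================
A    protein links to one module and regulation *from* the other
B    protein links to one module and regulation *onto* the other
C    protein links to both modules
D    regulated by both modules
E    regulates both modules
==== =============================================================

A gene satisfying several patterns carries them all; its primary label
follows the priority C > D > E > A > B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .network import WpiNetwork
from .scoring import ModulePair

logger = logging.getLogger(__name__)

LINK_KINDS = ("ppi", "reg_in", "reg_out")
TYPE_PRIORITY = ("C", "D", "E", "A", "B")


@dataclass
class NullModelConfig:
    n_random: int = 1000
    swaps_per_edge: int = 10
    alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class CorrelatedGene:
    gene: str
    pair_id: int
    p_values: Dict[str, float]  # keys: ppi_m1, ppi_m2, reg_in_m1, ... reg_out_m2
    coop_type: str
    all_types: Tuple[str, ...] = ()


def _swap_undirected(
    edges: List[Tuple[int, int]], attempts: int, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Double-edge swaps on an undirected edge list (degree-preserving)."""
    m = len(edges)
    if m < 2:
        return list(edges)
    present = {(a, b) if a < b else (b, a) for a, b in edges}
    edges = list(edges)
    idx = rng.integers(0, m, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for k in range(attempts):
        e1, e2 = idx[k]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[k]:
            c, d = d, c
        # propose a-d, c-b
        if a == d or c == b:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in present or new2 in present:
            continue
        present.discard((a, b) if a < b else (b, a))
        present.discard((c, d) if c < d else (d, c))
        present.add(new1)
        present.add(new2)
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    return edges


def _swap_directed(
    edges: List[Tuple[int, int]], attempts: int, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Directed edge swaps preserving every in- and out-degree."""
    m = len(edges)
    if m < 2:
        return list(edges)
    present = set(edges)
    edges = list(edges)
    idx = rng.integers(0, m, size=(attempts, 2))
    for k in range(attempts):
        e1, e2 = idx[k]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        # propose a->d, c->b
        if a == d or c == b:
            continue
        new1 = (a, d)
        new2 = (c, b)
        if new1 in present or new2 in present:
            continue
        present.discard((a, b))
        present.discard((c, d))
        present.add(new1)
        present.add(new2)
        edges[e1] = new1
        edges[e2] = new2
    return edges


def rewire_degree_preserving(
    net: WpiNetwork, rng: np.random.Generator, swaps_per_edge: int = 10
) -> WpiNetwork:
    """Randomized copy of the network with all degree sequences preserved."""
    gene_index = {g: i for i, g in enumerate(net.genes)}
    names = list(net.genes)
    ppi = [(gene_index[u], gene_index[v]) for u, v in net.ppi.edges()]
    reg = [(gene_index[u], gene_index[v]) for u, v in net.reg.edges()]
    new_ppi = _swap_undirected(ppi, swaps_per_edge * len(ppi), rng)
    new_reg = _swap_directed(reg, swaps_per_edge * len(reg), rng)
    return net.with_edges(
        [(names[u], names[v]) for u, v in new_ppi],
        [(names[u], names[v]) for u, v in new_reg],
    )


def _tabulate_counts(
    ppi: np.ndarray, reg: np.ndarray, member_masks: np.ndarray, n_genes: int
) -> np.ndarray:
    """Link counts of every gene to every module, per link kind.

    ``ppi``/``reg`` are (m, 2) integer edge arrays; ``member_masks`` a
    boolean (n_modules, n_genes) matrix.  Returns (n_modules, 3,
    n_genes) with kinds ordered (ppi, reg_in, reg_out); reg_in counts
    regulation from the module onto the gene, reg_out regulation by the
    gene into the module.  No self-loops exist, so self-links can never
    be counted.
    """
    n_mod = member_masks.shape[0]
    counts = np.zeros((n_mod, 3, n_genes), dtype=np.int32)
    pu, pv = (ppi[:, 0], ppi[:, 1]) if len(ppi) else (np.empty(0, int), np.empty(0, int))
    ru, rv = (reg[:, 0], reg[:, 1]) if len(reg) else (np.empty(0, int), np.empty(0, int))
    for mi in range(n_mod):
        mask = member_masks[mi]
        if len(pu):
            sel = mask[pv]
            np.add.at(counts[mi, 0], pu[sel], 1)
            sel = mask[pu]
            np.add.at(counts[mi, 0], pv[sel], 1)
        if len(ru):
            sel = mask[ru]
            np.add.at(counts[mi, 1], rv[sel], 1)
            sel = mask[rv]
            np.add.at(counts[mi, 2], ru[sel], 1)
    return counts


def null_count_ensemble(
    net: WpiNetwork,
    members: Sequence[Set[str]],
    cfg: NullModelConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, int]]:
    """Observed and null link-count tables for a set of modules.

    Returns ``(observed, null, gene_index)`` where ``observed`` has shape
    (n_modules, 3, n_genes) and ``null`` (n_random, n_modules, 3, n_genes).
    One ensemble of rewired networks is generated and tabulated against
    every module at once.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    gene_index = {g: i for i, g in enumerate(net.genes)}
    n = len(gene_index)
    masks = np.zeros((len(members), n), dtype=bool)
    for mi, mem in enumerate(members):
        for g in mem:
            masks[mi, gene_index[g]] = True
    ppi = [(gene_index[u], gene_index[v]) for u, v in net.ppi.edges()]
    reg = [(gene_index[u], gene_index[v]) for u, v in net.reg.edges()]
    observed = _tabulate_counts(
        np.array(ppi, dtype=int).reshape(-1, 2),
        np.array(reg, dtype=int).reshape(-1, 2),
        masks, n,
    )
    null = np.zeros((cfg.n_random, len(members), 3, n), dtype=np.int32)
    ppi_attempts = cfg.swaps_per_edge * len(ppi)
    reg_attempts = cfg.swaps_per_edge * len(reg)
    for r in range(cfg.n_random):
        rp = _swap_undirected(ppi, ppi_attempts, rng)
        rr = _swap_directed(reg, reg_attempts, rng)
        null[r] = _tabulate_counts(
            np.array(rp, dtype=int).reshape(-1, 2),
            np.array(rr, dtype=int).reshape(-1, 2),
            masks, n,
        )
    return observed, null, gene_index


def empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Add-one upper-tail empirical p-values, shape = observed.shape."""
    n_random = null.shape[0]
    ge = (null >= observed[None, ...]).sum(axis=0)
    return (1.0 + ge) / (1.0 + n_random)


def link_count_pvalue(
    net: WpiNetwork,
    gene: str,
    module: Iterable[str],
    link_kind: str,
    cfg: NullModelConfig,
) -> float:
    """Empirical p-value for one gene/module/link-kind count."""
    if link_kind not in LINK_KINDS:
        raise ValueError(f"unknown link kind {link_kind!r}")
    members = [set(module)]
    observed, null, gene_index = null_count_ensemble(net, members, cfg)
    kind = LINK_KINDS.index(link_kind)
    gi = gene_index[gene]
    return float(empirical_pvalues(observed, null)[0, kind, gi])


def classify_cooperation_type(
    p_values: Dict[str, float], alpha: float
) -> Tuple[str, Tuple[str, ...]]:
    """Primary label and all satisfied cooperation patterns for one gene.

    ``p_values`` keys: ppi_m1, ppi_m2, reg_in_m1, reg_in_m2, reg_out_m1,
    reg_out_m2 — where reg_in_mK is regulation from module K onto the
    gene and reg_out_mK is regulation by the gene onto module K.
    """
    sig = {k: (v <= alpha) for k, v in p_values.items()}
    patterns: List[str] = []
    if sig["ppi_m1"] and sig["ppi_m2"]:
        patterns.append("C")
    if sig["reg_in_m1"] and sig["reg_in_m2"]:
        patterns.append("D")
    if sig["reg_out_m1"] and sig["reg_out_m2"]:
        patterns.append("E")
    if (sig["ppi_m1"] and sig["reg_in_m2"]) or (sig["ppi_m2"] and sig["reg_in_m1"]):
        patterns.append("A")
    if (sig["ppi_m1"] and sig["reg_out_m2"]) or (sig["ppi_m2"] and sig["reg_out_m1"]):
        patterns.append("B")
    if not patterns:
        raise ValueError("no qualifying cooperation pattern in evidence")
    ordered = tuple(t for t in TYPE_PRIORITY if t in patterns)
    return ordered[0], ordered


def _collect_for_pair(
    net: WpiNetwork,
    pvals: np.ndarray,
    gene_index: Dict[str, int],
    pair_id: int,
    alpha: float,
) -> List[CorrelatedGene]:
    """Assemble CorrelatedGene records from a (2, 3, n_genes) p-value block."""
    out: List[CorrelatedGene] = []
    for gene in net.genes:
        gi = gene_index[gene]
        p = {
            "ppi_m1": float(pvals[0, 0, gi]),
            "ppi_m2": float(pvals[1, 0, gi]),
            "reg_in_m1": float(pvals[0, 1, gi]),
            "reg_in_m2": float(pvals[1, 1, gi]),
            "reg_out_m1": float(pvals[0, 2, gi]),
            "reg_out_m2": float(pvals[1, 2, gi]),
        }
        sig_m1 = min(p["ppi_m1"], p["reg_in_m1"], p["reg_out_m1"]) <= alpha
        sig_m2 = min(p["ppi_m2"], p["reg_in_m2"], p["reg_out_m2"]) <= alpha
        if not (sig_m1 and sig_m2):
            continue
        try:
            primary, all_types = classify_cooperation_type(p, alpha)
        except ValueError:
            logger.debug(
                "gene %s significant to both modules but matches no A-E pattern",
                gene,
            )
            continue
        out.append(
            CorrelatedGene(
                gene=gene, pair_id=pair_id, p_values=p,
                coop_type=primary, all_types=all_types,
            )
        )
    return out


def identify_correlated_genes(
    net: WpiNetwork,
    pair: ModulePair,
    cfg: NullModelConfig,
    pair_id: int = 0,
    ensemble: Optional[Tuple[np.ndarray, np.ndarray, Dict[str, int]]] = None,
) -> List[CorrelatedGene]:
    """All genes significantly linked to both modules of a pair, typed A-E.

    One null ensemble is generated per call and reused for every gene; a
    precomputed ensemble (from :func:`null_count_ensemble` on the same
    module pair) can be passed to share nulls across callers.
    """
    members = [pair.m1.gene_set, pair.m2.gene_set]
    if ensemble is None:
        ensemble = null_count_ensemble(net, members, cfg)
    observed, null, gene_index = ensemble
    pvals = empirical_pvalues(observed, null)  # (2, 3, n_genes)
    return _collect_for_pair(net, pvals, gene_index, pair_id, cfg.alpha)


def identify_correlated_genes_for_pairs(
    net: WpiNetwork,
    pairs: Sequence[ModulePair],
    cfg: NullModelConfig,
) -> List[CorrelatedGene]:
    """Correlated genes for every pair from a single shared null ensemble.

    The rewired-network ensemble is generated once and its link counts
    tabulated for every module of every pair, which keeps a multi-pair
    run at the cost of a single-pair one.
    """
    if not pairs:
        return []
    members: List[Set[str]] = []
    for pair in pairs:
        members.append(pair.m1.gene_set)
        members.append(pair.m2.gene_set)
    observed, null, gene_index = null_count_ensemble(net, members, cfg)
    pvals = empirical_pvalues(observed, null)
    out: List[CorrelatedGene] = []
    for pair_id in range(len(pairs)):
        block = pvals[2 * pair_id : 2 * pair_id + 2]
        out.extend(_collect_for_pair(net, block, gene_index, pair_id, cfg.alpha))
    return out
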