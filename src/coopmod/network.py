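"""Weighted physical interaction (WPI) network construction.

The WPI network integrates three data types for one organism/condition:

* a gene-by-condition expression matrix, from which a co-expression network
  is built (edges between genes whose Pearson correlation satisfies
  ``|r| >= 0.683``) — the *degree* of a gene in that network becomes its
  node weight (``CopL``), a proxy for how central the gene is to the
  process under study;
* an undirected protein-protein interaction edge list (BioGRID-style);
* a directed regulatory edge list (transcription factor -> target,
  ChIP-chip-style).

Nodes are genes; links are physical (protein or regulatory) interactions.
Link counting treats one undirected protein pair as one link and one
directed regulatory pair as one link (direction kept as metadata); a gene
pair connected by both kinds contributes two links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_COEXPR_THRESHOLD = 0.683


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation is requested for a zero-variance vector."""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Raises
    ------
    ValueError
        If the vectors differ in length or are shorter than 3.
    UndefinedCorrelationError
        If either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance expression profile")
    r = float((xc @ yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


@dataclass
class ExpressionMatrix:
    """Gene-by-condition expression table.

    Rows with missing values are dropped (and counted) at load time, so the
    stored table is always complete. Gene ids are unique, opaque strings.
    """

    data: pd.DataFrame  # index: gene ids, columns: condition labels
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.data.shape[1] < 3:
            raise ValueError("expression matrix needs >= 3 conditions")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a raw frame, dropping (and logging) incomplete rows."""
        complete = frame.dropna(axis=0)
        n_dropped = len(frame) - len(complete)
        if n_dropped:
            logger.info("dropped %d expression rows with missing values", n_dropped)
        return cls(data=complete.astype(float), n_dropped=n_dropped)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def condition_ids(self) -> List[str]:
        return list(self.data.columns)


def build_coexpression_network(
    expr: ExpressionMatrix, threshold: float = DEFAULT_COEXPR_THRESHOLD
) -> nx.Graph:
    """Co-expression network: edge (i, j) iff ``|r(i, j)| >= threshold``.

    Both strongly positive and strongly negative correlations produce an
    edge; the signed ``r`` is stored as the edge attribute ``r``.  Genes
    with constant profiles cannot participate in any edge and are skipped
    with a log entry.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(expr.gene_ids)
    values = expr.data.to_numpy(dtype=float)
    genes = expr.gene_ids
    if len(genes) < 2:
        logger.warning("fewer than 2 genes: empty co-expression network")
        return g
    sd = values.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        logger.info(
            "skipping %d constant expression profiles in co-expression network",
            int(constant.sum()),
        )
    keep = ~constant
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size >= 2:
        sub = values[kept_idx]
        centered = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        unit = centered / norms[:, None]
        corr = np.clip(unit @ unit.T, -1.0, 1.0)
        ii, jj = np.nonzero(np.triu(np.abs(corr) >= threshold, k=1))
        for a, b in zip(ii, jj):
            g.add_edge(genes[kept_idx[a]], genes[kept_idx[b]], r=float(corr[a, b]))
    return g


def compute_gene_weights(
    coexp: nx.Graph, universe: Iterable[str]
) -> Dict[str, int]:
    """Per-gene weight CopL = degree in the co-expression network (0 if absent)."""
    return {g: (coexp.degree(g) if g in coexp else 0) for g in universe}


@dataclass
class WpiNetwork:
    """Weighted physical interaction network.

    Attributes
    ----------
    genes : sorted tuple of gene ids (the universe of size N)
    weights : gene -> CopL (co-expression degree; 0 when unknown)
    ppi : undirected protein-interaction graph over ``genes``
    reg : directed regulatory graph over ``genes``
    """

    genes: Tuple[str, ...]
    weights: Dict[str, int]
    ppi: nx.Graph
    reg: nx.DiGraph
    # derived caches
    links: Dict[str, Dict[str, int]] = field(repr=False, default_factory=dict)
    nl: Dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.links:
            self._rebuild_caches()

    def _rebuild_caches(self) -> None:
        links: Dict[str, Dict[str, int]] = {g: {} for g in self.genes}
        for u, v in self.ppi.edges():
            links[u][v] = links[u].get(v, 0) + 1
            links[v][u] = links[v].get(u, 0) + 1
        for u, v in self.reg.edges():
            links[u][v] = links[u].get(v, 0) + 1
            links[v][u] = links[v].get(u, 0) + 1
        self.links = links
        self.nl = {g: sum(nbrs.values()) for g, nbrs in links.items()}

    @property
    def n(self) -> int:
        return len(self.genes)

    def link_count(self, gene: str) -> int:
        """NL_i: total incident physical links (protein + regulatory)."""
        return self.nl[gene]

    def neighbors(self, gene: str) -> Set[str]:
        """Genes linked to ``gene`` by any physical link."""
        return set(self.links[gene])

    def multiplicity(self, i: str, j: str) -> int:
        """Number of links between genes i and j (0, 1 or 2)."""
        return self.links[i].get(j, 0)

    def with_edges(
        self, ppi_edges: Iterable[Tuple[str, str]], reg_edges: Iterable[Tuple[str, str]]
    ) -> "WpiNetwork":
        """Same genes and weights, different edge sets (used by null models)."""
        ppi = nx.Graph()
        ppi.add_nodes_from(self.genes)
        ppi.add_edges_from(ppi_edges)
        reg = nx.DiGraph()
        reg.add_nodes_from(self.genes)
        reg.add_edges_from(reg_edges)
        return WpiNetwork(genes=self.genes, weights=self.weights, ppi=ppi, reg=reg)


def assemble_wpi(
    ppi_edges: Iterable[Tuple[str, str]],
    reg_edges: Iterable[Tuple[str, str]],
    weights: Mapping[str, int],
    extra_genes: Iterable[str] = (),
) -> WpiNetwork:
    """Assemble the WPI network from edge lists and co-expression weights.

    The gene universe is the union of all edge endpoints and
    ``extra_genes``.  Self-loops are dropped (logged), duplicate edges are
    deduplicated within each edge kind, and genes without a weight entry
    get weight 0.
    """
    ppi_set: Set[FrozenSet[str]] = set()
    n_self = 0
    for u, v in ppi_edges:
        if u == v:
            n_self += 1
            continue
        ppi_set.add(frozenset((u, v)))
    reg_set: Set[Tuple[str, str]] = set()
    for u, v in reg_edges:
        if u == v:
            n_self += 1
            continue
        reg_set.add((u, v))
    if n_self:
        logger.info("dropped %d self-loop input edges", n_self)
    if not ppi_set and not reg_set:
        raise ValueError("no physical links: nothing to analyze")

    universe: Set[str] = set(extra_genes)
    for e in ppi_set:
        universe.update(e)
    for u, v in reg_set:
        universe.update((u, v))
    genes = tuple(sorted(universe))

    ppi = nx.Graph()
    ppi.add_nodes_from(genes)
    ppi.add_edges_from(tuple(sorted(e)) for e in ppi_set)
    reg = nx.DiGraph()
    reg.add_nodes_from(genes)
    reg.add_edges_from(reg_set)

    w = {g: int(weights.get(g, 0)) for g in genes}
    return WpiNetwork(genes=genes, weights=w, ppi=ppi, reg=reg)


def build_wpi_from_data(
    expr: ExpressionMatrix,
    ppi_edges: Iterable[Tuple[str, str]],
    reg_edges: Iterable[Tuple[str, str]],
    threshold: float = DEFAULT_COEXPR_THRESHOLD,
    extra_genes: Iterable[str] = (),
) -> WpiNetwork:
    """End-to-end stage 1: co-expression network -> weights -> WPI network."""
    coexp = build_coexpression_network(expr, threshold=threshold)
    ppi_edges = list(ppi_edges)
    reg_edges = list(reg_edges)
    endpoints: Set[str] = set(extra_genes)
    for u, v in ppi_edges:
        endpoints.update((u, v))
    for u, v in reg_edges:
        endpoints.update((u, v))
    weights = compute_gene_weights(coexp, endpoints)
    return assemble_wpi(ppi_edges, reg_edges, weights, extra_genes=extra_genes)
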