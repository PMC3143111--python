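"""Module-level graphs: the cooperative module network and per-phase
regulator-mediated relationship graphs.

The cooperative module network (CMN) has one node per retained module and
one undirected edge per discovered cooperative pair.  A per-phase
relationship graph routes module crosstalk through that phase's known
regulators: for each (pair, regulator) with the regulator among the
pair's correlated genes, a significant protein association draws an
undirected edge and a significant regulatory association a directed edge
(module -> regulator node when the module's factors regulate it,
regulator node -> module when it regulates the module).  The regulator
node is the module containing the regulator when one exists (one edge
per containing module), otherwise a gene node.  Modules left without any
link are dropped from the phase graph.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx

from .correlated import CorrelatedGene
from .discovery import DiscoveryResult
from .evaluation import GeneSet
from .scoring import Module, ModulePair

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2", "M")


def module_node(module_id: int) -> str:
    return f"module:{module_id}"


def gene_node(gene: str) -> str:
    return f"gene:{gene}"


def build_cmn(result: DiscoveryResult) -> nx.Graph:
    """Cooperative module network: modules as nodes, pairs as undirected edges."""
    g = nx.Graph()
    for m in result.modules:
        g.add_node(module_node(m.id), size=len(m), label=f"module {m.id}")
    for idx, pair in enumerate(result.pairs):
        a, b = sorted((pair.m1.id, pair.m2.id))
        if a == b:
            continue
        g.add_edge(module_node(a), module_node(b), pair_id=idx,
                   mcoop_score=pair.mcoop_score)
    return g


def _regulator_endpoints(
    regulator: str, membership: Mapping[str, Sequence[int]]
) -> List[str]:
    """Graph nodes standing for a regulator: its containing modules, else itself."""
    mods = membership.get(regulator, ())
    if mods:
        return [module_node(mid) for mid in mods]
    return [gene_node(regulator)]


def build_phase_graph(
    pairs: Sequence[ModulePair],
    correlated: Sequence[CorrelatedGene],
    regulators: GeneSet,
    membership: Mapping[str, Sequence[int]],
    phase: str,
    alpha: float = 0.05,
) -> nx.MultiDiGraph:
    """Relationship graph for one cell-cycle phase.

    ``correlated`` holds the correlated genes of every pair, with
    ``pair_id`` indexing into ``pairs``.  ``membership`` maps a gene to
    the ids of modules containing it.  Undirected (protein) edges are
    stored once with attribute ``directed=False``.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    g = nx.MultiDiGraph(phase=phase)
    by_pair: Dict[int, List[CorrelatedGene]] = {}
    for cg in correlated:
        by_pair.setdefault(cg.pair_id, []).append(cg)

    seen_edges: Dict[Tuple[str, str, bool, str], List[str]] = {}

    def add_edge(u: str, v: str, directed: bool, kind: str, regulator: str, pair_id: int) -> None:
        if u == v:
            return
        key = (u, v, directed, kind) if directed else (*sorted((u, v)), False, kind)
        if key in seen_edges:
            if regulator not in seen_edges[key]:
                seen_edges[key].append(regulator)
            return
        seen_edges[key] = [regulator]
        uu, vv = (u, v) if directed else (key[0], key[1])
        g.add_edge(uu, vv, directed=directed, kind=kind, pair_id=pair_id,
                   regulator=regulator, phase=phase)

    for pair_id, cgs in by_pair.items():
        pair = pairs[pair_id]
        module_ids = {"m1": pair.m1.id, "m2": pair.m2.id}
        for cg in cgs:
            x = cg.gene
            if x not in regulators.genes:
                continue
            x_nodes = _regulator_endpoints(x, membership)
            for side, mid in module_ids.items():
                mnode = module_node(mid)
                p_ppi = cg.p_values[f"ppi_{side}"]
                p_in = cg.p_values[f"reg_in_{side}"]  # module regulates x
                p_out = cg.p_values[f"reg_out_{side}"]  # x regulates module
                for xn in x_nodes:
                    if p_ppi <= alpha:
                        add_edge(xn, mnode, False, "ppi", x, pair_id)
                    if p_out <= alpha:
                        add_edge(xn, mnode, True, "transcriptional", x, pair_id)
                    if p_in <= alpha:
                        add_edge(mnode, xn, True, "transcriptional", x, pair_id)

    # attach the regulator list per edge and drop isolated nodes
    for u, v, k, data in g.edges(keys=True, data=True):
        key = (u, v, data["directed"], data["kind"]) if data["directed"] else (
            *sorted((u, v)), False, data["kind"])
        data["regulators"] = ",".join(sorted(seen_edges.get(key, [data["regulator"]])))
    g.remove_nodes_from(list(nx.isolates(g)))
    return g


def export_graph(graph: nx.Graph, path: str, fmt: str = "graphml") -> None:
    """Write a graph as graphml (lossless), sif, or a TSV edge list."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                kind = data.get("kind", "link")
                fh.write(f"{u}\t{kind}\t{v}\n")
            for node in nx.isolates(graph):
                fh.write(f"{node}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# source\ttarget\tdirected\ttype\tphase\tregulator\tpair_id\n")
            for u, v, data in graph.edges(data=True):
                fh.write(
                    "\t".join(
                        [
                            u,
                            v,
                            str(data.get("directed", False)),
                            str(data.get("kind", "link")),
                            str(data.get("phase", "")),
                            str(data.get("regulators", data.get("regulator", ""))),
                            str(data.get("pair_id", "")),
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown export format {fmt!r}")
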