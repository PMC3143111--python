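"""Readers and writers for the tool's tabular formats.

All tables are TSV; output tables carry a '#'-prefixed schema header
line.  Gene ids are opaque case-sensitive strings (yeast systematic
names in the original datasets).  Gene sets are accepted as GMT
(name, description, genes...) or two-column (set, gene) TSV.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .correlated import CorrelatedGene
from .discovery import DiscoveryResult
from .evaluation import EnrichmentResult, GeneSet
from .network import ExpressionMatrix, WpiNetwork
from .scoring import Module, ModulePair

logger = logging.getLogger(__name__)


def read_expression(path: str) -> ExpressionMatrix:
    """TSV with gene ids in the first column and condition labels in the header."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix.from_frame(frame)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_edge_list(path: str) -> List[Tuple[str, str]]:
    """Two-column TSV edge list; '#' comment lines ignored."""
    edges: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated ids")
            edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges: Iterable[Tuple[str, str]], path: str,
                    header: str = "# source\ttarget") -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_gene_sets(path: str, fmt: str | None = None) -> List[GeneSet]:
    """Parse gene sets from GMT or two-column TSV (format guessed from suffix)."""
    if fmt is None:
        fmt = "gmt" if str(path).endswith(".gmt") else "tsv"
    if fmt not in ("gmt", "tsv"):
        raise ValueError(f"unknown gene-set format {fmt!r}")
    sets: Dict[str, List[str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if fmt == "gmt":
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT rows need name, description and >= 1 gene"
                    )
                name, genes = parts[0], [g for g in parts[2:] if g]
            else:
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ValueError(f"{path}:{lineno}: expected (set, gene) columns")
                name, genes = parts[0], [parts[1]]
            if name not in sets:
                sets[name] = []
                order.append(name)
            for g in genes:
                if g in sets[name]:
                    logger.warning("%s:%d: duplicate gene %s in set %s", path, lineno, g, name)
                else:
                    sets[name].append(g)
    if not order:
        raise ValueError(f"{path}: no gene sets found")
    return [GeneSet(name=n, genes=frozenset(sets[n])) for n in order]


def write_gene_sets_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tcoopmod\t{genes}\n")


def write_wpi(net: WpiNetwork, edge_path: str, node_path: str) -> None:
    """WPI network as an edge table (source, target, kind) + node weight table."""
    with open(edge_path, "w") as fh:
        fh.write("# source\ttarget\tkind\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.ppi.edges()):
            fh.write(f"{u}\t{v}\tppi\n")
        for u, v in sorted(net.reg.edges()):
            fh.write(f"{u}\t{v}\treg\n")
    with open(node_path, "w") as fh:
        fh.write("# gene\tweight\tn_links\n")
        for g in net.genes:
            fh.write(f"{g}\t{net.weights[g]}\t{net.nl[g]}\n")


def read_wpi(edge_path: str, node_path: str) -> WpiNetwork:
    from .network import assemble_wpi

    ppi: List[Tuple[str, str]] = []
    reg: List[Tuple[str, str]] = []
    with open(edge_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{edge_path}:{lineno}: expected 3 columns")
            if parts[2] == "ppi":
                ppi.append((parts[0], parts[1]))
            elif parts[2] == "reg":
                reg.append((parts[0], parts[1]))
            else:
                raise ValueError(f"{edge_path}:{lineno}: unknown kind {parts[2]!r}")
    weights: Dict[str, int] = {}
    with open(node_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            weights[parts[0]] = int(parts[1])
    return assemble_wpi(ppi, reg, weights, extra_genes=weights.keys())


def write_modules_gmt(modules: Sequence[Module], path: str) -> None:
    write_gene_sets_gmt({f"module_{m.id}": m.genes for m in modules}, path)


def write_pairs(pairs: Sequence[ModulePair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# pair_id\tmodule1_id\tmodule2_id\tseed_s\tseed_t\tmcoop_score\tmerged\n")
        for idx, p in enumerate(pairs):
            fh.write(
                f"{idx}\t{p.m1.id}\t{p.m2.id}\t{p.seed.s}\t{p.seed.t}"
                f"\t{p.mcoop_score:.6g}\t{int(p.merged)}\n"
            )


def write_correlated(genes: Sequence[CorrelatedGene], path: str) -> None:
    cols = ["ppi_m1", "ppi_m2", "reg_in_m1", "reg_in_m2", "reg_out_m1", "reg_out_m2"]
    with open(path, "w") as fh:
        fh.write("# pair_id\tgene\tcoop_type\tall_types\t" + "\t".join("p_" + c for c in cols) + "\n")
        for cg in genes:
            ps = "\t".join(f"{cg.p_values[c]:.6g}" for c in cols)
            fh.write(f"{cg.pair_id}\t{cg.gene}\t{cg.coop_type}\t{''.join(cg.all_types)}\t{ps}\n")


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# pair_id\tset\tG\tB\tC\tb\tp_value\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.pair_id}\t{r.set_name}\t{r.G}\t{r.B}\t{r.C}\t{r.b}"
                f"\t{r.p_value:.6g}\t{int(r.significant)}\n"
            )


def load_phase_regulators() -> Dict[str, Set[str]]:
    """Packaged per-phase regulator lists (transcription factors, the
    cyclin-dependent kinase, cyclins and cell-division-cycle genes)."""
    text = resources.files("coopmod.data").joinpath("phase_regulators.tsv").read_text()
    out: Dict[str, Set[str]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        phase, gene, _cls = line.split("\t")
        out.setdefault(phase, set()).add(gene)
    return out


def read_phase_regulators(path: str) -> Dict[str, Set[str]]:
    """User-supplied per-phase regulator table (phase, gene[, class])."""
    out: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected (phase, gene) columns")
            out.setdefault(parts[0], set()).add(parts[1])
    if not out:
        raise ValueError(f"{path}: no regulators found")
    return out
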