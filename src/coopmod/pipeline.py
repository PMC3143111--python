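"""End-to-end pipeline: network construction -> discovery -> correlated
genes -> gene-set evaluation -> relationship graphs.

A single run is driven by a :class:`RunConfig` (serializable to YAML or
JSON; unknown keys are rejected).  One global ``rng_seed`` fans out to
per-stage seeds by stable hashing of the stage name, so stages are
independently reproducible.  Reruns with identical inputs, config and
seed produce byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import yaml

from . import io as cio
from .correlated import (
    CorrelatedGene,
    NullModelConfig,
    identify_correlated_genes_for_pairs,
)
from .discovery import DiscoveryConfig, DiscoveryResult, discover
from .evaluation import EnrichmentResult, GeneSet, pair_geneset_significance, rank_phase_pairs
from .graphs import PHASES, build_cmn, build_phase_graph, export_graph
from .network import DEFAULT_COEXPR_THRESHOLD, build_wpi_from_data
from .simulate import FixtureConfig, generate_fixture

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    expression: str = ""
    ppi_edges: str = ""
    reg_edges: str = ""
    gene_sets: str = ""
    phase_regulators: str = ""  # empty -> packaged table
    out_dir: str = "coopmod_out"
    rng_seed: int = 0
    coexpr_threshold: float = DEFAULT_COEXPR_THRESHOLD
    alpha: float = 0.05
    log_level: str = "INFO"
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    nulls: NullModelConfig = field(default_factory=NullModelConfig)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        disc = raw.pop("discovery", {})
        nulls = raw.pop("nulls", {})
        for sub, sub_cls, name in ((disc, DiscoveryConfig, "discovery"),
                                   (nulls, NullModelConfig, "nulls")):
            bad = set(sub) - set(sub_cls.__dataclass_fields__)
            if bad:
                raise ValueError(f"unknown {name} config keys: {sorted(bad)}")
        return cls(discovery=DiscoveryConfig(**disc), nulls=NullModelConfig(**nulls), **raw)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunReport:
    version: str
    config: dict
    counts: Dict[str, int]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "counts": self.counts,
             "started": self.started, "finished": self.finished},
            indent=2, sort_keys=True,
        )


def run_all(cfg: RunConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``cfg.out_dir``."""
    from . import __version__

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, int] = {}

    # stage 1: network construction
    try:
        expr = cio.read_expression(cfg.expression)
        ppi_edges = cio.read_edge_list(cfg.ppi_edges)
        reg_edges = cio.read_edge_list(cfg.reg_edges)
    except OSError as exc:
        raise RuntimeError(f"[network_construction] cannot read input: {exc}") from exc
    net = build_wpi_from_data(expr, ppi_edges, reg_edges, threshold=cfg.coexpr_threshold)
    cio.write_wpi(net, str(out / "wpi_edges.tsv"), str(out / "wpi_nodes.tsv"))
    counts["genes"] = net.n
    counts["ppi_edges"] = net.ppi.number_of_edges()
    counts["reg_edges"] = net.reg.number_of_edges()

    # stage 2: discovery
    result = discover(net, cfg.discovery)
    counts["seeds"] = len(result.provenance)
    counts["pairs_before_filter"] = len(result.provenance)
    counts["modules"] = len(result.modules)
    counts["pairs"] = len(result.pairs)
    cio.write_modules_gmt(result.modules, str(out / "modules.gmt"))
    cio.write_pairs(result.pairs, str(out / "pairs.tsv"))
    (out / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2, sort_keys=True)
    )

    # stage 3: correlated genes
    null_cfg = NullModelConfig(
        n_random=cfg.nulls.n_random, swaps_per_edge=cfg.nulls.swaps_per_edge,
        alpha=cfg.nulls.alpha, rng_seed=stage_seed(cfg.rng_seed, "correlated"),
    )
    correlated: List[CorrelatedGene] = identify_correlated_genes_for_pairs(
        net, result.pairs, null_cfg
    )
    counts["correlated_genes"] = len(correlated)
    cio.write_correlated(correlated, str(out / "correlated_genes.tsv"))

    # stage 4: gene-set evaluation
    enrichment: List[EnrichmentResult] = []
    if cfg.gene_sets:
        gene_sets = cio.read_gene_sets(cfg.gene_sets)
        universe = net.n
        by_pair: Dict[int, Set[str]] = {}
        for cg in correlated:
            by_pair.setdefault(cg.pair_id, set()).add(cg.gene)
        for pair_id in range(len(result.pairs)):
            genes = by_pair.get(pair_id, set())
            for gs in gene_sets:
                restricted = frozenset(gs.genes) & set(net.genes)
                if not restricted:
                    continue
                enrichment.append(
                    pair_geneset_significance(
                        genes & set(net.genes), GeneSet(gs.name, frozenset(restricted)),
                        universe, pair_id=pair_id, alpha=cfg.alpha,
                    )
                )
        cio.write_enrichment(enrichment, str(out / "enrichment.tsv"))
        phase_results = [r for r in enrichment if r.set_name.startswith("phase_")]
        ranked = rank_phase_pairs(phase_results)
        with open(out / "phase_ranking.tsv", "w") as fh:
            fh.write("# phase\trank\tpair_id\tb\tp_value\n")
            for phase in sorted(ranked):
                for rank, r in enumerate(ranked[phase], 1):
                    fh.write(f"{phase}\t{rank}\t{r.pair_id}\t{r.b}\t{r.p_value:.6g}\n")
    counts["significant_set_pairs"] = sum(r.significant for r in enrichment)

    # stage 4b: within/between-module correlation significance
    from .evaluation import module_correlation_significance

    corr_cfg = NullModelConfig(
        n_random=cfg.nulls.n_random, swaps_per_edge=cfg.nulls.swaps_per_edge,
        alpha=cfg.nulls.alpha, rng_seed=stage_seed(cfg.rng_seed, "module_correlation"),
    )
    per_module, per_pair = module_correlation_significance(
        net, expr, result.modules, result.pairs, corr_cfg,
        threshold=cfg.coexpr_threshold,
    )
    with open(out / "correlation_significance.tsv", "w") as fh:
        fh.write("# object\tid\twithin_physical_p\twithin_coexpr_p"
                 "\tbetween_physical_p\tbetween_coexpr_p\n")
        for mid in sorted(per_module):
            row = per_module[mid]
            fh.write(f"module\t{mid}\t{row['within_physical_p']:.6g}"
                     f"\t{row['within_coexpr_p']:.6g}\t\t\n")
        for key in sorted(per_pair):
            row = per_pair[key]
            fh.write(f"pair\t{key[0]}-{key[1]}\t\t"
                     f"\t{row['between_physical_p']:.6g}"
                     f"\t{row['between_coexpr_p']:.6g}\n")

    # stage 5: graphs
    cmn = build_cmn(result)
    export_graph(cmn, str(out / "cmn.graphml"), "graphml")
    export_graph(cmn, str(out / "cmn.tsv"), "tsv")
    regulators = (
        cio.read_phase_regulators(cfg.phase_regulators)
        if cfg.phase_regulators
        else cio.load_phase_regulators()
    )
    membership: Dict[str, List[int]] = {}
    for m in result.modules:
        for g in m.genes:
            membership.setdefault(g, []).append(m.id)
    for phase in PHASES:
        regs = regulators.get(phase, set())
        if not regs:
            continue
        graph = build_phase_graph(
            result.pairs, correlated, GeneSet(f"regulators_{phase}", frozenset(regs)),
            membership, phase, alpha=cfg.alpha,
        )
        export_graph(graph, str(out / f"phase_{phase}.graphml"), "graphml")
        export_graph(graph, str(out / f"phase_{phase}.tsv"), "tsv")

    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report = RunReport(
        version=__version__, config=cfg.to_dict(), counts=counts,
        started=started, finished=finished,
    )
    (out / "report.json").write_text(report.to_json())
    return report


def write_fixture_inputs(
    out_dir: str,
    cfg: Optional[FixtureConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, str], dict]:
    """Generate the synthetic fixture and write its four input files.

    Returns ``(paths, truth_dict)``; also writes ``truth.json``.
    """
    cfg = cfg or FixtureConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, ppi_edges, reg_edges, gene_sets, truth = generate_fixture(cfg, rng)
    paths = {
        "expression": str(out / "expression.tsv"),
        "ppi_edges": str(out / "ppi_edges.tsv"),
        "reg_edges": str(out / "reg_edges.tsv"),
        "gene_sets": str(out / "gene_sets.gmt"),
    }
    cio.write_expression(expr, paths["expression"])
    cio.write_edge_list(ppi_edges, paths["ppi_edges"], header="# gene_a\tgene_b")
    cio.write_edge_list(reg_edges, paths["reg_edges"], header="# tf\ttarget")
    cio.write_gene_sets_gmt(gene_sets, paths["gene_sets"])
    truth_dict = {
        "module1": truth.module1, "module2": truth.module2,
        "mediators": truth.mediators, "tf": truth.tf,
        "tf_targets": sorted(truth.tf_targets),
        "mediator_phases": truth.mediator_phases,
    }
    (out / "truth.json").write_text(json.dumps(truth_dict, indent=2, sort_keys=True))
    return paths, truth_dict
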