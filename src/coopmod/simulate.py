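"""Synthetic benchmark data with planted cooperative module pairs.

The generator emulates the four input data types at a small, controlled
scale: two dense planted protein-interaction modules, a handful of
mediator genes physically linked to a fixed fraction of both modules, an
optional planted transcription factor regulating members of both
modules, a sparse random background, and an expression matrix in which
planted genes (modules + mediators) share a common latent profile plus
independent Gaussian noise while background genes are pure noise.

At zero noise every planted-gene pair is perfectly correlated, so every
planted gene's co-expression degree (and hence WPI weight) is at least
the number of other planted genes; at the default noise level (sd 0.2,
signal sd 1) planted pairwise correlations stay far above the 0.683
edge threshold while background pairs rarely cross it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .network import ExpressionMatrix

PHASES = ("G1", "S", "G2", "M")


@dataclass
class FixtureConfig:
    n_background_genes: int = 200
    module_sizes: Tuple[int, int] = (8, 8)
    n_mediators: int = 3
    within_module_edge_prob: float = 0.85
    background_edge_prob: float = 0.015
    mediator_link_fraction: float = 0.625
    n_conditions: int = 17
    coexpr_noise_sd: float = 0.2
    planted_tf: bool = True
    rng_seed: int = 0
    # regulatory background so the directed null ensemble can actually mix
    n_background_tfs: int = 6
    background_reg_prob: float = 0.04

    def __post_init__(self) -> None:
        for p in (self.within_module_edge_prob, self.background_edge_prob,
                  self.mediator_link_fraction, self.background_reg_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.module_sizes) < 3:
            raise ValueError("module sizes must be >= 3")
        if self.n_conditions < 6:
            raise ValueError("n_conditions must be >= 6")


@dataclass
class FixtureTruth:
    module1: List[str]
    module2: List[str]
    mediators: List[str]
    tf: Optional[str]
    tf_targets: List[str]
    mediator_phases: Dict[str, str] = field(default_factory=dict)

    @property
    def planted_genes(self) -> Set[str]:
        out = set(self.module1) | set(self.module2) | set(self.mediators)
        if self.tf:
            out.add(self.tf)
        return out


def _gene_names(cfg: FixtureConfig) -> Tuple[List[str], List[str], List[str], List[str]]:
    m1 = [f"M1G{i:02d}" for i in range(cfg.module_sizes[0])]
    m2 = [f"M2G{i:02d}" for i in range(cfg.module_sizes[1])]
    med = [f"MED{i}" for i in range(cfg.n_mediators)]
    bg = [f"BG{i:03d}" for i in range(cfg.n_background_genes)]
    return m1, m2, med, bg


def generate_network_fixture(
    cfg: FixtureConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[Tuple[str, str]], List[Tuple[str, str]], FixtureTruth]:
    """Protein and regulatory edge lists with a planted cooperative pair."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    m1, m2, mediators, background = _gene_names(cfg)

    ppi: Set[frozenset] = set()

    def add(u: str, v: str) -> None:
        if u != v:
            ppi.add(frozenset((u, v)))

    # dense planted modules; a backbone path guarantees connectivity
    for module in (m1, m2):
        for a, b in zip(module, module[1:]):
            add(a, b)
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < cfg.within_module_edge_prob:
                    add(module[i], module[j])

    # mediators touch a fixed fraction of both modules
    k1 = max(1, int(np.ceil(cfg.mediator_link_fraction * len(m1))))
    k2 = max(1, int(np.ceil(cfg.mediator_link_fraction * len(m2))))
    for med in mediators:
        for target in rng.choice(m1, size=k1, replace=False):
            add(med, str(target))
        for target in rng.choice(m2, size=k2, replace=False):
            add(med, str(target))

    # sparse background: edges among background genes and from background
    # to planted genes
    planted = m1 + m2
    for i in range(len(background)):
        for j in range(i + 1, len(background)):
            if rng.random() < cfg.background_edge_prob:
                add(background[i], background[j])
        for g in planted:
            if rng.random() < cfg.background_edge_prob:
                add(background[i], g)

    # regulatory edges
    reg: Set[Tuple[str, str]] = set()
    tf: Optional[str] = None
    tf_targets: List[str] = []
    if cfg.planted_tf:
        tf = "TF0"
        half1 = max(1, len(m1) // 2)
        half2 = max(1, len(m2) // 2)
        tf_targets = [str(g) for g in rng.choice(m1, size=half1, replace=False)]
        tf_targets += [str(g) for g in rng.choice(m2, size=half2, replace=False)]
        for g in tf_targets:
            reg.add((tf, g))
    bg_tfs = background[: cfg.n_background_tfs]
    for btf in bg_tfs:
        for g in background:
            if g != btf and rng.random() < cfg.background_reg_prob:
                reg.add((btf, g))

    phases = {med: PHASES[i % len(PHASES)] for i, med in enumerate(mediators)}
    truth = FixtureTruth(
        module1=m1, module2=m2, mediators=mediators, tf=tf,
        tf_targets=tf_targets, mediator_phases=phases,
    )
    ppi_edges = sorted(tuple(sorted(e)) for e in ppi)
    return ppi_edges, sorted(reg), truth


def generate_expression_fixture(
    cfg: FixtureConfig,
    truth: FixtureTruth,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Expression matrix: shared latent profile for planted genes, noise elsewhere."""
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 1)
    m1, m2, mediators, background = _gene_names(cfg)
    genes = m1 + m2 + mediators + background
    if truth.tf:
        genes = genes + [truth.tf]
    n_cond = cfg.n_conditions
    # one shared periodic latent signal (unit sd) for the planted structure
    t = np.arange(n_cond)
    latent = np.sqrt(2.0) * np.sin(2.0 * np.pi * t / max(8, n_cond // 2))
    shared = set(m1) | set(m2) | set(mediators)
    rows = []
    for g in genes:
        if g in shared:
            rows.append(latent + cfg.coexpr_noise_sd * rng.standard_normal(n_cond))
        else:
            rows.append(rng.standard_normal(n_cond))
    frame = pd.DataFrame(
        np.asarray(rows), index=genes,
        columns=[f"t{i:02d}" for i in range(n_cond)],
    )
    return ExpressionMatrix.from_frame(frame)


def generate_gene_set_fixtures(
    cfg: FixtureConfig,
    truth: FixtureTruth,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, Set[str]]:
    """Reference gene sets mirroring a process-related set and per-phase groups.

    The process set holds every planted gene plus a random tenth of the
    background; each phase set holds the mediators assigned to that phase
    plus a small random background group.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed + 2)
    _, _, _, background = _gene_names(cfg)
    n_decoys = max(1, cfg.n_background_genes // 10)
    decoys = [str(g) for g in rng.choice(background, size=n_decoys, replace=False)]
    sets: Dict[str, Set[str]] = {
        "process_related": set(truth.planted_genes) | set(decoys)
    }
    for phase in PHASES:
        members = {m for m, ph in truth.mediator_phases.items() if ph == phase}
        extra = [str(g) for g in rng.choice(background, size=max(2, n_decoys // 4),
                                            replace=False)]
        sets[f"phase_{phase}"] = members | set(extra)
    return sets


def generate_fixture(
    cfg: Optional[FixtureConfig] = None,
    rng: Optional[np.random.Generator] = None,
):
    """All four synthetic inputs plus ground truth.

    Returns ``(expr, ppi_edges, reg_edges, gene_sets, truth)``.
    """
    cfg = cfg or FixtureConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    ppi_edges, reg_edges, truth = generate_network_fixture(cfg, rng)
    expr = generate_expression_fixture(cfg, truth, rng)
    gene_sets = generate_gene_set_fixtures(cfg, truth, rng)
    return expr, ppi_edges, reg_edges, gene_sets, truth
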