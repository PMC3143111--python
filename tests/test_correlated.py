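import collections

import numpy as np
import pytest

from coopmod.correlated import (
    NullModelConfig,
    classify_cooperation_type,
    empirical_pvalues,
    identify_correlated_genes,
    link_count_pvalue,
    null_count_ensemble,
    rewire_degree_preserving,
)
from coopmod.network import assemble_wpi
from coopmod.scoring import Module, ModulePair, Seed

from .conftest import random_wpi


def _pvals(**kw):
    base = {k: 1.0 for k in
            ("ppi_m1", "ppi_m2", "reg_in_m1", "reg_in_m2", "reg_out_m1", "reg_out_m2")}
    base.update(kw)
    return base


class TestRewiring:
    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            net = random_wpi(rng, n_genes=12, ppi_prob=0.3, reg_prob=0.15)
            null = rewire_degree_preserving(net, rng)
            assert dict(null.ppi.degree()) == dict(net.ppi.degree())
            assert dict(null.reg.in_degree()) == dict(net.reg.in_degree())
            assert dict(null.reg.out_degree()) == dict(net.reg.out_degree())
            # still simple graphs
            assert all(u != v for u, v in null.ppi.edges())
            assert all(u != v for u, v in null.reg.edges())

    def test_four_cycle_reaches_both_configurations(self):
        # a-b, c-d, a-d, b-c admits exactly one alternative perfect
        # matching of swaps; both configurations must occur over many
        # seeded rewirings
        net = assemble_wpi([("a", "b"), ("c", "d"), ("a", "d"), ("b", "c")], [], {})
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(200):
            null = rewire_degree_preserving(net, rng)
            seen.add(frozenset(frozenset(e) for e in null.ppi.edges()))
        expected_a = frozenset(
            frozenset(e) for e in [("a", "b"), ("c", "d"), ("a", "d"), ("b", "c")]
        )
        expected_b = frozenset(
            frozenset(e) for e in [("a", "c"), ("b", "d"), ("a", "d"), ("b", "c")]
        )
        # the 4-cycle's degree sequence admits exactly 3 labelled simple
        # graphs; the double-edge swap can reach the two containing no
        # triangle-breaking move
        assert expected_a in seen
        assert len(seen) >= 2
        for config in seen:
            deg = collections.Counter()
            for e in config:
                for v in e:
                    deg[v] += 1
            assert deg == {"a": 2, "b": 2, "c": 2, "d": 2}


class TestPvalues:
    def test_observed_zero_gives_p_one(self):
        net = assemble_wpi([("a", "b"), ("c", "d")], [], {})
        cfg = NullModelConfig(n_random=50, rng_seed=3)
        # gene c has no links to module {a, b}: every null count >= 0
        assert link_count_pvalue(net, "c", ["a", "b"], "ppi", cfg) == 1.0

    def test_unattainable_count_gives_minimum(self):
        # hub linked to every member of a module whose members have no
        # other partners: rewiring must scatter the hub's stubs, so the
        # observed count is never matched
        ppi = [("hub", f"m{i}") for i in range(4)]
        ppi += [(f"o{i}", f"q{i}") for i in range(6)]  # swap material
        net = assemble_wpi(ppi, [], {})
        cfg = NullModelConfig(n_random=200, rng_seed=5)
        p = link_count_pvalue(net, "hub", [f"m{i}" for i in range(4)], "ppi", cfg)
        assert p == pytest.approx(1.0 / 201.0)

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(11)
        null = rng.integers(0, 5, size=(100, 1, 1, 1))
        prev = None
        for obs in range(6):
            p = empirical_pvalues(np.array([[[obs]]]), null)[0, 0, 0]
            assert 1.0 / 101.0 <= p <= 1.0
            if prev is not None:
                assert p <= prev
            prev = p

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        net = random_wpi(rng, n_genes=10, ppi_prob=0.3, reg_prob=0.1)
        cfg = NullModelConfig(n_random=30, rng_seed=42)
        module = list(net.genes)[:3]
        p1 = link_count_pvalue(net, list(net.genes)[5], module, "ppi", cfg)
        p2 = link_count_pvalue(net, list(net.genes)[5], module, "ppi", cfg)
        assert p1 == p2


class TestClassification:
    def test_figure_patterns(self):
        assert classify_cooperation_type(
            _pvals(ppi_m1=0.01, reg_in_m2=0.01), 0.05
        ) == ("A", ("A",))
        assert classify_cooperation_type(
            _pvals(ppi_m1=0.01, reg_out_m2=0.01), 0.05
        ) == ("B", ("B",))
        assert classify_cooperation_type(
            _pvals(ppi_m1=0.01, ppi_m2=0.04), 0.05
        ) == ("C", ("C",))
        assert classify_cooperation_type(
            _pvals(reg_in_m1=0.01, reg_in_m2=0.01), 0.05
        ) == ("D", ("D",))
        assert classify_cooperation_type(
            _pvals(reg_out_m1=0.01, reg_out_m2=0.01), 0.05
        ) == ("E", ("E",))

    def test_priority_on_multiple_patterns(self):
        primary, all_types = classify_cooperation_type(
            _pvals(ppi_m1=0.01, ppi_m2=0.01, reg_in_m1=0.01, reg_in_m2=0.01), 0.05
        )
        assert primary == "C"
        assert set(all_types) >= {"C", "D", "A"}

    def test_no_pattern_raises(self):
        with pytest.raises(ValueError):
            classify_cooperation_type(_pvals(reg_in_m1=0.01, reg_out_m2=0.01), 0.05)


class TestIdentifyCorrelatedGenes:
    def _planted_net(self):
        # two 4-cliques plus a mediator linked to every member of both,
        # and background edges providing swap material
        m1 = [f"a{i}" for i in range(4)]
        m2 = [f"b{i}" for i in range(4)]
        ppi = [(x, y) for i, x in enumerate(m1) for y in m1[i + 1:]]
        ppi += [(x, y) for i, x in enumerate(m2) for y in m2[i + 1:]]
        ppi += [("med", g) for g in m1 + m2]
        rng = np.random.default_rng(0)
        bg = [f"z{i}" for i in range(20)]
        for i in range(len(bg)):
            for j in range(i + 1, len(bg)):
                if rng.random() < 0.12:
                    ppi.append((bg[i], bg[j]))
        net = assemble_wpi(ppi, [], {})
        pair = ModulePair(
            m1=Module(id=0, genes=m1, anchor=m1[0]),
            m2=Module(id=1, genes=m2, anchor=m2[0]),
            seed=Seed(m1[0], m2[0], 0.0),
        )
        return net, pair

    def test_planted_mediator_found_and_typed_c(self):
        net, pair = self._planted_net()
        cfg = NullModelConfig(n_random=200, rng_seed=9)
        found = identify_correlated_genes(net, pair, cfg)
        by_gene = {cg.gene: cg for cg in found}
        assert "med" in by_gene
        assert by_gene["med"].coop_type == "C"

    def test_one_sided_gene_excluded(self):
        net, pair = self._planted_net()
        cfg = NullModelConfig(n_random=100, rng_seed=9)
        found = identify_correlated_genes(net, pair, cfg)
        # module members link only their own module (plus med): genes of
        # m1 must not appear unless significant to m2 as well
        for cg in found:
            assert min(cg.p_values["ppi_m1"], cg.p_values["reg_in_m1"],
                       cg.p_values["reg_out_m1"]) <= cfg.alpha
            assert min(cg.p_values["ppi_m2"], cg.p_values["reg_in_m2"],
                       cg.p_values["reg_out_m2"]) <= cfg.alpha

    def test_deterministic_for_fixed_seed(self):
        net, pair = self._planted_net()
        cfg = NullModelConfig(n_random=60, rng_seed=33)
        r1 = identify_correlated_genes(net, pair, cfg)
        r2 = identify_correlated_genes(net, pair, cfg)
        assert [(c.gene, c.coop_type, c.p_values) for c in r1] == [
            (c.gene, c.coop_type, c.p_values) for c in r2
        ]

    def test_label_equivariance(self):
        net, pair = self._planted_net()
        cfg = NullModelConfig(n_random=80, rng_seed=3)
        found = {cg.gene for cg in identify_correlated_genes(net, pair, cfg)}
        # relabel genes by a fixed prefix swap and rebuild
        def rel(g):
            return "X" + g

        ppi = [(rel(u), rel(v)) for u, v in net.ppi.edges()]
        reg = [(rel(u), rel(v)) for u, v in net.reg.edges()]
        net2 = assemble_wpi(ppi, reg, {rel(g): w for g, w in net.weights.items()},
                            extra_genes=[rel(g) for g in net.genes])
        pair2 = ModulePair(
            m1=Module(id=0, genes=[rel(g) for g in pair.m1.genes], anchor=rel(pair.m1.anchor)),
            m2=Module(id=1, genes=[rel(g) for g in pair.m2.genes], anchor=rel(pair.m2.anchor)),
            seed=Seed(rel(pair.seed.s), rel(pair.seed.t), 0.0),
        )
        found2 = {cg.gene for cg in identify_correlated_genes(net2, pair2, cfg)}
        assert found2 == {rel(g) for g in found}
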