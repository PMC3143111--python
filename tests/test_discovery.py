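import numpy as np
import pytest

from coopmod.discovery import (
    DiscoveryConfig,
    discover,
    enumerate_seed_candidates,
    filter_pairs,
    merge_overlapping_modules,
    score_seed_pairs,
    select_seeds,
    span_module_pair,
)
from coopmod.network import assemble_wpi
from coopmod.scoring import Module, ModulePair, Seed, consistency_score

from .conftest import random_wpi
from .oracles import exhaustive_best_pair, naive_consistency


class TestSeedCandidates:
    def test_t1_includes_bridged_pair(self, t1_network):
        assert ("s", "t") in enumerate_seed_candidates(t1_network)

    def test_star_network_leaf_pairs(self):
        ppi = [("c", f"l{i}") for i in range(4)]
        net = assemble_wpi(ppi, [], {"c": 2, "l0": 1, "l1": 1, "l2": 1, "l3": 1})
        cands = set(enumerate_seed_candidates(net))
        for i in range(4):
            for j in range(i + 1, 4):
                assert tuple(sorted((f"l{i}", f"l{j}"))) in cands

    def test_superset_of_nonzero_scores(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            net = random_wpi(rng, n_genes=8)
            cands = set(enumerate_seed_candidates(net))
            genes = list(net.genes)
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    pair = (genes[i], genes[j])
                    if naive_consistency(net, [pair[0]], [pair[1]]) != 0:
                        assert pair in cands

    def test_scored_pairs_match_naive(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_wpi(rng, n_genes=8)
            scores = score_seed_pairs(net)
            genes = list(net.genes)
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    expected = naive_consistency(net, [genes[i]], [genes[j]])
                    assert scores.get((genes[i], genes[j]), 0.0) == expected


class TestSelectSeeds:
    def _net_with_scores(self):
        # reuse T1-like bridging to produce non-zero scores
        ppi = [("s", "a"), ("t", "a"), ("s", "b"), ("a", "b"), ("c", "d")]
        return assemble_wpi(ppi, [], {"s": 1, "t": 1, "a": 5, "b": 2, "c": 0, "d": 3})

    def test_top_percentile_on_distinct_scores(self):
        # 200 distinct positive scores -> strictly above the 99th
        # percentile leaves exactly the top 2
        values = np.arange(1.0, 201.0)
        cutoff = np.percentile(values, 99)
        assert (values > cutoff).sum() == 2

    def test_single_nonzero_pair_yields_no_seed(self):
        ppi = [("s", "a"), ("t", "a")]
        net = assemble_wpi(ppi, [], {"a": 5, "s": 0, "t": 0})
        # only (s, t) scores non-zero; its own percentile equals itself
        assert select_seeds(net, DiscoveryConfig()) == []

    def test_all_zero_scores(self):
        net = assemble_wpi([("a", "b")], [], {})
        assert select_seeds(net, DiscoveryConfig()) == []

    def test_deterministic_order(self):
        net = self._net_with_scores()
        cfg = DiscoveryConfig(seed_percentile=10.0)
        seeds1 = select_seeds(net, cfg)
        seeds2 = select_seeds(net, cfg)
        assert [(s.s, s.t) for s in seeds1] == [(s.s, s.t) for s in seeds2]
        scores = [s.ct_score for s in seeds1]
        assert scores == sorted(scores, reverse=True)


class TestSpanning:
    def test_t1_full_trace(self, t1_network, t1_seed):
        """Faithful chain on T1: b joins (MCoop 7 >= 3, CT rises 3->4, recurse),
        then a joins (MCoop 7.9 >= 7) and the chain stops on the CT drop."""
        pair = span_module_pair(t1_network, t1_seed, DiscoveryConfig())
        assert pair.m1.genes == ["s", "b", "a"]
        assert pair.m2.genes == ["t"]
        assert pair.mcoop_score == pytest.approx(7.9)
        assert set(pair.m1.genes) >= {"s", "b"}

    def test_isolated_seed_genes(self):
        net = assemble_wpi([("a", "b"), ("x", "y")], [], {}, extra_genes=["s", "t"])
        seed = Seed("s", "t", 0.0)
        pair = span_module_pair(net, seed, DiscoveryConfig())
        assert pair.m1.genes == ["s"]
        assert pair.m2.genes == ["t"]
        assert pair.mcoop_score == pytest.approx(0.0)

    def test_rejected_candidate_consumed_from_visit_list(self, t1_network):
        # seed (c, d): c's only neighbour is d (in the other module), so
        # nothing can extend; modules stay singletons
        seed = Seed("c", "d", consistency_score(t1_network, ["c"], ["d"]))
        pair = span_module_pair(t1_network, seed, DiscoveryConfig())
        assert pair.m1.genes == ["c"]
        assert pair.m2.genes == ["d"]

    def test_modules_stay_disjoint_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_wpi(rng, n_genes=10)
            genes = list(net.genes)
            i, j = rng.choice(len(genes), size=2, replace=False)
            s, t = genes[i], genes[j]
            seed = Seed(s, t, consistency_score(net, [s], [t]))
            pair = span_module_pair(net, seed, DiscoveryConfig())
            assert not (pair.m1.gene_set & pair.m2.gene_set)

    def test_never_beats_exhaustive_optimum(self):
        rng = np.random.default_rng(123)
        for _ in range(25):
            n = int(rng.integers(5, 9))
            net = random_wpi(rng, n_genes=n)
            genes = list(net.genes)
            i, j = rng.choice(len(genes), size=2, replace=False)
            s, t = genes[i], genes[j]
            seed = Seed(s, t, consistency_score(net, [s], [t]))
            pair = span_module_pair(net, seed, DiscoveryConfig())
            assert pair.mcoop_score <= exhaustive_best_pair(net, seed) + 1e-9


def _mod(mid, genes):
    return Module(id=mid, genes=list(genes), anchor=list(genes)[0])


class TestMergeAndFilter:
    def test_merge_rule_arithmetic(self):
        mods = [_mod(0, ["1", "2", "3"]), _mod(1, ["1", "2", "3", "9"])]
        merged, mapping = merge_overlapping_modules(mods, DiscoveryConfig())
        assert len(merged) == 1
        assert merged[0].gene_set == {"1", "2", "3", "9"}
        assert mapping == {0: 0, 1: 0}

    def test_exact_two_thirds_boundary_does_not_merge(self):
        mods = [_mod(0, ["1", "2", "3"]), _mod(1, ["2", "3", "4"])]
        merged, mapping = merge_overlapping_modules(mods, DiscoveryConfig())
        assert len(merged) == 2
        assert mapping == {0: 0, 1: 1}

    def test_disjoint_modules_unchanged(self):
        mods = [_mod(0, "abc"), _mod(1, "xyz")]
        merged, mapping = merge_overlapping_modules(mods, DiscoveryConfig())
        assert [m.gene_set for m in merged] == [set("abc"), set("xyz")]
        assert mapping == {0: 0, 1: 1}

    def test_fixpoint_and_idempotence(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(12)]
        mods = []
        for mid in range(8):
            size = int(rng.integers(3, 7))
            genes = rng.choice(universe, size=size, replace=False)
            mods.append(_mod(mid, sorted(genes)))
        cfg = DiscoveryConfig()
        merged, _ = merge_overlapping_modules(mods, cfg)
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                a, b = merged[i].gene_set, merged[j].gene_set
                inter = len(a & b)
                assert not (inter > cfg.overlap_fraction * min(len(a), len(b)))
        again, mapping = merge_overlapping_modules(merged, cfg)
        assert [m.gene_set for m in again] == [m.gene_set for m in merged]
        assert all(mapping[m.id] == m.id for m in merged)

    def test_filter_drops_self_small_and_duplicate_pairs(self, t1_network):
        seed = Seed("s", "t", 3.0)
        m_a = _mod(0, ["s", "a", "b"])
        m_b = _mod(1, ["t", "c", "d"])
        m_small = _mod(2, ["t"])
        cfg = DiscoveryConfig()
        merged = [m_a, m_b]
        mapping = {0: 0, 1: 1, 2: 1, 3: 0}
        pairs = [
            ModulePair(m1=_mod(0, ["s", "a", "b"]), m2=_mod(3, ["x"]), seed=seed, mcoop_score=1.0),  # both -> 0
            ModulePair(m1=m_a, m2=m_small, seed=seed, mcoop_score=2.0),
            ModulePair(m1=m_a, m2=_mod(1, ["t", "c", "d"]), seed=seed, mcoop_score=5.0),
        ]
        out = filter_pairs(pairs, merged, mapping, cfg)
        assert len(out) == 1
        assert out[0].mcoop_score == 5.0  # duplicate resolved by best score

    def test_pair_with_undersized_module_removed(self):
        seed = Seed("s", "t", 1.0)
        small = _mod(0, ["s", "x"])
        big = _mod(1, ["t", "a", "b"])
        out = filter_pairs(
            [ModulePair(m1=small, m2=big, seed=seed, mcoop_score=1.0)],
            [small, big], {0: 0, 1: 1}, DiscoveryConfig(),
        )
        assert out == []


class TestDiscover:
    def test_empty_seed_list_gives_empty_result(self):
        net = assemble_wpi([("a", "b")], [], {})
        res = discover(net)
        assert res.pairs == [] and res.modules == []

    def test_determinism(self):
        rng = np.random.default_rng(8)
        net = random_wpi(rng, n_genes=14, ppi_prob=0.3)
        cfg = DiscoveryConfig(seed_percentile=60.0)
        r1 = discover(net, cfg)
        r2 = discover(net, cfg)
        assert [(p.m1.genes, p.m2.genes) for p in r1.pairs] == [
            (p.m1.genes, p.m2.genes) for p in r2.pairs
        ]
        assert r1.merge_map == r2.merge_map

    def test_result_modules_respect_overlap_fixpoint(self):
        rng = np.random.default_rng(21)
        net = random_wpi(rng, n_genes=16, ppi_prob=0.35)
        cfg = DiscoveryConfig(seed_percentile=50.0)
        res = discover(net, cfg)
        for i in range(len(res.modules)):
            for j in range(i + 1, len(res.modules)):
                a = res.modules[i].gene_set
                b = res.modules[j].gene_set
                assert not (len(a & b) > cfg.overlap_fraction * min(len(a), len(b)))
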