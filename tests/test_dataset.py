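import numpy as np
import pandas as pd
import pytest

from adrnet.dataset import (
    ADRAssociationTable,
    TrainingConfig,
    build_training_sets,
    config_grid,
    diamond_expand,
    filter_associations,
    merge_to_soc,
    read_associations_tsv,
)
from adrnet.features import FeatureVector
from adrnet.propagation import SeedSet

from conftest import graph_from_edges
from oracles import hypergeom_tail, random_connected_graph


def assoc_table(rows):
    return ADRAssociationTable(
        records=pd.DataFrame(rows, columns=["adr_label", "soc_label", "accession"])
    )


def dummy_features(acc):
    return FeatureVector(*([float(len(acc))] * 8))


class TestAssociations:
    def test_read_requires_header(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("nausea\tgastro\tP1\n")
        with pytest.raises(ValueError, match="header"):
            read_associations_tsv(str(p))

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assoc_table([("a1", "s1", "P1"), ("a1", "s1", "P1")])

    def test_filter_drops_small_adrs(self):
        rows = [("big", "s1", f"P{i}") for i in range(12)]
        rows += [("small", "s1", f"P{i}") for i in range(3)]
        out = filter_associations(assoc_table(rows), min_proteins_per_adr=10)
        assert out.adr_labels == ["big"]

    def test_soc_eligibility_flag(self):
        rows = []
        for a in range(4):  # only 4 ADRs in the SOC -> ineligible at min 5
            rows += [(f"adr{a}", "soc1", f"P{a}_{i}") for i in range(10)]
        out = filter_associations(
            assoc_table(rows), min_proteins_per_adr=10, min_adrs_per_soc=5
        )
        assert out.soc_eligible == set()
        assert len(out.adr_labels) == 4  # PT-level models kept

    def test_filter_empty_result_errors(self):
        with pytest.raises(ValueError):
            filter_associations(
                assoc_table([("a", "s", "P1")]), min_proteins_per_adr=10
            )

    def test_merge_to_soc_union(self):
        rows = [("a1", "s1", p) for p in ("P1", "P2", "P3")]
        rows += [("a2", "s1", p) for p in ("P3", "P4", "P5")]
        rows += [("a3", "s2", "P9")]
        merged = merge_to_soc(assoc_table(rows))
        assert merged.proteins_of("s1") == {"P1", "P2", "P3", "P4", "P5"}
        assert merged.proteins_of("s2") == {"P9"}

    def test_soc_set_superset_of_members(self):
        rows = [("a1", "s1", p) for p in ("P1", "P2")]
        rows += [("a2", "s1", p) for p in ("P2", "P3")]
        t = assoc_table(rows)
        merged = merge_to_soc(t)
        for adr in ("a1", "a2"):
            assert t.proteins_of(adr) <= merged.proteins_of("s1")


class TestDiamond:
    def test_worked_hypergeometric_example(self):
        # N=10 nodes, 3 seeds; candidate "c" touches 2 of them and has
        # degree 2 -> p = C(3,2)C(7,0)/C(10,2) = 3/45
        edges = [("s1", "c"), ("s2", "c"), ("s1", "s2")]
        edges += [(f"f{i}", f"f{i+1}") for i in range(5)]
        edges += [("s3", "f0")]
        g = graph_from_edges(edges)
        assert g.n_nodes == 10
        seeds = SeedSet("x", {"s1", "s2", "s3"})
        ranking = diamond_expand(g, seeds, max_steps=1)
        acc, step, p, score = ranking.steps[0]
        assert acc == "c"
        assert p == pytest.approx(3 / 45, rel=1e-12)
        assert score == pytest.approx(1 - 3 / 45, rel=1e-12)

    def test_zero_connectivity_never_ranked(self):
        g = graph_from_edges([("s1", "a"), ("a", "b")], extra_nodes=["iso"])
        ranking = diamond_expand(g, SeedSet("x", {"s1"}), max_steps=10)
        ranked = [r[0] for r in ranking.steps]
        assert "iso" not in ranked
        assert ranked[0] == "a"  # only connected candidates join, nearest first

    def test_first_step_is_global_argmin(self):
        rng = np.random.default_rng(23)
        nodes, edges = random_connected_graph(rng, 10, 0.3)
        g = graph_from_edges(edges, extra_nodes=nodes)
        seeds = set(nodes[:3])
        ranking = diamond_expand(g, SeedSet("x", seeds), max_steps=1)
        acc, _, p, _ = ranking.steps[0]
        adj = {n: set(g.graph.neighbors(n)) for n in nodes}
        best = min(
            (
                (hypergeom_tail(len(adj[c] & seeds), 10, 3, len(adj[c])),
                 len(adj[c]), c)
                for c in nodes
                if c not in seeds and adj[c] & seeds
            ),
        )
        assert acc == best[2]
        assert p == pytest.approx(best[0], rel=1e-9)

    def test_pvalues_match_tail_sums_on_random_graphs(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            nodes, edges = random_connected_graph(rng, n, 0.35)
            g = graph_from_edges(edges, extra_nodes=nodes)
            n_seed = int(rng.integers(2, 5))
            seeds = SeedSet("x", set(nodes[:n_seed]))
            ranking = diamond_expand(g, seeds, max_steps=4)
            module = set(seeds.accessions)
            adj = {v: set(g.graph.neighbors(v)) for v in nodes}
            for acc, step, p, score in ranking.steps:
                ks = len(adj[acc] & module)
                assert ks >= 1
                want = hypergeom_tail(ks, n, len(module), len(adj[acc]))
                assert p == pytest.approx(want, rel=1e-9)
                assert score == pytest.approx(1 - want, rel=1e-9)
                module.add(acc)

    def test_truncation_when_no_candidate(self, caplog):
        g = graph_from_edges([("s1", "a")])
        ranking = diamond_expand(g, SeedSet("x", {"s1"}), max_steps=10)
        assert len(ranking.steps) == 1  # only "a" can ever join


class TestTrainingSets:
    def ranking(self, scored):
        from adrnet.dataset import DiamondRanking

        return DiamondRanking(
            steps=[
                (acc, i + 1, 1 - s, s) for i, (acc, s) in enumerate(scored)
            ]
        )

    def big_graph(self, n=60):
        edges = [(f"P{i}", f"P{i+1}") for i in range(n - 1)]
        return graph_from_edges(edges)

    def test_count_bookkeeping(self):
        g = self.big_graph()
        seeds = SeedSet("x", {f"P{i}" for i in range(10)})
        scored = [(f"P{10+i}", 0.95) for i in range(5)]
        scored += [(f"P{20+i}", 0.5) for i in range(5)]
        cfg = TrainingConfig(diamond_threshold=0.8, neg_ratio=1.0, rng_seed=0)
        ds = build_training_sets(g, seeds, self.ranking(scored), dummy_features, cfg)
        labels = [l for _, _, l in ds.rows]
        assert labels.count(1) == 15 and labels.count(-1) == 15

    def test_ratio_scales_negatives(self):
        g = self.big_graph()
        seeds = SeedSet("x", {f"P{i}" for i in range(10)})
        cfg = TrainingConfig(diamond_threshold=0.8, neg_ratio=3.0, rng_seed=0)
        ds = build_training_sets(g, seeds, self.ranking([]), dummy_features, cfg)
        labels = [l for _, _, l in ds.rows]
        assert labels.count(-1) == 30

    def test_deterministic_negative_sample(self):
        g = self.big_graph()
        seeds = SeedSet("x", {f"P{i}" for i in range(10)})
        cfg = TrainingConfig(diamond_threshold=0.8, neg_ratio=1.5, rng_seed=7)
        a = build_training_sets(g, seeds, self.ranking([]), dummy_features, cfg)
        b = build_training_sets(g, seeds, self.ranking([]), dummy_features, cfg)
        assert [r[0] for r in a.rows] == [r[0] for r in b.rows]

    def test_positive_negative_disjoint(self):
        g = self.big_graph()
        seeds = SeedSet("x", {f"P{i}" for i in range(10)})
        for cfg in config_grid(rng_seed=3):
            try:
                ds = build_training_sets(
                    g, seeds, self.ranking([("P30", 0.95)]), dummy_features, cfg
                )
            except ValueError:
                continue  # pool too small at high ratios is a legal outcome
            pos = {a for a, _, l in ds.rows if l == 1}
            neg = {a for a, _, l in ds.rows if l == -1}
            assert not pos & neg

    def test_pool_deficit_errors(self):
        g = graph_from_edges([(f"P{i}", f"P{i+1}") for i in range(10)])
        seeds = SeedSet("x", {f"P{i}" for i in range(8)})
        cfg = TrainingConfig(diamond_threshold=0.8, neg_ratio=5.0, rng_seed=0)
        with pytest.raises(ValueError, match="deficit"):
            build_training_sets(g, seeds, self.ranking([]), dummy_features, cfg)

    def test_config_menu_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(diamond_threshold=0.75, neg_ratio=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(diamond_threshold=0.8, neg_ratio=2.0)
        TrainingConfig(diamond_threshold=0.75, neg_ratio=2.0, allow_free_values=True)

    def test_grid_enumeration(self):
        grid = config_grid()
        assert len(grid) == 16
        assert len(set(grid)) == 16
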