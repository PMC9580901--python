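import io
import math

import pytest

from adrnet.clustering import ModulePartition
from adrnet.features import (
    EnrichedTermSet,
    GOAnnotationMap,
    VITPanel,
    assemble_features,
    fisher_enrichment,
    function_conservation_index,
    panel_q1_distances,
    read_annotations_tsv,
    read_gaf,
    read_panel,
    vit_q1_distance,
)
from adrnet.graphio import InteractomeGraph
from adrnet.propagation import DiffusionScores, SeedSet, propagate

from conftest import graph_from_edges
from oracles import bh_adjust, hypergeom_tail


def term(i):
    return f"GO:{i:07d}"


class TestFisherEnrichment:
    def test_exact_tail_worked_example(self):
        # 5 study proteins all carry T; exactly those 5 of 20 background do
        study = {f"S{i}" for i in range(5)}
        background = study | {f"B{i}" for i in range(15)}
        ann = GOAnnotationMap({p: {term(1)} for p in study})
        res = fisher_enrichment(ann, study, background, alpha=0.05)
        assert len(res.terms) == 1
        go, p, q = res.terms[0]
        assert go == term(1)
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert p == pytest.approx(hypergeom_tail(5, 20, 5, 5), rel=1e-9)

    def test_term_absent_from_study_never_retained(self):
        study = {"S1", "S2"}
        background = study | {"B1", "B2"}
        ann = GOAnnotationMap({"B1": {term(2)}, "S1": {term(1)}, "S2": {term(1)}})
        res = fisher_enrichment(ann, study, background, alpha=1.0)
        assert term(2) not in res.term_ids

    def test_bh_adjustment_step_up(self):
        adj = bh_adjust([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])
        # package path: build a scenario with two tested terms and compare
        # the adjusted values against statsmodels through the public API
        study = {f"S{i}" for i in range(4)}
        background = study | {f"B{i}" for i in range(12)}
        ann_map = {p: {term(1)} for p in study}
        for p in ("S0", "S1", "S2"):
            ann_map[p].add(term(2))
        ann_map["B0"] = {term(2)}
        res = fisher_enrichment(GOAnnotationMap(ann_map), study, background, alpha=1.0)
        raws = {g: p for g, p, _ in res.terms}
        adjs = {g: q for g, _, q in res.terms}
        order = sorted(raws)
        expect = bh_adjust([raws[g] for g in order])
        for g, e in zip(order, expect):
            assert adjs[g] == pytest.approx(e, rel=1e-9)

    def test_empty_study_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(GOAnnotationMap({}), set(), {"B"}, 0.05)

    def test_study_not_subset_errors(self):
        with pytest.raises(ValueError):
            fisher_enrichment(GOAnnotationMap({}), {"S"}, {"B"}, 0.05)

    def test_sorted_by_ascending_p(self):
        study = {f"S{i}" for i in range(5)}
        background = study | {f"B{i}" for i in range(15)}
        ann_map = {p: {term(1)} for p in study}
        for p in ("S0", "S1"):
            ann_map[p].add(term(2))
        res = fisher_enrichment(GOAnnotationMap(ann_map), study, background, alpha=1.0)
        ps = [p for _, p, _ in res.terms]
        assert ps == sorted(ps)


class TestFunctionIndex:
    def enriched(self, ids):
        return EnrichedTermSet(terms=[(t, 0.01, 0.01) for t in ids], alpha=0.05)

    def test_partial_overlap(self):
        e = self.enriched([term(i) for i in range(1, 5)])
        assert function_conservation_index({term(1), term(2)}, e) == pytest.approx(0.5)

    def test_full_overlap_is_one(self):
        ids = [term(i) for i in range(1, 4)]
        assert function_conservation_index(set(ids), self.enriched(ids)) == 1.0

    def test_disjoint_is_zero(self):
        e = self.enriched([term(1)])
        assert function_conservation_index({term(9)}, e) == 0.0

    def test_empty_universe_defaults_zero(self, caplog):
        assert function_conservation_index({term(1)}, self.enriched([])) == 0.0

    def test_bounded_and_monotone(self):
        e = self.enriched([term(i) for i in range(1, 6)])
        values = [
            function_conservation_index({term(j) for j in range(1, i + 1)}, e)
            for i in range(6)
        ]
        assert values == sorted(values)
        assert all(0.0 <= v <= 1.0 for v in values)


class TestVitDistance:
    def test_constant_sample(self):
        g = graph_from_edges([("p", f"v{i}") for i in range(4)] + [("v0", "w")])
        panel = VITPanel({f"v{i}" for i in range(4)})
        # all four panel members at hop distance 1 -> quartile 1.0
        assert vit_q1_distance(g, "p", panel) == pytest.approx(1.0)

    def test_linear_interpolation_quartile(self):
        # chain gives distances {1, 2, 2, 3} from p
        g = graph_from_edges(
            [("p", "a"), ("a", "b"), ("a", "c"), ("b", "d")]
        )
        panel = VITPanel({"a", "b", "c", "d"})
        assert vit_q1_distance(g, "p", panel) == pytest.approx(1.75)

    def test_self_membership_zero(self):
        g = graph_from_edges([("p", "q")])
        assert vit_q1_distance(g, "p", VITPanel({"p"})) == 0.0

    def test_unreachable_panel_sentinel(self):
        g = graph_from_edges([("p", "q"), ("x", "y")])
        assert vit_q1_distance(g, "p", VITPanel({"x", "y"})) == float(g.n_nodes)

    def test_unknown_protein_errors(self, path3):
        with pytest.raises(KeyError):
            vit_q1_distance(path3, "nope", VITPanel({"P1"}))

    def test_bulk_matches_per_protein(self, two_triangles_bridge):
        panel = VITPanel({"a", "y"})
        bulk = panel_q1_distances(two_triangles_bridge, panel)
        for node in two_triangles_bridge.nodes:
            assert bulk[node] == pytest.approx(
                vit_q1_distance(two_triangles_bridge, node, panel)
            )

    def test_duplicate_and_order_invariance(self, two_triangles_bridge):
        a = vit_q1_distance(two_triangles_bridge, "b", VITPanel({"x", "y"}))
        b = vit_q1_distance(two_triangles_bridge, "b", VITPanel({"y", "x"}))
        assert a == b


class TestAssemble:
    def context(self, g):
        seeds = SeedSet("adr", {"a", "b"})
        scores = propagate(g, seeds)
        assignment = {n: 0 for n in g.nodes}
        part = ModulePartition("LOUVAIN", assignment, 1)
        ann = GOAnnotationMap({"a": {term(1)}})
        enriched = EnrichedTermSet([(term(1), 0.01, 0.01)], alpha=0.05)
        panel = VITPanel({"c"})
        return seeds, scores, part, ann, enriched, panel

    def test_all_fields_finite_and_deterministic(self, triangle):
        seeds, scores, part, ann, enriched, panel = self.context(triangle)
        fv1 = assemble_features(
            triangle, "a", scores, part, part, seeds, ann, enriched, panel
        )
        fv2 = assemble_features(
            triangle, "a", scores, part, part, seeds, ann, enriched, panel
        )
        assert fv1 == fv2
        assert all(math.isfinite(v) for v in fv1.as_array())

    def test_protein_not_in_graph_errors(self, triangle):
        seeds, scores, part, ann, enriched, panel = self.context(triangle)
        with pytest.raises(KeyError):
            assemble_features(
                triangle, "zz", scores, part, part, seeds, ann, enriched, panel
            )

    def test_missing_structure_named(self, triangle):
        seeds, scores, part, ann, enriched, panel = self.context(triangle)
        scores.scores.pop("a")
        with pytest.raises(KeyError, match="diffusion"):
            assemble_features(
                triangle, "a", scores, part, part, seeds, ann, enriched, panel
            )


class TestReaders:
    def test_annotation_tsv(self):
        ann = read_annotations_tsv(
            io.StringIO("accession\tgo_id\nP1\tGO:0000001\nP1\tGO:0000002\n")
        )
        assert ann.terms_of("P1") == {"GO:0000001", "GO:0000002"}

    def test_malformed_go_id_rejected(self):
        with pytest.raises(ValueError):
            GOAnnotationMap({"P1": {"GO:12"}})

    def test_gaf_skips_not_qualifier(self):
        gaf = (
            "!gaf-version: 2.2\n"
            "UniProtKB\tP1\tG1\tinvolved_in\tGO:0000001\tREF\tIEA\n"
            "UniProtKB\tP2\tG2\tNOT|involved_in\tGO:0000002\tREF\tIEA\n"
        )
        ann = read_gaf(io.StringIO(gaf))
        assert ann.terms_of("P1") == {"GO:0000001"}
        assert ann.terms_of("P2") == set()

    def test_panel_reader(self):
        panel = read_panel(io.StringIO("# comment\nP1\nP2\n"))
        assert panel.accessions == {"P1", "P2"}

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            read_panel(io.StringIO("\n"))

    def test_panel_restrict_drops_missing(self, path3, caplog):
        panel = VITPanel({"P1", "ZZ"}).restrict_to(path3)
        assert panel.accessions == {"P1"}
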