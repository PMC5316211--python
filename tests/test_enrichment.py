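"""Metabolite enrichment tests, miRNA overlay, network assembly, pathway impact."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import omicsweave as ow
from omicsweave.datatypes import ExpressionMatrix, Pathway, PathwayDB, TargetDB
from omicsweave.de import paired_de_test
from omicsweave import enrichment as enr

from conftest import abundance_table


def db_from(genes_by_pathway: dict[str, set], metabolites_by_pathway: dict[str, set],
            edges_by_pathway: dict[str, list] | None = None) -> PathwayDB:
    pws = {}
    for pid, genes in genes_by_pathway.items():
        g = nx.DiGraph()
        g.add_nodes_from(metabolites_by_pathway[pid])
        g.add_edges_from((edges_by_pathway or {}).get(pid, []))
        pws[pid] = Pathway(name=pid, genes=set(genes),
                           metabolites=set(metabolites_by_pathway[pid]), graph=g)
    return PathwayDB(pws)


class TestMetabolicGenes:
    def test_single_pathway_returns_its_genes(self):
        db = db_from({"p1": {"a", "b", "c", "d", "e"}}, {"p1": {"m1"}})
        assert enr.metabolic_genes_for("m1", db) == {"a", "b", "c", "d", "e"}

    def test_union_over_shared_pathways(self):
        db = db_from({"p1": {"a", "b", "c", "d", "e"},
                      "p2": {"d", "e", "f", "g", "h"}},
                     {"p1": {"m1"}, "p2": {"m1"}})
        assert len(enr.metabolic_genes_for("m1", db)) == 8

    def test_unknown_metabolite_warns_empty(self):
        db = db_from({"p1": {"a"}}, {"p1": {"m1"}})
        with pytest.warns(UserWarning):
            assert enr.metabolic_genes_for("nope", db) == set()


class TestHypergeometric:
    def test_exact_fraction_example(self):
        # N=20, K=5, n=4, k=3 -> 155/4845
        correlated = set(range(4))
        metabolic = {0, 1, 2, 10, 11}
        universe = set(range(20))
        p = enr.hypergeometric_enrichment(correlated, metabolic, universe)
        assert p == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        p = enr.hypergeometric_enrichment({5, 6}, {0, 1}, set(range(10)))
        assert p == pytest.approx(1.0)

    def test_complete_overlap_most_extreme(self):
        # k = n = K -> p = 1/C(N, K)
        p = enr.hypergeometric_enrichment({0, 1, 2}, {0, 1, 2}, set(range(10)))
        assert p == pytest.approx(1 / math.comb(10, 3), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enr.hypergeometric_enrichment(set(), set(), set())

    def test_matches_enumeration_on_small_grid(self):
        """Exhaustive draw enumeration for a few (N, K, n)."""
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 4, 6)]:
            universe = set(range(N))
            metabolic = set(range(K))
            for k in range(min(K, n) + 1):
                correlated = set(range(k)) | set(range(K, K + n - k))
                p = enr.hypergeometric_enrichment(correlated, metabolic, universe)
                total = sum(math.comb(K, i) * math.comb(N - K, n - i)
                            for i in range(k, min(K, n) + 1))
                assert p == pytest.approx(total / math.comb(N, n), abs=1e-12)


class TestWilcoxon:
    def test_exact_small_sample(self):
        # {0.001, 0.002} vs {0.5, 0.6, 0.7}: most extreme of C(5,2)=10 -> 1/10
        p = enr.wilcoxon_enrichment([0.001, 0.002], [0.5, 0.6, 0.7])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_near_half(self):
        rng = np.random.default_rng(0)
        vals = rng.random(30)
        p = enr.wilcoxon_enrichment(vals, vals + rng.normal(0, 1e-12, 30))
        assert p > 0.4

    def test_wrong_direction_large_p(self):
        p = enr.wilcoxon_enrichment([0.8, 0.9, 0.95], [0.01, 0.02, 0.03])
        assert p >= 0.9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            enr.wilcoxon_enrichment([], [0.5])


class TestCorrelationFilter:
    @staticmethod
    def vector_with_exact_r(x: np.ndarray, r: float, seed=0) -> np.ndarray:
        """A vector whose sample Pearson correlation with x is exactly r."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(len(x))
        xc = (x - x.mean()) / x.std()
        zc = z - z.mean()
        zc -= (zc @ xc) / (xc @ xc) * xc
        zc /= zc.std()
        return r * xc + np.sqrt(1 - r**2) * zc

    def make_inputs(self, gene_vectors: dict[str, np.ndarray], metab: np.ndarray):
        idx = [f"s{i}" for i in range(len(metab))]
        expr = ExpressionMatrix(pd.DataFrame(gene_vectors, index=idx))
        return pd.Series(metab, index=idx), expr

    def test_exact_copy_retained_with_r_one(self):
        v = np.arange(10, dtype=float)
        m, expr = self.make_inputs({"g": v}, v)
        out = enr.correlate_metabolite_degs(m, expr)
        assert out.loc["g", "r"] == pytest.approx(1.0)
        assert bool(out.loc["g", "retained"])

    def test_r_at_threshold_not_retained(self):
        """The |r| filter is a strict inequality: r == r_thresh is dropped."""
        v = np.arange(40, dtype=float)
        g = self.vector_with_exact_r(v, 0.5)
        m, expr = self.make_inputs({"g": g}, v)
        r_obs = float(enr.correlate_metabolite_degs(m, expr).loc["g", "r"])
        assert r_obs == pytest.approx(0.5, abs=1e-12)
        out = enr.correlate_metabolite_degs(m, expr, r_thresh=r_obs)
        assert not bool(out.loc["g", "retained"])

    def test_r_064_at_n10_retained(self):
        # t = r sqrt(8)/sqrt(1-r^2), p ~ 0.0467 < 0.05
        v = np.arange(10, dtype=float)
        g = self.vector_with_exact_r(v, 0.64)
        m, expr = self.make_inputs({"g": g}, v)
        out = enr.correlate_metabolite_degs(m, expr)
        assert out.loc["g", "p"] == pytest.approx(0.0466, abs=2e-3)
        assert bool(out.loc["g", "retained"])

    def test_too_few_samples_rejected(self):
        m, expr = self.make_inputs({"g": np.array([1.0, 2.0])}, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            enr.correlate_metabolite_degs(m, expr)

    def test_zero_variance_gene_skipped_with_warning(self):
        v = np.arange(10, dtype=float)
        m, expr = self.make_inputs({"flat": np.ones(10), "g": v}, v)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = enr.correlate_metabolite_degs(m, expr)
        assert "flat" not in out.index


class TestSelection:
    def make_cand(self, mid, p_h, p_w):
        c = enr.MetaboliteEnrichment(metabolite_id=mid, metabolic_genes=set(),
                                     correlated_degs=set())
        c.p_hyper, c.p_wilcoxon = p_h, p_w
        return c

    def test_single_candidate_q_equals_p(self):
        out = enr.select_enriched_metabolites([self.make_cand("m", 0.05, 0.9)])
        assert out[0].q_hyper == pytest.approx(0.05)
        assert out[0].enriched

    def test_all_p_one_nothing_enriched(self):
        cands = [self.make_cand(f"m{i}", 1.0, 1.0) for i in range(5)]
        assert not any(c.enriched for c in enr.select_enriched_metabolites(cands))

    def test_either_test_rule(self):
        out = enr.select_enriched_metabolites(
            [self.make_cand("m", 0.9, 0.01)], fdr=0.1)
        assert out[0].enriched

    def test_planted_recovery_on_generated_cohorts(self):
        recalls, fps = [], []
        for seed in range(10):
            cfg = ow.SyntheticConfig(
                n_horses=20, n_metabolites=30, n_genes=1000, n_mirnas=20,
                n_pathways=10, genes_per_pathway=25, n_active_metabolites=5,
                latent_coupling=0.8, n_active_regulators=0, frac_de_genes=0.3,
                seed=500 + seed)
            b = ow.simulate(cfg)
            de = paired_de_test(b.genes, b.metadata)
            cands = enr.enrich_metabolites(abundance_table(b), b.pathway_db,
                                           de, b.genes)
            hit = {c.metabolite_id for c in cands if c.enriched}
            recalls.append(len(hit & b.truth.active_metabolites))
            fps.append(len(hit - b.truth.active_metabolites))
        assert np.median(recalls) >= 4
        assert np.median(fps) <= 1


class TestMirnaOverlay:
    def make_de(self, sig: dict[str, float]):
        table = pd.DataFrame({
            "log_fc": 1.0, "t": 3.0, "p": list(sig.values()),
            "q": list(sig.values()),
            "direction": "over", "degenerate": False, "significant": True,
        }, index=pd.Index(sig, name="feature_id"))
        from omicsweave.de import DEResults
        return DEResults(table, n_pairs=5, alpha=0.05, feature_kind="mirna",
                         moderated=False)

    def test_significant_mirna_with_targets_retained(self):
        targets = TargetDB(pd.DataFrame({
            "mirna_id": ["mirA"] * 12, "gene_id": [f"g{i}" for i in range(12)],
            "support": "validated"}))
        de = self.make_de({"mirA": 0.001})
        edges = enr.mirna_overlay({f"g{i}" for i in range(12)}, targets, de)
        assert len(edges) == 12

    def test_mirna_without_in_set_targets_dropped(self):
        targets = TargetDB(pd.DataFrame({
            "mirna_id": ["mirA"], "gene_id": ["gX"], "support": "validated"}))
        de = self.make_de({"mirA": 0.001})
        assert len(enr.mirna_overlay({"g1", "g2"}, targets, de)) == 0

    def test_non_significant_mirna_dropped(self):
        targets = TargetDB(pd.DataFrame({
            "mirna_id": ["mirA"] * 3, "gene_id": ["g1", "g2", "g3"],
            "support": "validated"}))
        de = self.make_de({"mirA": 0.5})
        assert len(enr.mirna_overlay({"g1", "g2", "g3"}, targets, de)) == 0


class TestNetworkAssembly:
    def make_gene_de(self, fc: dict[str, float]):
        from omicsweave.de import DEResults
        table = pd.DataFrame({
            "log_fc": list(fc.values()), "t": 1.0, "p": 0.01, "q": 0.01,
            "direction": "over", "degenerate": False, "significant": True,
        }, index=pd.Index(fc, name="feature_id"))
        return DEResults(table, 5, 0.05, "gene", False)

    def build(self):
        c = enr.MetaboliteEnrichment("m1", metabolic_genes={"g1", "g2", "tf1"},
                                     correlated_degs={"g1", "g2", "tf1"})
        c.enriched = True
        edges = pd.DataFrame({"mirna_id": ["mirA", "mirA"],
                              "gene_id": ["g1", "g2"]})
        de_g = self.make_gene_de({"g1": 1.0, "g2": -2.0, "tf1": 0.5})
        de_m = self.make_gene_de({"mirA": -1.0})
        return enr.assemble_network([c], edges, {"tf1"}, de_g, de_m,
                                    metabolite_directions={"m1": "up"})

    def test_nodes_typed_and_directed(self):
        net = self.build()
        assert net.nodes_of_kind("metabolite") == {"m1"}
        assert net.nodes_of_kind("tf") == {"tf1"}
        assert net.nodes_of_kind("mirna") == {"mirA"}
        assert net.graph.nodes["g2"]["direction"] == "down"

    def test_every_edge_carries_evidence(self):
        net = self.build()
        assert all("evidence" in d for _, _, d in net.graph.edges(data=True))

    def test_empty_enrichment_gives_empty_network(self):
        net = enr.assemble_network([], pd.DataFrame(columns=["mirna_id", "gene_id"]),
                                   set(), self.make_gene_de({"g": 1.0}),
                                   self.make_gene_de({"m": 1.0}))
        assert net.graph.number_of_nodes() == 0

    def test_min_targets_prunes_weak_mirnas(self):
        c = enr.MetaboliteEnrichment("m1", metabolic_genes={"g1", "g2"},
                                     correlated_degs={"g1", "g2"})
        c.enriched = True
        edges = pd.DataFrame({"mirna_id": ["mirA"], "gene_id": ["g1"]})
        de_g = self.make_gene_de({"g1": 1.0, "g2": 1.0})
        de_m = self.make_gene_de({"mirA": 1.0})
        net = enr.assemble_network([c], edges, set(), de_g, de_m, min_targets=2)
        assert "mirA" not in net.graph

    def test_graphml_round_trip_preserves_structure(self, tmp_path):
        net = self.build()
        path = tmp_path / "net.graphml"
        net.write_graphml(path)
        back = enr.RegulatoryNetwork.read_graphml(path)
        assert set(back.graph.nodes(data="kind")) == set(net.graph.nodes(data="kind"))
        assert (sorted(back.graph.edges(data="evidence"))
                == sorted(net.graph.edges(data="evidence")))

    def test_planted_pairs_recovered_in_pipeline_network(self, planted_bundle):
        b = planted_bundle
        de_g = paired_de_test(b.genes, b.metadata)
        cands = enr.enrich_metabolites(abundance_table(b), b.pathway_db, de_g, b.genes)
        hit_pairs = {(c.metabolite_id, g) for c in cands if c.enriched
                     for g in c.overlap}
        planted = b.truth.metabolite_gene_pairs
        # most planted couplings surface as correlation edges
        assert len(hit_pairs & planted) / len(planted) > 0.5


class TestPathwayImpact:
    PATH_DB = db_from({"p": set()}, {"p": {"A", "B", "C"}},
                      {"p": [("A", "B"), ("B", "C")]})

    def test_interior_node_carries_all_impact(self):
        assert enr.pathway_impact(self.PATH_DB, "p", {"B"}) == pytest.approx(1.0)

    def test_source_node_has_zero_betweenness_impact(self):
        assert enr.pathway_impact(self.PATH_DB, "p", {"A"}) == pytest.approx(0.0)

    def test_full_match_is_one(self):
        assert enr.pathway_impact(self.PATH_DB, "p", {"A", "B", "C"}) == pytest.approx(1.0)

    def test_out_degree_variant(self):
        # out-degrees A:1, B:1, C:0 -> importance 0.5/0.5/0
        v = enr.pathway_impact(self.PATH_DB, "p", {"A"}, centrality="out_degree")
        assert v == pytest.approx(0.5)

    def test_monotone_in_matched_set(self):
        db = db_from({"p": set()}, {"p": {"A", "B", "C", "D"}},
                     {"p": [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")]})
        matched = []
        last = 0.0
        for m in ["A", "B", "C", "D"]:
            matched.append(m)
            v = enr.pathway_impact(db, "p", set(matched))
            assert 0.0 <= v <= 1.0
            assert v >= last - 1e-12
            last = v

    def test_all_zero_centrality_falls_back_uniform(self):
        db = db_from({"p": set()}, {"p": {"A", "B"}})
        with pytest.warns(UserWarning, match="uniform"):
            assert enr.pathway_impact(db, "p", {"A"}) == pytest.approx(0.5)


def test_null_generator_false_call_rate_bounded(null_bundle):
    """At FDR 0.1 with no planted couplings, enrichment calls stay below
    the binomial upper bound for 40 candidates."""
    b = null_bundle
    de = paired_de_test(b.genes, b.metadata)
    cands = enr.enrich_metabolites(abundance_table(b), b.pathway_db, de, b.genes)
    frac = np.mean([c.enriched for c in cands]) if cands else 0.0
    assert frac <= 0.1 + 1.96 * np.sqrt(0.1 * 0.9 / max(len(cands), 1))
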