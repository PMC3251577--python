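"""Connection graph, reciprocity, cliques, hubs, coordination, power law."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import make_gene
from racenet import network
from racenet.assignment import Assignment
from racenet.calling import RACEfrag
from racenet.core import ExperimentKey, GenomicInterval
from racenet.network import (
    ConnectionGraph,
    build_graph,
    clique_analysis,
    expression_coordination,
    fit_powerlaw,
    hub_detection,
    randomize_network,
    reciprocal_connections,
)


def assignment(locus, start, end, sample, pool="pool1", primer=None, chrom="chr1"):
    f = RACEfrag(GenomicInterval(chrom, start, end), ExperimentKey(pool, sample), 3, 9.0)
    return Assignment(f, primer or f"{locus}_p", locus, 0)


def three_gene_world():
    ga = make_gene("A", transcripts=(((100, 300), (500, 700)),))
    gb = make_gene("B", transcripts=(((5_000, 5_200), (5_500, 5_700)),))
    gc = make_gene("C", transcripts=(((9_000, 9_300),),))
    return [ga, gb, gc]


class TestBuildGraph:
    def test_single_edge(self):
        genes = three_gene_world()
        g = build_graph([assignment("A", 5_050, 5_150, "t1")], genes)
        assert list(g.digraph.edges()) == [("A", "B")]
        assert g.digraph["A"]["B"]["samples"] == {"t1"}

    def test_internal_frags_make_no_edges(self):
        genes = three_gene_world()
        g = build_graph([assignment("A", 120, 250, "t1")], genes)
        assert g.digraph.number_of_edges() == 0

    def test_no_self_edges(self, pipeline_result):
        assert all(u != v for u, v in pipeline_result.graph.digraph.edges())


class TestReciprocity:
    def make_graph(self, edges):
        genes = three_gene_world()
        return build_graph([assignment(src, *span, s) for src, span, s in edges], genes)

    def test_pure_and_unique_to_sample(self):
        # both directions of A-B observed in sample t2 only
        g = self.make_graph(
            [("A", (5_050, 5_150), "t2"), ("B", (150, 250), "t2")]
        )
        rec = reciprocal_connections(g)
        row = rec["pairs"].iloc[0]
        assert (row["gene_a"], row["gene_b"], row["label"]) == ("A", "B", "pure")
        assert row["unique_sample"] == "t2"
        assert rec["cell_type_specific_fraction"] == 1.0

    def test_composite_from_different_samples(self):
        g = self.make_graph(
            [("B", (9_100, 9_200), "t1"), ("C", (5_100, 5_180), "t3")]
        )
        rec = reciprocal_connections(g)
        assert rec["pairs"].iloc[0]["label"] == "composite"

    def test_one_direction_is_not_reciprocal(self):
        g = self.make_graph([("A", (5_050, 5_150), "t1")])
        assert reciprocal_connections(g)["n_reciprocal"] == 0

    def test_worked_reciprocity_panel(self):
        """Two reciprocal pairs: one pure and unique to sample 2, one
        composite across samples."""
        g = self.make_graph(
            [
                ("A", (5_050, 5_150), "t2"),
                ("B", (150, 250), "t2"),
                ("B", (9_100, 9_200), "t1"),
                ("C", (5_100, 5_180), "t3"),
            ]
        )
        rec = reciprocal_connections(g)
        by_pair = rec["pairs"].set_index(["gene_a", "gene_b"])
        assert by_pair.loc[("A", "B"), "label"] == "pure"
        assert by_pair.loc[("A", "B"), "unique_sample"] == "t2"
        assert by_pair.loc[("B", "C"), "label"] == "composite"
        assert rec["n_reciprocal"] == 2 and rec["n_pure"] == 1

    def test_pairing_bound(self, pipeline_result):
        g = pipeline_result.graph
        n_rec = reciprocal_connections(g)["n_reciprocal"]
        din = g.digraph.in_degree()
        assert n_rec <= min(g.digraph.number_of_edges(), sum(d for _, d in din))


def clique_census_oracle(g, k_max):
    """Exhaustive subset enumeration of complete subgraphs."""
    counts = {k: 0 for k in range(2, k_max + 1)}
    nodes = list(g.nodes())
    for k in range(2, k_max + 1):
        for subset in itertools.combinations(nodes, k):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(subset, 2)):
                counts[k] += 1
    return counts


class TestCliques:
    def test_triangle(self):
        g = nx.complete_graph(3)
        table = clique_analysis(g, k_max=3, n_rand=5, seed=0).set_index("size")
        assert table.loc[2, "observed"] == 3 and table.loc[3, "observed"] == 1

    def test_k4_counts(self):
        g = nx.complete_graph(4)
        table = clique_analysis(g, k_max=4, n_rand=5, seed=0).set_index("size")
        assert list(table["observed"]) == [6, 4, 1]
        assert table.loc[4, "observed_maximal"] == 1 and table.loc[3, "observed_maximal"] == 0

    def test_random_graphs_match_exhaustive_oracle(self, rng):
        for trial in range(5):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(0, 10_000)))
            table = clique_analysis(g, k_max=5, n_rand=2, seed=trial).set_index("size")
            oracle = clique_census_oracle(g, 5)
            assert {k: int(table.loc[k, "observed"]) for k in oracle} == oracle

    def test_k_max_validation(self):
        with pytest.raises(ValueError):
            clique_analysis(nx.complete_graph(3), k_max=1)


class TestRandomize:
    def test_degree_sequence_preserved_exactly(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=4)
        r = randomize_network(g, seed=11)
        assert sorted(dict(g.degree()).values()) == sorted(dict(r.degree()).values())
        assert not any(u == v for u, v in r.edges())

    def test_two_edge_path_unchanged(self):
        g = nx.path_graph(3)
        r = randomize_network(g, seed=0)
        assert set(map(frozenset, r.edges())) == set(map(frozenset, g.edges()))

    def test_edge_set_differs_with_high_probability(self):
        g = nx.gnp_random_graph(40, 0.1, seed=7)
        r = randomize_network(g, seed=3)
        assert set(map(frozenset, r.edges())) != set(map(frozenset, g.edges()))

    def test_under_two_edges_warns(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.warns(UserWarning):
            r = randomize_network(g, seed=0)
        assert set(r.edges()) == {("a", "b")}


def graph_with_covariates(edges, lengths, primer_counts=None):
    dg = nx.DiGraph()
    for node, length in lengths.items():
        dg.add_node(
            node,
            locus=GenomicInterval("chr1", 0, length),
            length=length,
            n_primers=(primer_counts or {}).get(node, 1),
        )
    for u, v in edges:
        dg.add_edge(u, v, samples={"t1"})
        dg.add_edge(v, u, samples={"t1"})
    return ConnectionGraph(digraph=dg)


class TestHubs:
    def test_symmetric_regular_graph_scores_near_zero(self):
        nodes = [f"g{i}" for i in range(8)]
        edges = [(nodes[i], nodes[(i + 1) % 8]) for i in range(8)]  # 2-regular ring
        g = graph_with_covariates(edges, {n: 1000 for n in nodes})
        report = hub_detection(g, n_rand=400, seed=0)
        assert report.table["score"].abs().max() < 1.0

    def test_planted_hub_recovers_top_score(self):
        nodes = [f"g{i}" for i in range(14)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(0, 12, 2)]  # degree-1 pairs
        hub_edges = [("hub", n) for n in nodes[:12]]
        g = graph_with_covariates(
            edges + hub_edges, {**{n: 1000 for n in nodes}, "hub": 1000}
        )
        report = hub_detection(g, n_rand=200, seed=1)
        top = report.table.sort_values("score", ascending=False).iloc[0]
        assert top["gene_id"] == "hub" and bool(top["hub"])

    def test_expected_degrees_conserve_edge_count(self):
        nodes = [f"g{i}" for i in range(10)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(9)]
        lengths = {n: int(500 * (i + 1)) for i, n in enumerate(nodes)}
        g = graph_with_covariates(edges, lengths)
        report = hub_detection(g, n_rand=500, seed=2)
        m = g.undirected().number_of_edges()
        assert report.table["expected"].sum() == pytest.approx(2 * m, rel=0.02)


class TestCoordination:
    def test_identical_profiles_correlate_fully(self):
        genes = three_gene_world()
        g = build_graph([assignment("A", 5_050, 5_150, "t1"), assignment("B", 150, 250, "t1")], genes)
        prof = np.tile(np.arange(8.0), (2, 1))
        expr = pd.DataFrame(np.vstack([prof, np.random.default_rng(0).normal(size=(1, 8))]),
                            index=["A", "B", "C"])
        rep = expression_coordination(expr, g)
        assert rep["mean_r_connected"] == pytest.approx(1.0)

    def test_independent_profiles_near_zero(self, rng):
        genes = three_gene_world()
        g = build_graph([], genes)
        expr = pd.DataFrame(rng.normal(size=(3, 200)), index=["A", "B", "C"])
        rep = expression_coordination(expr, g)
        assert abs(rep["mean_r_nonconnected"]) < 0.2

    def test_constant_profile_skipped(self, rng):
        genes = three_gene_world()
        g = build_graph([], genes)
        expr = pd.DataFrame(
            np.vstack([np.ones(8), rng.normal(size=(2, 8))]), index=["A", "B", "C"]
        )
        rep = expression_coordination(expr, g)
        assert rep["n_skipped_constant"] == 1


class TestPowerLaw:
    def test_recovers_planted_exponent(self, rng):
        # inverse-CDF sampling of a continuous power law with alpha = 1.5
        alpha, xmin, n = 1.5, 1_000.0, 10_000
        u = rng.random(n)
        x = xmin * (1 - u) ** (-1 / (alpha - 1))
        fit = fit_powerlaw(x, x_min=xmin)
        assert fit.exponent == pytest.approx(-1.5, abs=0.05)

    def test_scale_invariance(self, rng):
        x = 1_000.0 * (1 - rng.random(2_000)) ** (-1 / 0.5)
        f1 = fit_powerlaw(x)
        f2 = fit_powerlaw(2 * x)
        assert f1.exponent == pytest.approx(f2.exponent, abs=1e-9)

    def test_degenerate_all_equal(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_powerlaw([100.0] * 50)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_powerlaw([10.0, 20.0])

    def test_zeros_excluded(self, rng):
        x = np.concatenate([np.zeros(5), 1_000.0 * (1 - rng.random(500)) ** (-2.0)])
        fit = fit_powerlaw(x)
        assert fit.n == 500


class TestMapStatistics:
    def test_sensitivity_ratio_and_composition(self):
        genes = three_gene_world()
        from racenet.pooling import RacePrimer

        primers = [
            RacePrimer("A_3p", "A", GenomicInterval("chr1", 150, 175, "+"), "3p"),
        ]
        assignments = [
            assignment("A", 520, 680, "t1", primer="A_3p"),   # internal exonic (exon 2)
            assignment("A", 5_250, 5_400, "t1", primer="A_3p"),  # external genic intronic
            assignment("A", 20_000, 20_100, "t1", primer="A_3p"),  # intergenic
        ]
        rep = network.map_statistics(assignments, genes, primers)
        counts = rep["composition_counts"]
        assert counts[("internal", "exonic")] == 1
        assert counts[("external_genic", "intronic")] == 1
        assert counts[("intergenic", "intergenic")] == 1
        # A has exon pair (e1, e2) with primer in e1 pointing at e2: detected
        assert rep["detectable_exon_connections"] == 1
        assert rep["detected_exon_connections"] == 1
        assert rep["sensitivity"] == 1.0

    def test_partial_sensitivity(self, pipeline_result):
        rep = network.map_statistics(
            pipeline_result.assignments, pipeline_result.ann.genes, pipeline_result.ann.primers
        )
        assert 0.0 <= rep["sensitivity"] <= 1.0
        assert rep["detected_exon_connections"] <= rep["detectable_exon_connections"]
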