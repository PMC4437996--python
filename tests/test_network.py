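import math

import networkx as nx
import numpy as np
import pytest

from rqlnet import network as N
from rqlnet.errors import InsufficientDegreesError
from rqlnet.rules import DiscoveryConfig, Rule, RuleSet
from rqlnet.synthetic import GeneratorSpec, random_dataset
from rqlnet.tables import Dataset


def rule(lhs, rhs, conf=1.0, lev=0.1):
    return Rule(frozenset(lhs), rhs, support=0.2, confidence=conf,
                lift=2.0, leverage=lev, exact=conf == 1.0)


def ruleset(rules, qid="q"):
    return RuleSet(list(rules), DiscoveryConfig(), qid, N=10)


class TestBuildNetwork:
    def test_single_rule(self):
        net = N.build_network([ruleset([rule(["A"], "B")])])
        assert net.nodes == {"A", "B"}
        assert len(net.edges) == 1

    def test_reciprocal_rules_merge_undirected(self):
        rs = ruleset([rule(["A"], "B", conf=0.9), rule(["B"], "A")])
        net = N.build_network([rs], directed=False)
        assert len(net.edges) == 1
        assert net.edges[0].confidence == 1.0  # best-confidence rule kept

    def test_star_expansion_shares_rule_id(self):
        net = N.build_network([ruleset([rule(["A", "B"], "C")])])
        assert {(e.source, e.target) for e in net.edges} == \
            {("A", "C"), ("B", "C")}
        assert len({e.rule_id for e in net.edges}) == 1

    def test_collapse_labels_merges_best_confidence(self):
        rs = ruleset([rule(["G1_high"], "G2_high", conf=0.95),
                      rule(["G1_low"], "G2_low", conf=1.0)])
        net = N.build_network([rs], collapse_labels=True)
        assert net.nodes == {"G1", "G2"}
        assert len(net.edges) == 1
        assert net.edges[0].confidence == 1.0

    def test_nodes_equal_attributes_in_rules(self):
        rs = ruleset([rule(["A"], "B"), rule(["C", "D"], "B")])
        net = N.build_network([rs])
        assert net.nodes == {"A", "B", "C", "D"}


class TestTopology:
    def from_edges(self, pairs):
        rs = ruleset([rule([a], b) for a, b in pairs])
        return N.build_network([rs], directed=False)

    def test_triangle(self):
        t = N.topology(self.from_edges([("A", "B"), ("B", "C"), ("C", "A")]))
        assert t.density == 1.0
        assert t.avg_clustering == 1.0
        assert t.char_path_length == 1.0
        assert t.n_components == 1

    def test_star_centralization_is_one(self):
        t = N.topology(self.from_edges([("H", x) for x in "ABCD"]))
        assert t.centralization == pytest.approx(1.0, abs=0)
        assert t.avg_neighbors == pytest.approx(2 * 4 / 5)

    def test_disjoint_edges_components(self):
        t = N.topology(self.from_edges([("A", "B"), ("C", "D")]))
        assert t.n_components == 2
        assert math.isnan(t.char_path_length) is False

    def test_heterogeneity_is_degree_cv(self):
        net = self.from_edges([("H", x) for x in "ABCD"])
        degs = np.array([4, 1, 1, 1, 1], float)
        t = N.topology(net)
        assert t.heterogeneity == pytest.approx(degs.std() / degs.mean())


class TestScaleFree:
    def exact_power_law_graph(self):
        """Degrees 1, 2, 4 with counts 16, 4, 1: P(k) ∝ k^−2 exactly."""
        g = nx.Graph()
        g.add_edges_from([("hub", f"m{i}") for i in range(4)])
        g.add_edges_from([("m0", "m1"), ("m2", "m3")])
        for i in range(8):
            g.add_edge(f"u{2 * i}", f"u{2 * i + 1}")
        return g

    def test_exact_power_law(self):
        g = self.exact_power_law_graph()
        counts = {k: 0 for k in (1, 2, 4)}
        for _, d in g.degree():
            counts[d] += 1
        assert counts == {1: 16, 2: 4, 4: 1}
        r2, gamma = N.scale_free_fit(g)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert gamma == pytest.approx(2.0, abs=1e-12)

    def test_regular_graph_insufficient(self):
        with pytest.raises(InsufficientDegreesError):
            N.scale_free_fit(nx.cycle_graph(10))

    def test_preferential_attachment_fits_well(self):
        g = nx.barabasi_albert_graph(400, 2, seed=5)
        r2, gamma = N.scale_free_fit(g)
        assert r2 > 0.8
        assert gamma > 1.0


class TestPearsonBaseline:
    def make(self, cols):
        import pandas as pd
        frame = pd.DataFrame(cols, index=[f"s{i}" for i in
                                          range(len(next(iter(cols.values()))))])
        return Dataset("d", frame,
                       {c: "quantitative" for c in cols})

    def test_identical_columns_edge(self):
        ds = self.make({"A": [1.0, 2, 3, 4], "B": [1.0, 2, 3, 4]})
        net = N.pearson_baseline(ds, cutoff=0.8)
        assert {(e.source, e.target) for e in net.edges} == {("A", "B")}

    def test_orthogonal_columns_no_edge(self):
        ds = self.make({"A": [1.0, -1, 1, -1], "B": [1.0, 1, -1, -1]})
        assert N.pearson_baseline(ds, cutoff=0.8).edges == []

    def test_noisy_duplicate_above_cutoff(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=30)
        ds = self.make({"A": base, "B": base + 0.3 * rng.normal(size=30)})
        r = np.corrcoef(base, ds.frame["B"])[0, 1]
        net = N.pearson_baseline(ds, cutoff=0.8)
        assert (len(net.edges) == 1) == (abs(r) >= 0.8)
        assert abs(r) >= 0.8  # construction keeps noise well below cutoff

    def test_constant_attribute_excluded_with_warning(self):
        ds = self.make({"A": [1.0, 2, 3], "K": [5.0, 5, 5]})
        with pytest.warns(UserWarning):
            net = N.pearson_baseline(ds, cutoff=0.8)
        assert "K" not in net.nodes


class TestExport:
    def test_roundtrip_preserves_edges_and_metrics(self, tmp_path):
        rs = ruleset([rule(["A"], "B", conf=0.93, lev=0.12),
                      rule(["B", "C"], "D")])
        net = N.build_network([rs])
        p = tmp_path / "edges.tsv"
        N.export_cytoscape(net, p)
        back = N.import_cytoscape(p)
        assert {(e.source, e.target) for e in back.edges} == \
            {(e.source, e.target) for e in net.edges}
        orig = {(e.source, e.target): e for e in net.edges}
        for e in back.edges:
            o = orig[(e.source, e.target)]
            assert e.confidence == pytest.approx(o.confidence)
            assert e.leverage == pytest.approx(o.leverage)

    def test_single_edge_two_lines(self, tmp_path):
        net = N.build_network([ruleset([rule(["A"], "B")])])
        p = tmp_path / "e.tsv"
        N.export_cytoscape(net, p)
        assert len(p.read_text().strip().split("\n")) == 2

    def test_empty_network_header_only(self, tmp_path):
        net = N.Network(set(), [], True)
        p = tmp_path / "e.tsv"
        N.export_cytoscape(net, p)
        assert p.read_text().strip().split("\n") == \
            ["\t".join(["source", "interaction", "target", "support",
                        "confidence", "lift", "leverage", "query_id"])]

    def test_sif_output(self, tmp_path):
        net = N.build_network([ruleset([rule(["A"], "B")])])
        p = tmp_path / "e.sif"
        N.export_sif(net, p)
        assert p.read_text() == "A\trule\tB\n"
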