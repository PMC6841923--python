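from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from termnet.errors import DomainError
from termnet.influence import build_influence_network, influence_matrix
from termnet.network_analysis import (
    DEFAULT_FERMENTATION_PRODUCTS,
    FunctionalClass,
    RemovalMode,
    betweenness_centrality,
    centrality_report,
    classify_influencers,
    classify_species,
    identify_influencers,
    robustness_sample,
    segment_byproduct_profile,
)
from termnet.network_model import Activity
from termnet.segmentation import AbundanceTable, partition_segments
from termnet.synthetic_data import generate_community

from conftest import hub_spec, make_network


def brute_force_betweenness(g: nx.DiGraph) -> dict:
    """Exhaustive simple-path enumeration (no shortest-path library calls)."""
    nodes = list(g.nodes)
    adj = {u: set(g.successors(u)) for u in nodes}

    def all_simple_paths(x, y):
        out, stack = [], [(x, [x])]
        while stack:
            cur, path = stack.pop()
            if cur == y:
                out.append(path)
                continue
            for nxt in adj[cur]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return out

    raw = {v: 0.0 for v in nodes}
    for x in nodes:
        for y in nodes:
            if x == y:
                continue
            paths = all_simple_paths(x, y)
            if not paths:
                continue
            d = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == d]
            for v in nodes:
                if v in (x, y):
                    continue
                through = sum(1 for p in shortest if v in p)
                raw[v] += through / len(shortest)

    comp_size = {}
    for comp in nx.weakly_connected_components(g):
        for v in comp:
            comp_size[v] = len(comp)
    return {
        v: (raw[v] * 2.0 / ((comp_size[v] - 1) * (comp_size[v] - 2))
            if comp_size[v] >= 3 else 0.0)
        for v in nodes
    }


class TestBetweenness:
    def test_directed_path_middle_node(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        cb = betweenness_centrality(g)
        assert cb["b"] == pytest.approx(1.0)
        assert cb["a"] == cb["c"] == 0.0

    def test_edgeless_graph_all_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from("abcde")
        assert set(betweenness_centrality(g).values()) == {0.0}

    def test_out_star_hub_is_zero(self):
        g = nx.DiGraph([("hub", f"leaf{i}") for i in range(4)])
        cb = betweenness_centrality(g)
        assert cb["hub"] == 0.0

    def test_matches_bruteforce_on_random_digraphs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < 0.3:
                        g.add_edge(u, v)
            expected = brute_force_betweenness(g)
            got = betweenness_centrality(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-12)

    def test_directed_normalization_halves(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        printed = betweenness_centrality(g, normalization="printed")
        halved = betweenness_centrality(g, normalization="directed")
        assert halved["b"] == pytest.approx(printed["b"] / 2)


class TestInfluencers:
    def test_equal_centrality_gives_empty_set(self):
        cb = {"a": 0.3, "b": 0.3, "c": 0.3}
        infl, frac, cut = identify_influencers(cb, "auto")
        assert infl == set()
        assert frac == 0.0
        assert cut == pytest.approx(0.3)

    def test_fraction_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(2)
        cb = {f"s{i}": float(rng.random()) for i in range(50)}
        fracs = [identify_influencers(cb, c)[1] for c in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_planted_hub_is_top_influencer(self):
        com = generate_community(hub_spec(0))
        part = partition_segments(com.abundance)
        mat = influence_matrix(com.network, com.abundance, part)
        g = build_influence_network(mat)
        cb = betweenness_centrality(g)
        assert max(cb, key=cb.get) == com.truth["hubs"][0]


class TestClassification:
    def test_degrader_fermenter_both(self):
        net = make_network(
            [
                ("D", "cellulose", Activity.DEGRADES),
                ("F", "acetate", Activity.EXPORT),
                ("X", "cellulose", Activity.DEGRADES),
                ("X", "acetate", Activity.EXPORT),
                ("O", "glucose", Activity.IMPORT),
            ],
            products={"cellulose": ["glucose"]},
        )
        assert classify_species("D", net) is FunctionalClass.DEGRADER
        assert classify_species("F", net) is FunctionalClass.FERMENTER
        assert classify_species("X", net) is FunctionalClass.BOTH
        assert classify_species("O", net) is FunctionalClass.OTHER

    def test_all_degrader_fractions(self):
        net = make_network(
            [("D1", "cellulose", Activity.DEGRADES), ("D2", "cellulose", Activity.DEGRADES)],
            products={"cellulose": ["glucose"]},
        )
        _, fracs = classify_influencers(["D1", "D2"], net)
        assert fracs["degrader"] == pytest.approx(100.0)
        assert fracs["fermenter"] == fracs["both"] == 0.0

    def test_unknown_influencer_rejected(self, toy_net):
        with pytest.raises(DomainError):
            classify_influencers(["ghost"], toy_net)


class TestByproductProfile:
    def test_unanimous_export_is_100_percent(self):
        net = make_network(
            [
                ("A", "acetate", Activity.EXPORT),
                ("A", "glucose", Activity.IMPORT),
                ("B", "acetate", Activity.EXPORT),
                ("B", "glucose", Activity.IMPORT),
            ]
        )
        g = nx.DiGraph()
        g.add_node("a", segment="S1")
        g.add_node("b", segment="S1")
        profiles = segment_byproduct_profile(g, net)
        assert profiles["S1"].loc["acetate", "producer_pct"] == pytest.approx(100.0)
        assert profiles["S1"].loc["glucose", "consumer_pct"] == pytest.approx(100.0)
        assert profiles["S1"].attrs["top_exported"][0] == "acetate"


class TestRobustness:
    def run(self, com, **kw):
        part = partition_segments(com.abundance)
        return robustness_sample(com.network, com.abundance, part, **kw)

    def test_same_seed_reproducible(self, small_community):
        r1 = self.run(small_community, removal_fraction=0.25, seed=4)
        r2 = self.run(small_community, removal_fraction=0.25, seed=4)
        assert r1 == r2

    def test_zero_removal_retains_everything(self, small_community):
        res = self.run(small_community, removal_fraction=0.0, seed=0)
        assert res.retention_surviving_pct == pytest.approx(100.0)
        assert res.retention_all_pct == pytest.approx(100.0)

    def test_species_only_mode_keeps_compounds(self, small_community):
        res = self.run(
            small_community, removal_fraction=0.25,
            mode=RemovalMode.SPECIES_ONLY, seed=1,
        )
        assert 0.0 <= res.retention_surviving_pct <= 100.0

    def test_invalid_fraction_rejected(self, small_community):
        with pytest.raises(DomainError):
            self.run(small_community, removal_fraction=1.0)

    def test_retention_beats_shuffled_baseline(self):
        """Planted-hub communities keep their influencers under 25% removal at a
        rate well above random relabeling of the same number of influencers."""
        rng = np.random.default_rng(0)
        retained, null = [], []
        for seed in range(5):
            com = generate_community(hub_spec(seed + 50))
            part = partition_segments(com.abundance)
            res = robustness_sample(
                com.network, com.abundance, part, removal_fraction=0.25, seed=seed
            )
            retained.append(res.retention_surviving_pct)
            # null: influencer labels shuffled among surviving nodes
            n_nodes = len(com.network.species)
            k = len(res.original_influencers)
            if k:
                null.append(100.0 * k / n_nodes)
        assert np.mean(retained) > np.mean(null) + 10


class TestCentralityReport:
    def test_report_fields(self, small_community):
        part = partition_segments(small_community.abundance)
        mat = influence_matrix(small_community.network, small_community.abundance, part)
        g = build_influence_network(mat)
        report = centrality_report(g, small_community.network)
        t = report.table
        assert set(t.columns) >= {
            "out_degree", "betweenness", "influencer", "functional_class",
            "positive_influence_pct", "negative_influence_pct",
        }
        for v in t.index:
            assert t.loc[v, "out_degree"] == g.out_degree(v)
        assert ((t["positive_influence_pct"] >= 0) & (t["positive_influence_pct"] <= 100)).all()
        assert report.influencers == set(t.index[t["betweenness"] > report.cutoff])
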