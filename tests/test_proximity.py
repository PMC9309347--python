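"""Set-distance proximity, degree-matched nulls, ranking and overlap."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netprox as npx

from conftest import named_gnp, table_from_graph


def net_of(g: nx.Graph) -> npx.InteractionNetwork:
    return npx.build_network(table_from_graph(g), set(g.nodes), {})


class TestProximityScore:
    def test_containment_gives_zero(self, path_network):
        assert npx.proximity_score(path_network, {"c"}, {"b", "c"}) == 0.0

    def test_closest_and_average_hand_values(self, path_network):
        assert npx.proximity_score(path_network, {"a"}, {"c", "d"}) == 2.0
        assert npx.proximity_score(path_network, {"a"}, {"c", "d"},
                                   metric="average") == 2.5

    def test_unreachable_penalty_is_node_count(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        g.add_nodes_from([f"x{i}" for i in range(6)])  # pad to 10 nodes
        net = net_of(g)
        assert npx.proximity_score(net, {"a"}, {"c"}) == 10.0

    def test_closest_never_exceeds_average(self):
        for seed in range(10):
            g = named_gnp(30, 0.12, seed=seed)
            rng = np.random.default_rng(seed)
            nodes = sorted(g.nodes)
            t = set(rng.choice(nodes, 4, replace=False))
            s = set(rng.choice(nodes, 8, replace=False))
            net = net_of(g)
            assert (npx.proximity_score(net, t, s)
                    <= npx.proximity_score(net, t, s, metric="average") + 1e-12)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(3)
        g = named_gnp(25, 0.1, seed=3)
        nodes = sorted(g.nodes)
        t = set(rng.choice(nodes, 3, replace=False))
        s = set(rng.choice(nodes, 6, replace=False))
        before = npx.proximity_score(net_of(g), t, s)
        non_edges = [e for e in nx.non_edges(g)]
        g.add_edge(*non_edges[rng.integers(len(non_edges))])
        assert npx.proximity_score(net_of(g), t, s) <= before + 1e-12

    def test_all_absent_ids_rejected(self, path_network):
        with pytest.raises(ValueError):
            npx.proximity_score(path_network, {"zz"}, {"a"})


class TestDegreeMatchedNull:
    def test_deterministic_given_seed(self):
        g = named_gnp(60, 0.1, seed=0)
        net = net_of(g)
        nodes = sorted(g.nodes)
        a = npx.degree_matched_null(net, nodes[:3], nodes[10:20], n_perm=100, seed=4)
        b = npx.degree_matched_null(net, nodes[:3], nodes[10:20], n_perm=100, seed=4)
        assert (a.d_obs, a.null_mean, a.null_sd, a.z, a.p_emp) == \
               (b.d_obs, b.null_mean, b.null_sd, b.z, b.p_emp)

    def test_degenerate_null_flagged_not_crashed(self):
        g = nx.complete_graph([f"k{i}" for i in range(12)])
        net = net_of(g)
        res = npx.degree_matched_null(net, {"k0"}, set(g.nodes), n_perm=100, seed=0)
        assert np.isnan(res.z)
        assert res.p_emp == 1.0

    def test_planted_proximal_target_detected(self):
        hits = 0
        for seed in range(20):
            truth = npx.gen_interactome(10, 25, 0.25, 0.01, seed=seed)
            sig, targets = npx.gen_signature_and_targets(
                truth, sig_size=20, n_targets=4, target_distance=0, seed=seed
            )
            full = npx.build_network(truth.interactions, set(truth.block_of), {})
            res = npx.degree_matched_null(
                full, set().union(*targets.values()), sig, n_perm=200, seed=seed
            )
            hits += res.p_emp <= 0.05
        assert hits >= 18

    def test_too_few_permutations_rejected(self, path_network):
        with pytest.raises(ValueError):
            npx.degree_matched_null(path_network, {"a"}, {"d"}, n_perm=10)


class TestRankAllProteins:
    def test_adjacent_node_outranks_distant_node(self):
        g = nx.Graph()
        sig = [f"s{i}" for i in range(5)]
        g.add_edges_from((a, b) for i, a in enumerate(sig) for b in sig[i + 1:])
        g.add_edges_from(("near", s) for s in sig)          # distance 1, degree 5
        g.add_edges_from([("s0", "m1"), ("m1", "m2"), ("m2", "far")])
        g.add_edges_from(("far", f"leaf{i}") for i in range(4))  # degree 5 too
        ranked = npx.rank_all_proteins(net_of(g), set(sig), n_perm=200, seed=0)
        ranked = ranked.set_index("id")
        assert ranked.loc["near", "rank"] < ranked.loc["far", "rank"]

    def test_signature_covering_everything_gives_empty_list(self, path_network):
        ranked = npx.rank_all_proteins(path_network, {"a", "b", "c", "d"},
                                       n_perm=100, seed=0)
        assert len(ranked) == 0

    def test_output_length_counts_non_signature_nodes(self):
        g = named_gnp(40, 0.15, seed=2)
        sig = set(sorted(g.nodes)[:10])
        ranked = npx.rank_all_proteins(net_of(g), sig, n_perm=100, seed=1)
        assert len(ranked) == 30
        assert list(ranked["rank"]) == list(range(1, 31))

    def test_observed_distances_match_brute_force(self):
        g = named_gnp(30, 0.12, seed=5)
        sig = set(sorted(g.nodes)[:6])
        ranked = npx.rank_all_proteins(net_of(g), sig, n_perm=100, seed=0)
        for _, row in ranked.iterrows():
            dists = [
                nx.shortest_path_length(g, row["id"], s)
                for s in sig if nx.has_path(g, row["id"], s)
            ]
            expected = min(dists) if dists else g.number_of_nodes()
            assert row["d_obs"] == expected


class TestMechanism:
    def test_radius_zero_is_target_itself(self, path_network):
        assert npx.mechanism_subnetwork(path_network, "b", radius=0) == {"b"}

    def test_star_radius_one_is_whole_star(self):
        g = nx.star_graph([f"n{i}" for i in range(6)])
        assert npx.mechanism_subnetwork(net_of(g), "n0", radius=1) == set(g.nodes)

    def test_path_radius_two_hand_enumeration(self, path_network):
        assert npx.mechanism_subnetwork(path_network, "a", radius=2) == {"a", "b", "c"}

    def test_identical_targets_full_overlap(self, path_network):
        res = npx.mechanism_overlap(path_network, {"a"}, {"a"})
        assert res["jaccard"] == 1.0

    def test_disjoint_components_zero_overlap(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        res = npx.mechanism_overlap(net_of(g), {"a"}, {"c"}, radius=1)
        assert res["jaccard"] == 0.0
        assert res["shared_nodes"] == []

    def test_constructed_half_union_overlap(self):
        g = nx.Graph([("t1", "c1"), ("t1", "c2"), ("t2", "c1"), ("t2", "c2")])
        res = npx.mechanism_overlap(net_of(g), {"t1"}, {"t2"}, radius=1)
        assert res["jaccard"] == pytest.approx(0.5)
        assert res["shared_nodes"] == ["c1", "c2"]


class TestProximityScorer:
    def test_fit_score_rank_round_trip(self):
        g = named_gnp(50, 0.12, seed=8)
        sig = set(sorted(g.nodes)[:12])
        scorer = npx.ProximityScorer(n_perm=100, random_state=0).fit(net_of(g), sig)
        res = scorer.score_targets(sorted(g.nodes)[20:23])
        assert res.n_perm == 100
        ranked = scorer.rank()
        assert len(ranked) == 38
        assert scorer.get_params()["metric"] == "closest"
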