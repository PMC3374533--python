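import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from healthtrust import (
    DirectedGraph,
    build_content_graph,
    build_user_graph,
    build_graph,
    content_authoritativeness,
    hits,
    minmax_normalize,
    user_authoritativeness,
)

from conftest import fav, sub, user, video


def random_digraph(seed, max_nodes=50, p=0.2):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = {
        (nodes[i], nodes[j])
        for i in range(n) for j in range(n)
        if i != j and rng.random() < p
    }
    return DirectedGraph.from_sets(nodes, edges)


def eig_authority(graph):
    """Independent oracle: authority by dense eigendecomposition of A^T A.

    The mutual-reinforcement iteration starts from a uniform hub vector, so
    its first authority vector is A^T 1; the iteration converges to the
    projection of that vector onto the dominant eigenspace of A^T A. With a
    unique dominant eigenvector this is just that eigenvector. Computed
    here in closed form, with no iteration.
    """
    n = graph.n_nodes
    index = {v: i for i, v in enumerate(graph.nodes)}
    A = np.zeros((n, n))
    for u, v in graph.edges:
        A[index[u], index[v]] = 1.0
    w, V = np.linalg.eigh(A.T @ A)
    top = w[-1]
    if top <= 0:
        return {node: 0.0 for node in graph.nodes}
    dom = V[:, w > top * (1 - 1e-9)]
    v0 = A.T @ np.ones(n)
    vec = dom @ (dom.T @ v0)
    vec = np.clip(vec, 0.0, None)
    vec /= np.linalg.norm(vec)
    return {node: vec[i] for node, i in index.items()}


class TestGraphConstruction:
    def test_subscription_gives_user_edge(self):
        g = build_graph([user("A"), user("B")], [], [sub("A", "B")])
        assert build_user_graph(g).edges == (("A", "B"),)

    def test_favorite_projects_onto_author(self):
        g = build_graph([user("A"), user("B")], [video("v", "B")], [fav("A", "v")])
        assert build_user_graph(g).edges == (("A", "B"),)

    def test_subscription_and_favorites_deduplicate(self):
        g = build_graph(
            [user("A"), user("B")],
            [video("v1", "B"), video("v2", "B")],
            [sub("A", "B"), fav("A", "v1"), fav("A", "v2")],
        )
        assert build_user_graph(g).edges == (("A", "B"),)

    def test_content_graph_favorite_edge(self):
        g = build_graph([user("A"), user("B")], [video("z", "B")], [fav("A", "z")])
        assert ("A", "z") in build_content_graph(g).edges

    def test_content_graph_subscription_expands_to_videos(self):
        g = build_graph(
            [user("A"), user("B")],
            [video("w1", "B"), video("w2", "B")],
            [sub("A", "B")],
        )
        assert set(build_content_graph(g).edges) == {("A", "w1"), ("A", "w2")}

    def test_subscription_to_videoless_channel_adds_nothing(self):
        g = build_graph([user("A"), user("B")], [], [sub("A", "B")])
        assert build_content_graph(g).edges == ()

    def test_user_edge_mode_keeps_subscription_between_users(self):
        g = build_graph(
            [user("A"), user("B")], [video("w1", "B")], [sub("A", "B")]
        )
        assert build_content_graph(g, mode="user-edge").edges == (("A", "B"),)

    def test_unknown_mode_rejected(self):
        g = build_graph([user("A")], [], [])
        with pytest.raises(ValueError):
            build_content_graph(g, mode="bogus")


class TestHits:
    def test_star_center_is_unique_authority(self):
        g = DirectedGraph.from_sets(
            ["a", "h1", "h2", "h3"], [("h1", "a"), ("h2", "a"), ("h3", "a")]
        )
        scores = hits(g)
        assert scores.raw["a"] == pytest.approx(1.0)
        for h in ("h1", "h2", "h3"):
            assert scores.raw[h] == 0.0
        assert scores.converged

    @pytest.mark.parametrize("seed", range(10))
    def test_authority_matches_dense_eigendecomposition(self, seed):
        g = random_digraph(seed)
        scores = hits(g)
        oracle = eig_authority(g)
        for node in g.nodes:
            assert scores.raw[node] == pytest.approx(oracle[node], abs=1e-6)

    def test_matches_networkx_hits_after_scale_alignment(self):
        g = random_digraph(123, max_nodes=20)
        ours = hits(g)
        nxg = nx.DiGraph()
        nxg.add_nodes_from(g.nodes)
        nxg.add_edges_from(g.edges)
        _, nx_auth = nx.hits(nxg, max_iter=1000, tol=1e-12)
        ours_n = minmax_normalize(ours.raw)
        theirs_n = minmax_normalize(nx_auth)
        for node in g.nodes:
            assert ours_n[node] == pytest.approx(theirs_n[node], abs=1e-6)

    def test_two_disjoint_identical_stars_share_authority(self):
        edges = [("h1", "a"), ("h2", "a"), ("g1", "b"), ("g2", "b")]
        scores = hits(DirectedGraph.from_sets(["a", "b", "h1", "h2", "g1", "g2"], edges))
        assert scores.raw["a"] == pytest.approx(scores.raw["b"], abs=1e-9)

    def test_empty_graph_gives_empty_scores(self):
        scores = hits(DirectedGraph.from_sets([], []))
        assert scores.raw == {} and scores.normalized == {} and scores.hub == {}

    def test_edgeless_graph_gives_all_zero(self):
        scores = hits(DirectedGraph.from_sets(["a", "b"], []))
        assert set(scores.raw.values()) == {0.0}

    def test_nonconvergence_flag(self):
        g = random_digraph(3, max_nodes=20)
        scores = hits(g, tolerance=1e-14, max_iterations=1)
        assert not scores.converged
        assert scores.n_iterations == 1

    def test_zero_indegree_nodes_get_zero_authority(self):
        g = random_digraph(9)
        scores = hits(g)
        targets = {v for _, v in g.edges}
        for node in g.nodes:
            if node not in targets:
                assert scores.raw[node] == 0.0

    def test_deterministic_bit_identical(self):
        g = random_digraph(11)
        a, b = hits(g), hits(g)
        assert a.raw == b.raw and a.hub == b.hub and a.normalized == b.normalized

    @pytest.mark.parametrize("seed", range(5))
    def test_new_incoming_edge_from_hub_never_decreases_authority(self, seed):
        rng = np.random.default_rng(seed + 1000)
        g = random_digraph(seed + 500, max_nodes=12, p=0.25)
        scores = hits(g)
        hubs = sorted(g.nodes, key=lambda n: -scores.hub[n])
        hub_node = hubs[0]
        candidates = [v for v in g.nodes if v != hub_node and (hub_node, v) not in set(g.edges)]
        if not candidates:
            pytest.skip("saturated graph")
        target = candidates[int(rng.integers(len(candidates)))]
        g2 = DirectedGraph.from_sets(g.nodes, list(g.edges) + [(hub_node, target)])
        assert hits(g2).raw[target] >= scores.raw[target] - 1e-12

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            hits(DirectedGraph.from_sets(["a"], []), tolerance=0.0)


class TestMinmaxNormalize:
    def test_closed_form(self):
        assert minmax_normalize({"a": 2, "b": 4, "c": 6}) == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_degenerate_all_equal_maps_to_zero(self):
        assert minmax_normalize({"a": 5, "b": 5}) == {"a": 0.0, "b": 0.0}

    def test_empty_mapping(self):
        assert minmax_normalize({}) == {}

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, factor):
        rng = np.random.default_rng(17)
        raw = {f"n{i}": float(v) for i, v in enumerate(rng.random(50))}
        base = minmax_normalize(raw)
        scaled = minmax_normalize({k: v * factor for k, v in raw.items()})
        for k in raw:
            assert scaled[k] == pytest.approx(base[k], abs=1e-9)

    def test_output_in_unit_interval_with_extremes(self):
        rng = np.random.default_rng(3)
        raw = {f"n{i}": float(v) for i, v in enumerate(rng.random(20))}
        out = minmax_normalize(raw)
        assert min(out.values()) == 0.0
        assert max(out.values()) == 1.0
        assert all(0.0 <= v <= 1.0 for v in out.values())


class TestComposedScores:
    def test_star_center_channel_scores_one(self, star_community):
        scores = user_authoritativeness(star_community)
        assert scores["center"] == 1.0
        assert scores["h1"] == 0.0

    def test_all_isolated_users_score_zero(self):
        g = build_graph([user("a"), user("b"), user("c")], [], [])
        assert set(user_authoritativeness(g).values()) == {0.0}

    def test_single_favorited_video_scores_one(self):
        g = build_graph(
            [user("A"), user("B")],
            [video("z", "B"), video("z2", "B")],
            [fav("A", "z")],
        )
        scores = content_authoritativeness(g)
        assert scores["z"] == 1.0
        assert scores["z2"] == 0.0

    def test_composition_matches_chained_oracle(self, preset_community):
        """Normalized user scores equal min-max over the eigenvector oracle."""
        g, _ = preset_community
        ug = build_user_graph(g)
        oracle = minmax_normalize(eig_authority(ug))
        ours = user_authoritativeness(g)
        for node in ug.nodes:
            assert ours[node] == pytest.approx(oracle[node], abs=1e-6)

    def test_content_normalization_over_content_only(self, preset_community):
        g, _ = preset_community
        scores = content_authoritativeness(g)
        assert set(scores) == set(g.content)
        assert max(scores.values()) == pytest.approx(1.0)
        assert min(scores.values()) == 0.0
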