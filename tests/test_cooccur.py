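"""Co-occurrence graph, modularity, Louvain, ego view, affiliation."""

import itertools
import random

import pytest
from scipy.stats import spearmanr

from narrascope.cooccur import (CooccurrenceGraph, affiliation, build_graph,
                                ego_subgraph, louvain, modularity,
                                normalize_strengths)
from narrascope.synth import SyntheticConfig, generate
from tests.conftest import make_corpus, make_tweet


def tag_corpus(tag_lists):
    return make_corpus([
        make_tweet(f"t{i}", "vaccine " + " ".join(f"#{t}" for t in tags))
        for i, tags in enumerate(tag_lists)
    ])


def brute_force_best_q(graph):
    """Exhaustive set-partition search (restricted growth strings)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)

    def rec(i, maxc, assign):
        if i == n:
            yield dict(zip(nodes, assign))
            return
        for c in range(maxc + 1):
            yield from rec(i + 1, max(maxc, c + 1), assign + [c])

    return max(modularity(graph, p) for p in rec(0, 0, []))


TRIANGLES = CooccurrenceGraph(
    {t: 10 for t in "abcdef"},
    {("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 1,
     ("d", "e"): 1, ("d", "f"): 1, ("e", "f"): 1},
)


class TestBuildGraph:
    def test_pair_enumeration(self):
        corpus = tag_corpus([["a", "b"], ["a", "b"], ["a", "c"]])
        g = build_graph(corpus, min_node_freq=1)
        assert g.nodes == {"a": 3, "b": 2, "c": 1}
        assert g.edges == {("a", "b"): 2, ("a", "c"): 1}

    def test_repeated_tag_counts_once_per_tweet(self):
        g = build_graph(tag_corpus([["a", "a", "b"]]), min_node_freq=1)
        assert g.edges == {("a", "b"): 1}
        assert g.nodes["a"] == 1

    def test_min_freq_prunes_nodes_and_edges(self):
        corpus = tag_corpus([["a", "b"], ["a", "b"], ["a", "c"]])
        g = build_graph(corpus, min_node_freq=2)
        assert "c" not in g.nodes and ("a", "c") not in g.edges

    def test_brute_force_on_synthetic_corpus(self):
        corpus = generate(SyntheticConfig(n_tweets=1000, n_users=400, seed=4))
        g = build_graph(corpus, min_node_freq=1)
        brute_nodes, brute_edges = {}, {}
        for rec in corpus:
            tags = sorted(set(rec.hashtags))
            for t in tags:
                brute_nodes[t] = brute_nodes.get(t, 0) + 1
            for a, b in itertools.combinations(tags, 2):
                brute_edges[(a, b)] = brute_edges.get((a, b), 0) + 1
        assert g.nodes == brute_nodes
        assert g.edges == brute_edges

    def test_tag_free_corpus_gives_empty_graph(self):
        g = build_graph(make_corpus([make_tweet("t1", "vaccine only")]))
        assert g.nodes == {} and g.edges == {}


class TestStrengths:
    def test_single_edge_is_one(self):
        g = CooccurrenceGraph({"a": 5, "b": 5}, {("a", "b"): 3})
        assert normalize_strengths(g).strengths == {("a", "b"): 1.0}

    def test_direct_ratios(self):
        g = CooccurrenceGraph(
            {t: 20 for t in "abcd"},
            {("a", "b"): 10, ("a", "c"): 5, ("a", "d"): 2},
        )
        s = normalize_strengths(g).strengths
        assert s == {("a", "b"): 1.0, ("a", "c"): 0.5, ("a", "d"): 0.2}

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            normalize_strengths(CooccurrenceGraph({"a": 1}, {}))

    def test_rank_preserved(self):
        rng = random.Random(0)
        edges = {(f"a{i}", f"b{i}"): rng.randint(1, 50) for i in range(20)}
        nodes = {t: 60 for e in edges for t in e}
        s = normalize_strengths(CooccurrenceGraph(nodes, edges)).strengths
        counts = [edges[e] for e in sorted(edges)]
        strengths = [s[e] for e in sorted(edges)]
        assert spearmanr(counts, strengths).statistic == 1.0


class TestModularity:
    def test_two_triangles_split(self):
        part = {t: 0 for t in "abc"} | {t: 1 for t in "def"}
        assert modularity(TRIANGLES, part) == pytest.approx(0.5, abs=1e-12)

    def test_single_community_is_zero(self):
        part = {t: 0 for t in TRIANGLES.nodes}
        assert modularity(TRIANGLES, part) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_oracle(self):
        """Q equals the brute-force (1/2m)*sum_ij formula to 1e-12."""
        rng = random.Random(7)
        for _ in range(20):
            n = rng.randint(3, 7)
            names = [f"t{i}" for i in range(n)]
            edges = {}
            for a, b in itertools.combinations(names, 2):
                if rng.random() < 0.6:
                    edges[(a, b)] = rng.randint(1, 9)
            if not edges:
                edges[(names[0], names[1])] = 1
            g = CooccurrenceGraph({t: 100 for t in names}, edges)
            part = {t: rng.randint(0, 2) for t in names}
            w = {(a, b): 0.0 for a in names for b in names}
            for (a, b), wt in edges.items():
                w[(a, b)] = w[(b, a)] = wt
            k = {a: sum(w[(a, b)] for b in names) for a in names}
            m2 = sum(k.values())
            q = sum(
                (w[(a, b)] - k[a] * k[b] / m2)
                for a in names for b in names if part[a] == part[b]
            ) / m2
            assert modularity(g, part) == pytest.approx(q, abs=1e-12)

    def test_incomplete_assignment_errors(self):
        with pytest.raises(ValueError):
            modularity(TRIANGLES, {"a": 0})

    def test_edgeless_graph_errors(self):
        with pytest.raises(ValueError):
            modularity(CooccurrenceGraph({"a": 1}, {}), {"a": 0})


class TestLouvain:
    def test_two_triangles_recovered(self):
        part = louvain(TRIANGLES, seed=0)
        assert part.n_communities == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        assert {frozenset(c) for c in part.communities()} == {
            frozenset("abc"), frozenset("def")}

    def test_complete_graph_stays_whole(self):
        k4 = CooccurrenceGraph(
            {t: 10 for t in "abcd"},
            {e: 1 for e in itertools.combinations("abcd", 2)},
        )
        assert louvain(k4, seed=0).n_communities == 1

    def test_never_below_singleton_baseline(self):
        rng = random.Random(1)
        for seed in range(10):
            names = [f"t{i}" for i in range(6)]
            edges = {e: rng.randint(1, 5)
                     for e in itertools.combinations(names, 2)
                     if rng.random() < 0.5}
            if not edges:
                continue
            g = CooccurrenceGraph({t: 50 for t in names}, edges)
            part = louvain(g, seed=seed)
            singleton = modularity(g, {t: i for i, t in enumerate(names)})
            assert part.modularity >= singleton - 1e-12

    def test_history_non_decreasing(self):
        corpus = generate(SyntheticConfig(n_tweets=3000, n_users=1200, seed=6))
        part = louvain(build_graph(corpus, 2), seed=2)
        assert all(a <= b + 1e-12
                   for a, b in zip(part.history, part.history[1:]))

    def test_deterministic_given_seed(self):
        corpus = generate(SyntheticConfig(n_tweets=3000, n_users=1200, seed=6))
        g = build_graph(corpus, 2)
        assert louvain(g, seed=3) == louvain(g, seed=3)

    def test_reported_modularity_matches_recomputation(self):
        part = louvain(TRIANGLES, seed=5)
        assert part.modularity == pytest.approx(
            modularity(TRIANGLES, part.assignment), abs=1e-12)

    def test_planted_partition_recovered(self):
        """With p_out=0 the co-occurrence graph splits into the planted
        communities exactly (adjusted Rand index 1)."""
        from sklearn.metrics import adjusted_rand_score
        cfg = SyntheticConfig(n_tweets=5000, n_users=2000, p_out=0.0, seed=7)
        g = build_graph(generate(cfg), min_node_freq=2)
        part = louvain(g, seed=1)
        truth = {t: i for i, comm in enumerate(cfg.hashtag_communities)
                 for t in comm}
        nodes = sorted(g.nodes)
        ari = adjusted_rand_score([truth[t] for t in nodes],
                                  [part.assignment[t] for t in nodes])
        assert ari == 1.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            louvain(CooccurrenceGraph({}, {}), seed=0)

    def test_near_optimal_on_small_graphs(self):
        """Achieved Q is at least 95% of the exhaustive optimum on
        seeded random graphs of at most 8 nodes."""
        rng = random.Random(42)
        for trial in range(15):
            import networkx as nx
            n = rng.randint(4, 8)
            raw = nx.gnp_random_graph(n, 0.5, seed=rng.randint(0, 10 ** 6))
            if raw.number_of_edges() == 0:
                raw.add_edge(0, 1)
            edges = {}
            for u, v in raw.edges:
                a, b = sorted((f"t{u}", f"t{v}"))
                edges[(a, b)] = rng.randint(1, 5)
            g = CooccurrenceGraph({f"t{i}": 100 for i in raw.nodes}, edges)
            best = brute_force_best_q(g)
            got = louvain(g, seed=trial).modularity
            if best > 0:
                assert got >= 0.95 * best

    def test_cross_check_against_networkx(self):
        """Independent oracle: the networkx Louvain reaches the same
        modularity on a mid-size synthetic hashtag graph."""
        import networkx.algorithms.community as nxc
        g = build_graph(
            generate(SyntheticConfig(n_tweets=10_000, n_users=4_000, seed=8)),
            min_node_freq=2,
        )
        nxg = g.to_networkx()
        comms = nxc.louvain_communities(nxg, weight="weight", seed=5)
        q_nx = nxc.modularity(nxg, comms, weight="weight")
        q_mine = louvain(g, seed=5).modularity
        assert q_mine >= q_nx - 0.01


class TestEgoAndAffiliation:
    STAR = CooccurrenceGraph(
        {"hub": 10, "a": 5, "b": 5, "c": 5, "d": 5},
        {("a", "hub"): 4, ("b", "hub"): 3, ("c", "hub"): 2, ("d", "hub"): 1},
    )

    def test_top_k_neighbors(self):
        sub = ego_subgraph(self.STAR, "hub", top_k=2)
        assert set(sub.nodes) == {"hub", "a", "b"}

    def test_top_k_zero_single_node(self):
        assert set(ego_subgraph(self.STAR, "hub", 0).nodes) == {"hub"}

    def test_top_k_beyond_degree(self):
        assert set(ego_subgraph(self.STAR, "hub", 99).nodes) == set(
            self.STAR.nodes)

    def test_absent_ego_anchor_errors(self):
        with pytest.raises(KeyError):
            ego_subgraph(self.STAR, "nope", 2)

    def test_half_cooccurrence(self):
        corpus = tag_corpus([["h", "x"], ["h", "x"], ["h"], ["h"], ["x"]])
        [rec] = affiliation(corpus, "x", top_n=1)
        assert (rec.co_count, rec.total_count, rec.affiliation_pct) == (
            2, 4, 50.00)

    def test_full_affiliation_is_100(self):
        corpus = tag_corpus([["h", "x"], ["h", "x"], ["x"]])
        [rec] = affiliation(corpus, "x", top_n=1)
        assert rec.affiliation_pct == 100.00

    def test_table_format_ratio(self):
        # co=2371 of total=4606 -> 51.48
        tweets = [["anchor", "b1less"]] * 2371 + [["b1less"]] * 2235
        rec = affiliation(tag_corpus(tweets), "anchor", top_n=1)[0]
        assert rec.total_count == 4606
        assert rec.affiliation_pct == 51.48

    def test_anchor_excluded_and_range(self):
        corpus = tag_corpus([["x", "a"], ["x", "b"], ["x"]])
        recs = affiliation(corpus, "x", top_n=10)
        assert all(r.hashtag != "#x" for r in recs)
        assert all(0 <= r.affiliation_pct <= 100 for r in recs)

    def test_absent_anchor_errors(self):
        with pytest.raises(KeyError):
            affiliation(tag_corpus([["a"]]), "missing")
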