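"""Hashtag co-occurrence graph, Louvain communities, and affiliation.

The narrative structure of a corpus is read off an undirected weighted
graph whose nodes are hashtags and whose edge weights count the tweets
in which both endpoint tags appear. Communities in this graph are found
by modularity maximization (the two-phase Louvain algorithm, written
out here rather than delegated, with a seeded node order and
deterministic tie-breaking so runs are reproducible). Edge strengths
are reported normalized to the heaviest edge, whose strength is 1.00
by convention.

The affiliation statistic quantifies how exclusively a hashtag belongs
to an anchor hashtag's narrative: 100 x (tweets containing both) /
(tweets containing the hashtag).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from ._util import round_half_up
from .corpus import Corpus

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class CooccurrenceGraph:
    """Weighted undirected hashtag graph.

    ``nodes`` maps tag -> number of tweets containing it; ``edges``
    maps an ordered tag pair -> number of tweets containing both;
    ``strengths`` (set by :func:`normalize_strengths`) maps each pair
    to weight/max-weight in (0, 1].
    """

    nodes: dict[str, int]
    edges: dict[Edge, int]
    strengths: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references missing node")
            if w > min(self.nodes[a], self.nodes[b]):
                raise ValueError(
                    f"edge ({a}, {b}) count exceeds endpoint frequency"
                )

    def neighbors(self, tag: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for (a, b), w in self.edges.items():
            if a == tag:
                out[b] = w
            elif b == tag:
                out[a] = w
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for tag, freq in self.nodes.items():
            g.add_node(tag, frequency=freq)
        for (a, b), w in self.edges.items():
            attrs = {"weight": w}
            if self.strengths:
                attrs["strength"] = round_half_up(self.strengths[(a, b)], 2)
            g.add_edge(a, b, **attrs)
        return g


def build_graph(corpus: Corpus, min_node_freq: int = 2) -> CooccurrenceGraph:
    """Count tag frequencies and pairwise co-occurrences per tweet.

    A tag repeated inside one tweet counts once; a pair counts once per
    tweet containing both. Nodes below ``min_node_freq`` are removed
    together with their edges.
    """
    if min_node_freq < 1:
        raise ValueError("min_node_freq must be >= 1")
    nodes: dict[str, int] = {}
    edges: dict[Edge, int] = {}
    for rec in corpus:
        tags = sorted(set(rec.hashtags))
        for t in tags:
            nodes[t] = nodes.get(t, 0) + 1
        for a, b in combinations(tags, 2):
            e = (a, b)
            edges[e] = edges.get(e, 0) + 1
    kept = {t: f for t, f in nodes.items() if f >= min_node_freq}
    kept_edges = {
        e: w for e, w in edges.items() if e[0] in kept and e[1] in kept
    }
    return CooccurrenceGraph(kept, kept_edges)


def normalize_strengths(graph: CooccurrenceGraph) -> CooccurrenceGraph:
    """Attach strengths: edge weight divided by the maximum weight.

    The heaviest edge gets strength exactly 1.0; ordering by strength
    equals ordering by count. Raises ValueError on an edgeless graph.
    """
    if not graph.edges:
        raise ValueError("graph has no edges")
    wmax = max(graph.edges.values())
    strengths = {e: w / wmax for e, w in graph.edges.items()}
    return CooccurrenceGraph(dict(graph.nodes), dict(graph.edges), strengths)


def modularity(
    graph: CooccurrenceGraph, assignment: dict[str, int],
    resolution: float = 1.0,
) -> float:
    """Weighted Newman modularity of a partition.

    Q = (1/2m) * sum_ij [A_ij - r*k_i*k_j/(2m)] * delta(c_i, c_j) with
    A the co-occurrence weight matrix. Raises on an edgeless graph or
    an assignment that does not cover every node.
    """
    if not graph.edges:
        raise ValueError("modularity undefined on an edgeless graph")
    if set(assignment) != set(graph.nodes):
        raise ValueError("assignment must cover exactly the graph nodes")
    degree: dict[str, float] = {t: 0.0 for t in graph.nodes}
    m2 = 0.0
    intra = 0.0
    for (a, b), w in graph.edges.items():
        degree[a] += w
        degree[b] += w
        m2 += 2 * w
        if assignment[a] == assignment[b]:
            intra += w
    comm_degree: dict[int, float] = {}
    for t, k in degree.items():
        c = assignment[t]
        comm_degree[c] = comm_degree.get(c, 0.0) + k
    q = 2 * intra / m2
    q -= resolution * sum((kc / m2) ** 2 for kc in comm_degree.values())
    return q


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment (contiguous ids from 0) with its
    modularity and the per-level modularity trajectory."""

    assignment: dict[str, int]
    modularity: float
    history: tuple[float, ...] = ()

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def _one_level(
    adj: dict[int, dict[int, float]],
    loops: dict[int, float],
    m2: float,
    rng: random.Random,
    resolution: float,
) -> tuple[dict[int, int], bool]:
    """Phase 1: greedy local moves until no single move improves Q.

    Node degrees count self-loops twice (standard convention for
    aggregated graphs). Ties in modularity gain go to the lowest
    community id so runs are reproducible.
    """
    nodes = sorted(adj)
    comm = {v: v for v in nodes}
    degree = {v: sum(adj[v].values()) + 2 * loops.get(v, 0.0) for v in nodes}
    comm_degree = dict(degree)  # singleton start
    improved = False
    moved = True
    while moved:
        moved = False
        order = nodes[:]
        rng.shuffle(order)
        for v in order:
            old = comm[v]
            kv = degree[v]
            # weight from v to each neighboring community
            links: dict[int, float] = {old: 0.0}
            for nbr, w in adj[v].items():
                if nbr != v:
                    c = comm[nbr]
                    links[c] = links.get(c, 0.0) + w
            comm_degree[old] -= kv
            best_c, best_gain = old, links.get(old, 0.0) - (
                resolution * comm_degree[old] * kv / m2
            )
            for c in sorted(links):
                if c == old:
                    continue
                gain = links[c] - resolution * comm_degree[c] * kv / m2
                if gain > best_gain + 1e-12 or (
                    abs(gain - best_gain) <= 1e-12 and c < best_c
                ):
                    best_c, best_gain = c, gain
            comm_degree[best_c] = comm_degree.get(best_c, 0.0) + kv
            if best_c != old:
                comm[v] = best_c
                moved = True
                improved = True
    return comm, improved


def _aggregate(
    adj: dict[int, dict[int, float]],
    loops: dict[int, float],
    comm: dict[int, int],
) -> tuple[dict[int, dict[int, float]], dict[int, float], dict[int, int]]:
    """Phase 2: collapse communities into super-nodes with self-loops."""
    relabel = {c: i for i, c in enumerate(sorted(set(comm.values())))}
    new_adj: dict[int, dict[int, float]] = {i: {} for i in relabel.values()}
    new_loops: dict[int, float] = {i: 0.0 for i in relabel.values()}
    for v, nbrs in adj.items():
        cv = relabel[comm[v]]
        for nbr, w in nbrs.items():
            if nbr <= v:
                continue  # undirected: visit each pair once
            cn = relabel[comm[nbr]]
            if cv == cn:
                new_loops[cv] += w
            else:
                new_adj[cv][cn] = new_adj[cv].get(cn, 0.0) + w
                new_adj[cn][cv] = new_adj[cn].get(cv, 0.0) + w
    for v, w in loops.items():
        new_loops[relabel[comm[v]]] += w
    return new_adj, new_loops, relabel


def louvain(
    graph: CooccurrenceGraph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 8,
) -> CommunityPartition:
    """Two-phase Louvain modularity maximization with seeded restarts.

    Each restart runs greedy local node moves (seeded visit order,
    lowest-community-id tie-break) followed by community aggregation,
    repeated until no move improves modularity; the best-modularity
    partition over ``n_restarts`` differently-seeded runs is returned
    (greedy Louvain is order-dependent and can stall in local optima
    on small graphs; restarts recover the global optimum there at
    negligible cost). Deterministic for a given ``seed``. The returned
    modularity never falls below the all-singletons baseline, and the
    recorded per-level trajectory is non-decreasing.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: CommunityPartition | None = None
    for r in range(n_restarts):
        part = _louvain_once(graph, seed + r, resolution)
        if best is None or part.modularity > best.modularity + 1e-12:
            best = part
    assert best is not None
    return best


def _louvain_once(
    graph: CooccurrenceGraph, seed: int, resolution: float
) -> CommunityPartition:
    if not graph.edges:
        raise ValueError("louvain requires a graph with at least one edge")
    names = sorted(graph.nodes)
    index = {t: i for i, t in enumerate(names)}
    adj: dict[int, dict[int, float]] = {i: {} for i in range(len(names))}
    for (a, b), w in graph.edges.items():
        adj[index[a]][index[b]] = float(w)
        adj[index[b]][index[a]] = float(w)
    loops: dict[int, float] = {}
    m2 = 2.0 * sum(graph.edges.values())
    rng = random.Random(seed)

    # mapping from original node index to current community label
    membership = {i: i for i in adj}
    history: list[float] = []
    while True:
        comm, improved = _one_level(adj, loops, m2, rng, resolution)
        if not improved and history:
            break
        adj, loops, relabel = _aggregate(adj, loops, comm)
        membership = {v: relabel[comm[membership[v]]] for v in membership}
        assignment = {names[v]: c for v, c in membership.items()}
        q = modularity(graph, assignment, resolution)
        if history and q < history[-1] - 1e-12:
            raise AssertionError("modularity decreased across levels")
        history.append(q)
        if not improved:
            break

    # contiguous ids in order of first appearance over sorted node names
    final = {names[v]: membership[v] for v in membership}
    relabel2: dict[int, int] = {}
    for t in names:
        c = final[t]
        if c not in relabel2:
            relabel2[c] = len(relabel2)
    assignment = {t: relabel2[final[t]] for t in names}
    q = modularity(graph, assignment, resolution)
    singleton_q = modularity(graph, {t: i for i, t in enumerate(names)},
                             resolution)
    if q < singleton_q - 1e-12:
        raise AssertionError("louvain fell below the singleton baseline")
    return CommunityPartition(assignment, q, tuple(history))


def ego_subgraph(
    graph: CooccurrenceGraph, anchor: str, top_k: int
) -> CooccurrenceGraph:
    """Induced subgraph on the anchor and its top-k co-occurring
    neighbors by edge weight (ties broken lexicographically)."""
    anchor = anchor.lstrip("#").lower()
    if anchor not in graph.nodes:
        raise KeyError(f"anchor {anchor!r} not in graph")
    nbrs = graph.neighbors(anchor)
    top = sorted(nbrs, key=lambda t: (-nbrs[t], t))[:top_k]
    keep = {anchor, *top}
    nodes = {t: graph.nodes[t] for t in keep}
    edges = {
        e: w for e, w in graph.edges.items() if e[0] in keep and e[1] in keep
    }
    return CooccurrenceGraph(nodes, edges, {
        e: s for e, s in graph.strengths.items() if e in edges
    })


@dataclass(frozen=True)
class AffiliationRecord:
    """Co-occurrence of a hashtag with an anchor hashtag, and the share
    of the hashtag's total presence that the co-occurrence represents."""

    hashtag: str  # display form with '#'
    anchor: str
    co_count: int
    total_count: int
    affiliation_pct: float  # 100*co/total, half-up 2 decimals

    def __post_init__(self) -> None:
        if not 0 <= self.co_count <= self.total_count:
            raise ValueError("co_count must lie in [0, total_count]")


def affiliation(
    corpus: Corpus, anchor: str, top_n: int = 10
) -> list[AffiliationRecord]:
    """Rank hashtags by co-occurrence with an anchor hashtag.

    For each tag h != anchor: co_count = tweets containing both h and
    the anchor; affiliation_pct = 100*co_count/(tweets containing h).
    Ranked by co_count descending (lexicographic tie-break), top_n
    returned. Raises KeyError if the anchor never occurs.
    """
    anchor = anchor.lstrip("#").lower()
    totals: dict[str, int] = {}
    co: dict[str, int] = {}
    for rec in corpus:
        tags = set(rec.hashtags)
        for t in tags:
            totals[t] = totals.get(t, 0) + 1
        if anchor in tags:
            for t in tags:
                if t != anchor:
                    co[t] = co.get(t, 0) + 1
    if anchor not in totals:
        raise KeyError(f"anchor {anchor!r} absent from corpus")
    ranked = sorted(co.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [
        AffiliationRecord(
            hashtag=f"#{t}",
            anchor=f"#{anchor}",
            co_count=c,
            total_count=totals[t],
            affiliation_pct=round_half_up(100.0 * c / totals[t], 2),
        )
        for t, c in ranked
    ]
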