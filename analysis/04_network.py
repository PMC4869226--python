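#!/usr/bin/env python
"""Narrative structure: hashtag co-occurrence graph, Louvain
communities, normalized strengths, and the affiliation table around
the anchor hashtag of the antivaccination narrative.

Reads results/corpus.jsonl; writes results/graph.graphml,
results/partition.tsv, results/strengths.csv, results/affiliation.csv.
"""

from datetime import date
from pathlib import Path

import networkx as nx

from narrascope.cooccur import (affiliation, build_graph, louvain,
                                normalize_strengths)
from narrascope._util import round_half_up
from narrascope.corpus import read_corpus, write_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = (date(2015, 2, 1), date(2015, 3, 9))
ANCHOR = "cdcwhistleblower"


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl", WINDOW)
    graph = normalize_strengths(build_graph(corpus, min_node_freq=2))
    part = louvain(graph, seed=1)

    nx.write_graphml(graph.to_networkx(), RESULTS / "graph.graphml")
    write_table(
        [{"hashtag": t, "community": c}
         for t, c in sorted(part.assignment.items())],
        RESULTS / "partition.tsv", format="tsv",
    )
    strengths = sorted(graph.strengths.items(), key=lambda kv: -kv[1])
    write_table(
        [{"tag_a": a, "tag_b": b, "count": graph.edges[(a, b)],
          "strength": round_half_up(s, 2)}
         for (a, b), s in strengths],
        RESULTS / "strengths.csv",
    )
    aff = affiliation(corpus, ANCHOR, top_n=11)
    write_table([a.__dict__ for a in aff], RESULTS / "affiliation.csv")

    print(f"graph: {len(graph.nodes)} hashtags, {len(graph.edges)} edges")
    print(f"louvain: {part.n_communities} communities, "
          f"Q = {part.modularity:.4f}")
    for i, comm in enumerate(part.communities()):
        print(f"  community {i}: {', '.join(sorted(comm))}")
    print("strongest co-occurrences:")
    for (a, b), s in strengths[:5]:
        print(f"  #{a} - #{b}: strength {round_half_up(s, 2):.2f} "
              f"({graph.edges[(a, b)]} tweets)")
    print(f"affiliation with #{ANCHOR}:")
    for rec in aff[:5]:
        print(f"  {rec.hashtag:<16} co={rec.co_count:>5} "
              f"affiliation={rec.affiliation_pct}%")


if __name__ == "__main__":
    main()
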