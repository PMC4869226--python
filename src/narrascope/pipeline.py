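"""End-to-end pipeline: corpus -> term, network, retweet and geographic
tables, plus a machine-readable corpus-characteristics summary.

Every number in the summary is recomputed by the corresponding stage
function — the report never computes anything itself. Stage outputs
are plain files so any stage can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import networkx as nx

from . import geo as geo_mod
from . import influence as infl_mod
from .cooccur import affiliation, build_graph, louvain, normalize_strengths
from .corpus import (Corpus, filter_by_keywords, load_populations,
                     read_corpus, write_corpus, write_table)
from .synth import DEFAULT_KEYWORDS, SyntheticConfig, generate, summarize
from .textstats import (StopWordPolicy, per_user_stats, daily_rate,
                        term_frequencies, share_pct)

logger = logging.getLogger(__name__)


def default_populations() -> dict[str, int]:
    """Bundled synthetic US state population fixture (2014-style
    estimates assembled by hand; supply your own table for real work)."""
    ref = resources.files("narrascope.data").joinpath(
        "us_state_populations_2014_synthetic.csv"
    )
    with resources.as_file(ref) as path:
        return load_populations(path)


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``input_path`` / ``synthetic`` must be given."""

    outdir: Path
    input_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    keywords: frozenset[str] = DEFAULT_KEYWORDS
    stop_policy: StopWordPolicy = field(default_factory=StopWordPolicy)
    min_node_freq: int = 2
    anchor: str = "cdcwhistleblower"
    top_terms: int = 75
    top_affiliation: int = 10
    population_path: Path | None = None
    geo_level: str = "admin1"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of input_path / synthetic must be configured"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing tables under ``config.outdir``.

    Writes terms.csv, graph.graphml, partition.tsv, affiliation.csv,
    influence.csv, geo.csv, corpus.jsonl (synthetic runs only) and
    summary.json; returns the summary dict. Any stage failure aborts
    with an error naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if config.synthetic is not None:
            corpus = generate(config.synthetic)
            write_corpus(corpus, out / "corpus.jsonl")
        else:
            assert config.input_path is not None
            corpus = read_corpus(
                config.input_path,
                (date(2015, 2, 1), date(2015, 3, 9)),  # collection window
                config.keywords,
            )
        stage = "filter"
        corpus = filter_by_keywords(corpus, config.keywords)
        logger.info("stage %s: %d records", stage, len(corpus))

        stage = "terms"
        terms = term_frequencies(corpus, config.stop_policy, config.top_terms)
        write_table(
            [t.__dict__ for t in terms], out / "terms.csv"
        )

        stage = "network"
        graph = build_graph(corpus, config.min_node_freq)
        summary_network: dict = {"n_nodes": len(graph.nodes),
                                 "n_edges": len(graph.edges)}
        if graph.edges:
            graph = normalize_strengths(graph)
            part = louvain(graph, seed=config.seed)
            nx.write_graphml(graph.to_networkx(), out / "graph.graphml")
            write_table(
                [{"hashtag": t, "community": c}
                 for t, c in sorted(part.assignment.items())],
                out / "partition.tsv", format="tsv",
            )
            summary_network.update(
                modularity=part.modularity,
                n_communities=part.n_communities,
            )

        stage = "affiliation"
        try:
            aff = affiliation(corpus, config.anchor, config.top_affiliation)
        except KeyError:
            aff = []
        write_table([a.__dict__ for a in aff], out / "affiliation.csv")

        stage = "populations"
        populations = (
            load_populations(config.population_path)
            if config.population_path else default_populations()
        )

        stage = "retweets"
        rt_share = infl_mod.retweet_share(corpus)
        try:
            dist = infl_mod.retweet_distribution(corpus)
            rt_median, rt_max = dist.median, dist.max
            write_table(
                [{"retweet_count": k, "n_originals": v}
                 for k, v in dist.histogram.items()],
                out / "retweet_histogram.csv",
            )
        except ValueError:
            rt_median = rt_max = None
        geo_counts = geo_mod.aggregate_by_region(corpus, config.geo_level)
        scored = {r: c for r, c in geo_counts.items() if r in populations}
        if scored:
            sub = Corpus(
                tuple(r for r in corpus
                      if r.region(config.geo_level) in populations
                      or r.region(config.geo_level) is None),
                corpus.window_start, corpus.window_end, corpus.keywords,
            )
            by_inf, by_amp = infl_mod.region_influence(
                sub, populations, config.geo_level
            )
            write_table([i.__dict__ for i in by_inf], out / "influence.csv")
        else:
            write_table([], out / "influence.csv")

        stage = "geo"
        ranked = geo_mod.participation(scored, populations)
        write_table([g.__dict__ for g in ranked], out / "geo.csv")

        stage = "report"
        tiers = {"precise": 0, "toponym": 0, "none": 0}
        for r in corpus:
            tiers[r.geo_tier] += 1
        n = len(corpus)
        pu = per_user_stats(corpus)
        summary = {
            "seed": config.seed,
            "n_tweets": n,
            "n_days": corpus.n_days,
            "tweets_per_day": daily_rate(n, corpus.n_days),
            "n_users": pu.n_users,
            "mean_tweets_per_user": pu.mean_tweets_per_user,
            "median_tweets_per_user": pu.median_tweets_per_user,
            "retweet_share_pct": rt_share,
            "retweet_median": rt_median,
            "retweet_max": rt_max,
            "geo_tiers": tiers,
            "geolocated_share_pct": share_pct(
                tiers["precise"] + tiers["toponym"], n
            ),
            "network": summary_network,
            "top_terms": [t.term for t in terms[:10]],
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
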