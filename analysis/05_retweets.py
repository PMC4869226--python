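#!/usr/bin/env python
"""Retweeting patterns: overall/US/overseas retweet shares, the skewed
per-original retweet distribution, and state influencer/amplifier
rankings.

Reads results/corpus.jsonl; writes results/retweet_histogram.csv and
results/influence.csv.
"""

from datetime import date
from pathlib import Path

from narrascope.corpus import Corpus, read_corpus, write_table
from narrascope.influence import (region_influence, retweet_distribution,
                                  retweet_share)
from narrascope.pipeline import default_populations

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = (date(2015, 2, 1), date(2015, 3, 9))


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl", WINDOW)
    print(f"retweet share overall: {retweet_share(corpus)}%")
    print(f"  within US: {retweet_share(corpus, 'US')}%")
    print(f"  overseas:  "
          f"{retweet_share(corpus, lambda r: r.country not in (None, 'US'))}%")

    dist = retweet_distribution(corpus)
    print(f"per-original retweets: median {dist.median:.0f}, max {dist.max}")
    write_table(
        [{"retweet_count": k, "n_originals": v}
         for k, v in dist.histogram.items()],
        RESULTS / "retweet_histogram.csv",
    )

    pops = default_populations()
    kept = tuple(r for r in corpus
                 if r.admin1 is None or r.admin1 in pops)
    sub = Corpus(kept, corpus.window_start, corpus.window_end,
                 corpus.keywords)
    by_inf, by_amp = region_influence(sub, pops, level="admin1")
    write_table([i.__dict__ for i in by_inf], RESULTS / "influence.csv")
    print("top influencer states (retweets of their originals per 10k):")
    for r in by_inf[:5]:
        print(f"  {r.region}: {r.influencer_score:.2f}")
    print("top amplifier states (share of their tweets that are retweets):")
    for r in by_amp[:5]:
        print(f"  {r.region}: {r.amplifier_score:.2%}")


if __name__ == "__main__":
    main()
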