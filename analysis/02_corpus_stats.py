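#!/usr/bin/env python
"""Corpus characteristics: totals, geolocation tiers, per-user and
daily rates — the machine twin of a data-characteristics section.

Reads results/corpus.jsonl, writes results/corpus_stats.csv.
"""

from datetime import date
from pathlib import Path

from narrascope.corpus import read_corpus, write_table
from narrascope.textstats import daily_rate, per_user_stats, share_pct

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = (date(2015, 2, 1), date(2015, 3, 9))


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl", WINDOW)
    n = len(corpus)
    tiers = {"precise": 0, "toponym": 0, "none": 0}
    for r in corpus:
        tiers[r.geo_tier] += 1
    n_geo = tiers["precise"] + tiers["toponym"]
    pu = per_user_stats(corpus)
    n_rt = sum(r.is_retweet for r in corpus)

    rows = [
        {"quantity": "tweets", "value": n, "share_pct": ""},
        {"quantity": "geolocated", "value": n_geo,
         "share_pct": share_pct(n_geo, n)},
        {"quantity": "precise", "value": tiers["precise"],
         "share_pct": share_pct(tiers["precise"], n)},
        {"quantity": "toponym", "value": tiers["toponym"],
         "share_pct": share_pct(tiers["toponym"], n)},
        {"quantity": "retweets", "value": n_rt,
         "share_pct": share_pct(n_rt, n)},
        {"quantity": "distinct_users", "value": pu.n_users, "share_pct": ""},
        {"quantity": "mean_tweets_per_user",
         "value": pu.mean_tweets_per_user, "share_pct": ""},
        {"quantity": "median_tweets_per_user",
         "value": pu.median_tweets_per_user, "share_pct": ""},
        {"quantity": "tweets_per_day",
         "value": daily_rate(n, corpus.n_days), "share_pct": ""},
    ]
    write_table(rows, RESULTS / "corpus_stats.csv")
    for row in rows:
        extra = f" ({row['share_pct']}%)" if row["share_pct"] != "" else ""
        print(f"{row['quantity']}: {row['value']}{extra}")


if __name__ == "__main__":
    main()
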