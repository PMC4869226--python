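#!/usr/bin/env python
"""Geographic participation: country totals, and state-level
population-normalized participation overall and per topic
("1 tweet per X persons"; lower X = higher participation).

Reads results/corpus.jsonl; writes results/countries.csv,
results/geo.csv and results/topic_<term>.csv.
"""

from datetime import date
from pathlib import Path

from narrascope.corpus import read_corpus, write_table
from narrascope.geo import (aggregate_by_region, participation,
                            topic_participation)
from narrascope.pipeline import default_populations
from narrascope.textstats import share_pct

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = (date(2015, 2, 1), date(2015, 3, 9))
TOPICS = ("measles", "autism", "#cdcwhistleblower")


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl", WINDOW)

    countries = aggregate_by_region(corpus, "country")
    n_geo = sum(countries.values())
    rows = sorted(countries.items(), key=lambda kv: -kv[1])
    write_table(
        [{"country": c, "tweets": n, "share_pct": share_pct(n, n_geo)}
         for c, n in rows],
        RESULTS / "countries.csv",
    )
    print("top countries (share of geolocated total):")
    for c, n in rows[:5]:
        print(f"  {c}: {n} ({share_pct(n, n_geo)}%)")

    pops = default_populations()
    states = {
        r: c for r, c in aggregate_by_region(corpus, "admin1").items()
        if r in pops
    }
    ranked = participation(states, pops)
    write_table([g.__dict__ for g in ranked], RESULTS / "geo.csv")
    print("state participation (1 tweet per X persons, best five):")
    for g in ranked[:5]:
        print(f"  {g.region}: 1 in {g.one_in_x} "
              f"({g.rate_per_10k}/10k residents)")

    for term in TOPICS:
        topic = topic_participation(corpus, term, pops, level="admin1")
        safe = term.lstrip("#")
        write_table([g.__dict__ for g in topic],
                    RESULTS / f"topic_{safe}.csv")
        top = ", ".join(f"{g.region} 1 in {g.one_in_x}" for g in topic[:3])
        print(f"topic {term}: {top if top else 'no geolocated mentions'}")


if __name__ == "__main__":
    main()
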