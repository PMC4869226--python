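#!/usr/bin/env python
"""Dominant terms: ranked tweet-level frequency table with stop words,
common words and the search keywords themselves excluded.

Reads results/corpus.jsonl, writes results/terms.csv.
"""

from datetime import date
from pathlib import Path

from narrascope.corpus import read_corpus, write_table
from narrascope.synth import DEFAULT_KEYWORDS
from narrascope.textstats import StopWordPolicy, term_frequencies

RESULTS = Path(__file__).resolve().parent.parent / "results"
WINDOW = (date(2015, 2, 1), date(2015, 3, 9))


def main() -> None:
    corpus = read_corpus(RESULTS / "corpus.jsonl", WINDOW)
    policy = StopWordPolicy(excluded_terms=frozenset(DEFAULT_KEYWORDS))
    terms = term_frequencies(corpus, policy, top_n=75)
    write_table([t.__dict__ for t in terms], RESULTS / "terms.csv")
    print(f"{len(terms)} terms; top 10:")
    for t in terms[:10]:
        print(f"  {t.term:<20} {t.mentions:>7}  ({t.share_pct}%)")


if __name__ == "__main__":
    main()
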