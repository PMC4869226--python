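#!/usr/bin/env python
"""Generate the stated-world synthetic corpus used by all later steps.

The generator's defaults encode the observed corpus structure (44.27%
retweets; 0.94% precise / 52.60% toponym geolocation; power-law user
activity; four planted hashtag communities). For the geographic steps
the region mixture is refined here: the US share of geolocated traffic
is spread over states proportionally to population, the rest over the
other top contributing countries.

Writes results/corpus.jsonl and prints the recovered parameters.
"""

import argparse
from pathlib import Path

from narrascope.pipeline import default_populations
from narrascope.synth import (DEFAULT_REGION_WEIGHTS, SyntheticConfig,
                              generate, summarize)
from narrascope.corpus import write_corpus

RESULTS = Path(__file__).resolve().parent.parent / "results"


def state_region_weights() -> dict[str, float]:
    pops = default_populations()
    us_total = sum(pops.values())
    us_share = DEFAULT_REGION_WEIGHTS["US"]
    weights = {f"US-{s}": us_share * p / us_total for s, p in pops.items()}
    rest = {k: v for k, v in DEFAULT_REGION_WEIGHTS.items() if k != "US"}
    weights.update(rest)
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def build_config(seed: int, n_tweets: int = 50_000) -> SyntheticConfig:
    return SyntheticConfig(
        n_tweets=n_tweets,
        n_users=round(n_tweets / 2.45),
        region_weights=state_region_weights(),
        seed=seed,
    )


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-tweets", type=int, default=50_000)
    args = parser.parse_args()

    cfg = build_config(args.seed, args.n_tweets)
    corpus = generate(cfg)
    RESULTS.mkdir(exist_ok=True)
    write_corpus(corpus, RESULTS / "corpus.jsonl")

    s = summarize(corpus)
    print(f"generated {s.n_tweets} tweets from {s.n_users} users "
          f"(mean {s.mean_tweets_per_user:.2f}/user, "
          f"median {s.median_tweets_per_user:.0f}, max {s.max_tweets_per_user})")
    print(f"retweet share {100 * s.retweet_share:.2f}% "
          f"(target {100 * cfg.retweet_prob:.2f}%)")
    print("geo mixture precise/toponym/none: "
          + "/".join(f"{100 * x:.2f}%" for x in s.geo_mixture)
          + f" (target {'/'.join(f'{100 * x:.2f}%' for x in cfg.geo_mixture)})")
    print(f"wrote {RESULTS / 'corpus.jsonl'}")


if __name__ == "__main__":
    main()
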