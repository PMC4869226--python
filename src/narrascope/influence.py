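"""Retweet share, per-original retweet distributions, per-source
statistics, and regional influencer/amplifier scores.

Retweets whose source tweet is outside the corpus (dangling links)
still count toward the retweet share and amplifier scores; they are
excluded from per-original distributions, which require the original
record to attribute the count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import median
from typing import Callable

from ._util import round_half_up, share_pct
from .corpus import Corpus, TweetRecord

RegionFilter = str | Callable[[TweetRecord], bool] | None


def _apply_filter(corpus: Corpus, region_filter: RegionFilter):
    if region_filter is None:
        return list(corpus)
    if callable(region_filter):
        return [r for r in corpus if region_filter(r)]
    return [r for r in corpus if r.country == region_filter]


def retweet_share(corpus: Corpus, region_filter: RegionFilter = None) -> float:
    """Percentage of (optionally region-filtered) tweets that are
    retweets, half-up to 2 decimals.

    ``region_filter`` may be a country code or a record predicate
    (e.g. ``lambda r: r.country not in (None, "US")`` for overseas).
    """
    records = _apply_filter(corpus, region_filter)
    if not records:
        raise ValueError("no records after region filter")
    return share_pct(sum(r.is_retweet for r in records), len(records))


@dataclass(frozen=True)
class RetweetDistribution:
    median: float
    max: int
    histogram: dict[int, int]  # retweet count -> number of originals


def _counts_per_original(corpus: Corpus) -> Counter[str]:
    original_ids = {r.tweet_id for r in corpus if not r.is_retweet}
    return Counter(
        r.source_tweet_id for r in corpus
        if r.is_retweet and r.source_tweet_id in original_ids
    )


def retweet_distribution(
    corpus: Corpus, include_zeros: bool = False
) -> RetweetDistribution:
    """Distribution of in-corpus retweets per original tweet.

    Originals never retweeted enter (with count 0) only when
    ``include_zeros`` is set; otherwise only retweeted originals are
    summarized, matching the per-retweeted-tweet convention.
    """
    counts = _counts_per_original(corpus)
    values = list(counts.values())
    if include_zeros:
        n_orig = sum(not r.is_retweet for r in corpus)
        values += [0] * (n_orig - len(values))
    if not values:
        raise ValueError("no retweeted originals in corpus")
    return RetweetDistribution(
        median=float(median(values)),
        max=max(values),
        histogram=dict(sorted(Counter(values).items())),
    )


def source_stats(corpus: Corpus, author_id: str) -> tuple[float, float]:
    """(mean, median) in-corpus retweets over one author's originals.

    The mean is half-up to 1 decimal; never-retweeted originals count
    as zeros. Raises KeyError if the author has no originals.
    """
    originals = [
        r.tweet_id for r in corpus
        if not r.is_retweet and r.author_id == author_id
    ]
    if not originals:
        raise KeyError(f"author {author_id!r} has no originals in corpus")
    counts = _counts_per_original(corpus)
    per_orig = [counts.get(t, 0) for t in originals]
    mean = round_half_up(sum(per_orig) / len(per_orig), 1)
    return mean, float(median(per_orig))


@dataclass(frozen=True)
class RegionInfluence:
    """Influencer score: retweets received (anywhere) by originals
    authored in the region, per 10,000 residents. Amplifier score:
    fraction of the region's own tweets that are retweets."""

    region: str
    influencer_score: float
    amplifier_score: float

    def __post_init__(self) -> None:
        if self.influencer_score < 0 or not 0 <= self.amplifier_score <= 1:
            raise ValueError("scores out of range")


def region_influence(
    corpus: Corpus,
    populations: dict[str, int],
    level: str = "admin1",
) -> tuple[list[RegionInfluence], list[RegionInfluence]]:
    """Score each region as influencer and amplifier.

    Returns two independently ranked lists (descending influencer
    score; descending amplifier score) over the same records. A region
    is attributed via the original author's tweet geolocation. Raises
    ValueError if a scored region lacks a (positive) population.
    """
    counts = _counts_per_original(corpus)
    region_of_original = {
        r.tweet_id: r.region(level) for r in corpus if not r.is_retweet
    }
    received: Counter[str] = Counter()
    for tid, n in counts.items():
        region = region_of_original.get(tid)
        if region is not None:
            received[region] += n
    authored: Counter[str] = Counter()
    authored_rts: Counter[str] = Counter()
    for r in corpus:
        region = r.region(level)
        if region is None:
            continue
        authored[region] += 1
        if r.is_retweet:
            authored_rts[region] += 1
    regions = sorted(set(received) | set(authored))
    records = []
    for region in regions:
        pop = populations.get(region)
        if not pop or pop <= 0:
            raise ValueError(f"no population for region {region!r}")
        records.append(RegionInfluence(
            region=region,
            influencer_score=10_000 * received[region] / pop,
            amplifier_score=(
                authored_rts[region] / authored[region]
                if authored[region] else 0.0
            ),
        ))
    by_influence = sorted(
        records, key=lambda x: (-x.influencer_score, x.region)
    )
    by_amplification = sorted(
        records, key=lambda x: (-x.amplifier_score, x.region)
    )
    return by_influence, by_amplification
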