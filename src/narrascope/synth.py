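"""Synthetic tweet-corpus generator.

Emulates the statistical structure of a keyword-collected vaccination
corpus so every downstream stage is testable without real data:

* per-user activity follows a truncated discrete power law (a few very
  prolific users, a long tail of one-tweet users);
* a configurable share of tweets are retweets, with targets chosen by
  preferential attachment so per-original retweet counts are heavily
  skewed (median 1, large maximum);
* geolocation is a three-tier mixture (precise coordinates / toponym /
  none) with region attribution drawn from configurable weights;
* hashtags are drawn from planted communities: two tags co-occur in a
  tweet with probability p_in inside a community and p_out across.

Text is assembled as keyword + hashtags + filler tokens — sufficient
for every downstream stage, none of which needs natural language.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta, timezone
from statistics import median

import numpy as np

from .corpus import Corpus, TweetRecord

#: the six keyword variants tracked during collection
DEFAULT_KEYWORDS = frozenset(
    {"vaccination", "vaccine", "vaccines", "vax", "vaxine", "vaxx"}
)

#: planted narrative communities mirroring the four observed hashtag
#: clusters: political, health-oriented, pro-vaccination activism, and
#: the HPV/cancer conversation
DEFAULT_COMMUNITIES: tuple[frozenset[str], ...] = (
    frozenset({"vaccines", "gmo", "bigpharma", "news", "obama", "gop", "tcot"}),
    frozenset(
        {"vaccine", "measles", "cdcwhistleblower", "mmr", "autism", "ebola",
         "b1less", "hearthiswell", "nomandates", "vaccineinjury", "cdcfraud"}
    ),
    frozenset({"polio", "vaccineswork"}),
    frozenset({"hpv", "cancer"}),
)

#: country-level default region weights: the ten highest-contributing
#: countries at their observed shares of geolocated traffic, remainder
#: pooled under the placeholder code ZZ
DEFAULT_REGION_WEIGHTS: dict[str, float] = {
    "US": 0.6018, "CA": 0.0563, "GB": 0.0422, "IN": 0.0260, "AU": 0.0230,
    "ID": 0.0080, "FR": 0.0070, "PK": 0.0069, "DE": 0.0067, "NG": 0.0063,
    "ZZ": 0.2158,
}

_FILLER = ("outbreak", "shots", "kids", "school", "doctor", "debate",
           "parents", "risk", "news", "study")


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated-world parameters of the generator.

    Defaults reproduce the observed corpus structure: retweet share
    44.27%, geolocation mixture 0.94% precise / 52.60% toponym / 46.46%
    none, power-law per-user activity, and four planted hashtag
    communities.
    """

    n_tweets: int = 100_000
    n_users: int = 40_800  # keeps mean tweets/user near the observed 2.45
    activity_exponent: float = 2.2
    retweet_prob: float = 0.4427
    retweet_concentration: float = 1.0
    geo_mixture: tuple[float, float, float] = (0.0094, 0.5260, 0.4646)
    region_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    hashtag_communities: tuple[frozenset[str], ...] = DEFAULT_COMMUNITIES
    p_in: float = 0.3
    p_out: float = 0.02
    p_tagged: float = 0.6  # share of originals carrying any hashtags
    keywords: frozenset[str] = DEFAULT_KEYWORDS
    window: tuple[date, date] = (date(2015, 2, 1), date(2015, 3, 9))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tweets <= 0 or self.n_users <= 0:
            raise ValueError("n_tweets and n_users must be positive")
        if self.n_users > self.n_tweets:
            raise ValueError("n_users exceeds n_tweets with min-one-tweet activity")
        if self.activity_exponent <= 1:
            raise ValueError("activity_exponent must exceed 1")
        if not 0 <= self.retweet_prob <= 1:
            raise ValueError("retweet_prob outside [0, 1]")
        if self.retweet_concentration <= 0:
            raise ValueError("retweet_concentration must be positive")
        if abs(sum(self.geo_mixture) - 1) > 1e-9 or min(self.geo_mixture) < 0:
            raise ValueError("geo_mixture must be probabilities summing to 1")
        wsum = sum(self.region_weights.values())
        if abs(wsum - 1) > 1e-9 or min(self.region_weights.values()) < 0:
            raise ValueError("region_weights must sum to 1")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        tags = [t for c in self.hashtag_communities for t in c]
        if len(tags) != len(set(tags)):
            raise ValueError("hashtag communities must be disjoint")
        if not self.keywords:
            raise ValueError("keywords must be non-empty")


def _split_region(code: str) -> tuple[str, str | None]:
    """Region key 'CC' -> country; 'CC-XX' -> country + admin1 code."""
    if "-" in code:
        country, admin1 = code.split("-", 1)
        return country, admin1
    return code, None


def _user_activity(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-user tweet counts: truncated zeta draw, rescaled so the total
    is exactly n_tweets with every user keeping at least one tweet."""
    counts = rng.zipf(cfg.activity_exponent, size=cfg.n_users)
    counts = np.minimum(counts, cfg.n_tweets).astype(np.int64)
    total = int(counts.sum())
    if total > cfg.n_tweets:
        # shrink proportionally, floor at one tweet each
        scaled = np.maximum(
            1, np.floor(counts * (cfg.n_tweets / total)).astype(np.int64)
        )
        counts = scaled
        total = int(counts.sum())
        # proportional floor can still overshoot when many users sit at 1
        order = np.argsort(-counts)
        i = 0
        while total > cfg.n_tweets:
            u = order[i % len(order)]
            if counts[u] > 1:
                counts[u] -= 1
                total -= 1
            i += 1
    # residual assigned round-robin so totals are exact
    i = 0
    while total < cfg.n_tweets:
        counts[i % cfg.n_users] += 1
        total += 1
        i += 1
    return counts


def generate(cfg: SyntheticConfig) -> Corpus:
    """Generate a corpus; deterministic for a given config seed."""
    rng = np.random.default_rng(cfg.seed)
    counts = _user_activity(cfg, rng)
    authors = np.repeat(np.arange(cfg.n_users), counts)
    rng.shuffle(authors)

    start = datetime.combine(cfg.window[0], datetime.min.time(), timezone.utc)
    span = (cfg.window[1] - cfg.window[0]).days + 1
    offsets = np.sort(rng.integers(0, span * 86_400, size=cfg.n_tweets))

    tiers = rng.choice(3, size=cfg.n_tweets, p=list(cfg.geo_mixture))
    region_codes = list(cfg.region_weights)
    region_idx = rng.choice(
        len(region_codes), size=cfg.n_tweets, p=list(cfg.region_weights.values())
    )
    keyword_list = sorted(cfg.keywords)
    kw_idx = rng.integers(0, len(keyword_list), size=cfg.n_tweets)
    communities = [sorted(c) for c in cfg.hashtag_communities]

    records: list[TweetRecord] = []
    originals: list[int] = []  # indices into records
    # preferential-attachment urn: each past retweet target repeated once
    rt_urn: list[int] = []
    u = rng.random(size=cfg.n_tweets)

    for i in range(cfg.n_tweets):
        ts = start + timedelta(seconds=int(offsets[i]))
        tier = ("precise", "toponym", "none")[tiers[i]]
        country = admin1 = None
        lat = lon = None
        if tier != "none":
            country, admin1 = _split_region(region_codes[region_idx[i]])
            if tier == "precise":
                lat = float(rng.uniform(-60, 70))
                lon = float(rng.uniform(-180, 180))

        as_retweet = originals and u[i] < cfg.retweet_prob
        if as_retweet:
            # P(target) ∝ retweets(target) + concentration
            k = len(originals)
            total_rt = len(rt_urn)
            if rng.random() < cfg.retweet_concentration * k / (
                cfg.retweet_concentration * k + total_rt
            ):
                tgt = originals[int(rng.integers(k))]
            else:
                tgt = rt_urn[int(rng.integers(total_rt))]
            rt_urn.append(tgt)
            src = records[tgt]
            text = f"rt @{src.author_id}: {src.text}"
            rec = TweetRecord(
                tweet_id=f"t{i}",
                author_id=f"u{authors[i]}",
                timestamp=ts,
                text=text,
                is_retweet=True,
                source_tweet_id=src.tweet_id,
                source_author_id=src.author_id,
                geo_tier=tier,
                latitude=lat,
                longitude=lon,
                country=country,
                admin1=admin1,
            )
        else:
            parts = [keyword_list[kw_idx[i]]]
            if communities and rng.random() < cfg.p_tagged:
                ci = int(rng.integers(len(communities)))
                home = communities[ci]
                primary = home[int(rng.integers(len(home)))]
                parts.append(f"#{primary}")
                for cj, comm in enumerate(communities):
                    p = cfg.p_in if cj == ci else cfg.p_out
                    if p <= 0:
                        continue
                    draws = rng.random(len(comm))
                    parts.extend(
                        f"#{t}" for t, d in zip(comm, draws)
                        if t != primary and d < p
                    )
            parts.extend(rng.choice(_FILLER, size=2))
            rec = TweetRecord(
                tweet_id=f"t{i}",
                author_id=f"u{authors[i]}",
                timestamp=ts,
                text=" ".join(parts),
                geo_tier=tier,
                latitude=lat,
                longitude=lon,
                country=country,
                admin1=admin1,
            )
            originals.append(i)
        records.append(rec)

    return Corpus(tuple(records), cfg.window[0], cfg.window[1], cfg.keywords)


@dataclass(frozen=True)
class CorpusSummary:
    """Empirical estimates of the generator parameters."""

    n_tweets: int
    n_users: int
    retweet_share: float
    geo_mixture: tuple[float, float, float]
    mean_tweets_per_user: float
    median_tweets_per_user: float
    max_tweets_per_user: int
    region_freqs: dict[str, float]


def summarize(corpus: Corpus) -> CorpusSummary:
    """Estimate generator parameters back from a corpus."""
    n = len(corpus)
    if n == 0:
        raise ValueError("empty corpus")
    n_rt = sum(r.is_retweet for r in corpus)
    tier_counts = {"precise": 0, "toponym": 0, "none": 0}
    per_user: dict[str, int] = {}
    region_counts: dict[str, int] = {}
    for r in corpus:
        tier_counts[r.geo_tier] += 1
        per_user[r.author_id] = per_user.get(r.author_id, 0) + 1
        if r.geo_tier != "none":
            code = r.country if r.admin1 is None else f"{r.country}-{r.admin1}"
            region_counts[code] = region_counts.get(code, 0) + 1
    n_geo = sum(region_counts.values())
    counts = list(per_user.values())
    return CorpusSummary(
        n_tweets=n,
        n_users=len(per_user),
        retweet_share=n_rt / n,
        geo_mixture=(
            tier_counts["precise"] / n,
            tier_counts["toponym"] / n,
            tier_counts["none"] / n,
        ),
        mean_tweets_per_user=n / len(per_user),
        median_tweets_per_user=float(median(counts)),
        max_tweets_per_user=max(counts),
        region_freqs={
            k: v / n_geo for k, v in sorted(region_counts.items())
        } if n_geo else {},
    )


def binomial_se(p: float, n: int) -> float:
    """Standard error of a binomial proportion estimate."""
    return math.sqrt(p * (1 - p) / n)
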