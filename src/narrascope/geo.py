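"""Regional aggregation and population-normalized participation.

Participation is expressed in two equivalent representations: tweets
per 10,000 residents, and "1 tweet per X persons" (lower X = higher
participation), the convention used for state-level ranking tables.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from ._util import round_half_up
from .corpus import Corpus
from .tokenizer import tokenize

logger = logging.getLogger(__name__)

GEO_LEVELS = ("country", "admin1")


def aggregate_by_region(
    corpus: Corpus,
    level: str = "country",
    geo_tiers: frozenset[str] = frozenset({"precise", "toponym"}),
) -> dict[str, int]:
    """Count geolocated tweets per region at the given level.

    Only records in the allowed geolocation tiers with the level's
    attribute present are counted; everything else is excluded. An
    empty result is allowed.
    """
    if level not in GEO_LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if not geo_tiers <= {"precise", "toponym"}:
        raise ValueError("geo_tiers must be a subset of {precise, toponym}")
    counts: Counter[str] = Counter()
    for r in corpus:
        if r.geo_tier in geo_tiers:
            region = r.region(level)
            if region is not None:
                counts[region] += 1
    return dict(counts)


@dataclass(frozen=True)
class GeoParticipation:
    """Population-normalized participation of one region."""

    region: str
    n_tweets: int
    population: int
    rate_per_10k: float  # 10,000 * n_tweets / population, 2 decimals
    one_in_x: int  # round(population / n_tweets), half-up

    def __post_init__(self) -> None:
        if self.n_tweets >= 1 and self.one_in_x < 1:
            raise ValueError("one_in_x must be >= 1 for a participating region")


def participation(
    counts: dict[str, int], populations: dict[str, int]
) -> list[GeoParticipation]:
    """Normalize per-region counts by population, ranked by increasing
    one_in_x (most participating region first).

    Regions with zero tweets are excluded from the ranking (logged at
    info level); a counted region without a population entry raises a
    ValueError naming it.
    """
    out: list[GeoParticipation] = []
    for region, n in counts.items():
        if region not in populations:
            raise ValueError(f"missing population for region {region!r}")
        if n == 0:
            logger.info("region %s has zero tweets; excluded from ranking",
                        region)
            continue
        pop = populations[region]
        if pop <= 0:
            raise ValueError(f"non-positive population for region {region!r}")
        out.append(GeoParticipation(
            region=region,
            n_tweets=n,
            population=pop,
            rate_per_10k=round_half_up(10_000 * n / pop, 2),
            one_in_x=int(round_half_up(pop / n, 0)),
        ))
    return sorted(out, key=lambda g: (g.one_in_x, g.region))


def topic_participation(
    corpus: Corpus,
    term: str,
    populations: dict[str, int],
    level: str = "admin1",
    geo_tiers: frozenset[str] = frozenset({"precise", "toponym"}),
) -> list[GeoParticipation]:
    """Participation restricted to tweets mentioning a term.

    A bare term matches both its word and hashtag forms; a '#'-prefixed
    term matches the hashtag form only. A term absent from the corpus
    yields an empty ranking.
    """
    if not term:
        raise ValueError("term must be non-empty")
    term = term.lower()
    if term.startswith("#"):
        wanted = {term}
    else:
        wanted = {term, f"#{term}"}
    kept = tuple(
        r for r in corpus if wanted & set(tokenize(r.text))
    )
    if not kept:
        return []
    sub = Corpus(kept, corpus.window_start, corpus.window_end, corpus.keywords)
    return participation(
        aggregate_by_region(sub, level=level, geo_tiers=geo_tiers), populations
    )
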