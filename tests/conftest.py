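"""Shared fixtures: hand-built corpora and small synthetic configs."""

from __future__ import annotations

from datetime import date, datetime, timezone

import pytest

from narrascope.corpus import Corpus, TweetRecord

WINDOW = (date(2015, 2, 1), date(2015, 3, 9))


def make_tweet(
    tweet_id: str,
    text: str,
    author: str = "u0",
    day: int = 1,
    source: str | None = None,
    source_author: str | None = None,
    geo_tier: str = "none",
    country: str | None = None,
    admin1: str | None = None,
    latitude: float | None = None,
    longitude: float | None = None,
) -> TweetRecord:
    return TweetRecord(
        tweet_id=tweet_id,
        author_id=author,
        timestamp=datetime(2015, 2, day, 12, 0, tzinfo=timezone.utc),
        text=text,
        is_retweet=source is not None,
        source_tweet_id=source,
        source_author_id=source_author,
        geo_tier=geo_tier,
        country=country,
        admin1=admin1,
        latitude=latitude,
        longitude=longitude,
    )


def make_corpus(records, keywords=("vaccine",)) -> Corpus:
    return Corpus(tuple(records), *WINDOW, frozenset(keywords))


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Three tweets over two hashtag pairs, one retweet, mixed geo."""
    t1 = make_tweet("t1", "get the measles vaccine now #measles #mmr",
                    author="alice", geo_tier="toponym", country="US",
                    admin1="VT")
    t2 = make_tweet("t2", "vaccine debate #measles #mmr", author="bob",
                    geo_tier="precise", country="US", admin1="OR",
                    latitude=44.0, longitude=-120.5)
    t3 = make_tweet("t3", "rt @alice: get the measles vaccine now #measles #mmr",
                    author="carol", source="t1", source_author="alice",
                    geo_tier="toponym", country="CA")
    return make_corpus([t1, t2, t3])
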