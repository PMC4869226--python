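"""Tweet corpus model and JSON-lines I/O.

A corpus is a validated, windowed collection of tweet records. Records
carry three tiers of geolocation (precise coordinates, toponym-resolved
region, or none), retweet linkage, and hashtags derived directly from
the text so the two can never disagree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .tokenizer import extract_hashtags, match_token_set

logger = logging.getLogger(__name__)

GEO_TIERS = ("precise", "toponym", "none")

_MANDATORY = ("tweet_id", "author_id", "timestamp", "text")


@dataclass(frozen=True, slots=True)
class TweetRecord:
    """One microblog post.

    Invariants enforced at construction:

    * ``is_retweet`` iff ``source_tweet_id`` is present;
    * ``geo_tier='precise'`` implies coordinates in valid ranges;
    * ``geo_tier='none'`` implies no country/region attribution;
    * ``hashtags`` are exactly the '#'-tokens extractable from ``text``.
    """

    tweet_id: str
    author_id: str
    timestamp: datetime
    text: str
    is_retweet: bool = False
    source_tweet_id: str | None = None
    source_author_id: str | None = None
    geo_tier: str = "none"
    latitude: float | None = None
    longitude: float | None = None
    country: str | None = None
    admin1: str | None = None
    hashtags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )
        if self.is_retweet != (self.source_tweet_id is not None):
            raise ValueError("is_retweet must hold iff source_tweet_id is set")
        if self.geo_tier not in GEO_TIERS:
            raise ValueError(f"unknown geo_tier {self.geo_tier!r}")
        if self.geo_tier == "precise":
            if self.latitude is None or self.longitude is None:
                raise ValueError("precise tier requires coordinates")
            if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 180):
                raise ValueError("coordinates out of range")
        else:
            if self.latitude is not None or self.longitude is not None:
                raise ValueError("coordinates only valid for precise tier")
        if self.geo_tier == "none" and (self.country or self.admin1):
            raise ValueError("geo_tier 'none' excludes country/admin1")
        derived = extract_hashtags(self.text)
        if self.hashtags and tuple(self.hashtags) != derived:
            raise ValueError("hashtags field disagrees with text tokens")
        object.__setattr__(self, "hashtags", derived)

    def region(self, level: str) -> str | None:
        if level == "country":
            return self.country
        if level == "admin1":
            return self.admin1
        raise ValueError(f"unknown level {level!r}")


@dataclass(frozen=True)
class Corpus:
    """Sequence of tweet records inside a date window, with unique ids."""

    records: tuple[TweetRecord, ...]
    window_start: date
    window_end: date
    keywords: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "keywords", frozenset(self.keywords))
        ids = [r.tweet_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate tweet_ids in corpus")
        for r in self.records:
            d = r.timestamp.date()
            if not (self.window_start <= d <= self.window_end):
                raise ValueError(
                    f"tweet {r.tweet_id} timestamp {d} outside window"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TweetRecord]:
        return iter(self.records)

    @property
    def n_days(self) -> int:
        """Inclusive window length in days."""
        return (self.window_end - self.window_start).days + 1


def _record_from_json(obj: dict) -> TweetRecord:
    for key in _MANDATORY:
        if key not in obj or obj[key] in (None, ""):
            raise ValueError(f"missing mandatory field {key!r}")
    ts = datetime.fromisoformat(str(obj["timestamp"]))
    source = obj.get("source_tweet_id") or None
    text = str(obj["text"])
    # metadata linkage wins; absent any retweet metadata, a leading
    # "RT @" marks a retweet with an unresolvable (dangling) source
    if source is None:
        flagged = obj.get("is_retweet")
        if flagged or (flagged is None and text.lower().startswith("rt @")):
            source = f"unknown:{obj['tweet_id']}"
    is_rt = source is not None
    return TweetRecord(
        tweet_id=str(obj["tweet_id"]),
        author_id=str(obj["author_id"]),
        timestamp=ts,
        text=text,
        is_retweet=is_rt,
        source_tweet_id=source,
        source_author_id=obj.get("source_author_id") or None,
        geo_tier=obj.get("geo_tier", "none"),
        latitude=obj.get("latitude"),
        longitude=obj.get("longitude"),
        country=obj.get("country") or None,
        admin1=obj.get("admin1") or None,
    )


def read_corpus(
    path: str | Path,
    window: tuple[date, date],
    keywords: Iterable[str] = (),
) -> Corpus:
    """Read a JSON-lines tweet file into a validated :class:`Corpus`.

    Malformed lines (missing mandatory fields, unparseable timestamps,
    invariant violations) are rejected and counted; timestamps outside
    the window are dropped silently at info level. The number of
    rejections is logged and available as ``read_corpus.last_report``.
    """
    start, end = window
    records: list[TweetRecord] = []
    n_rejected = 0
    n_out_of_window = 0
    reasons: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = _record_from_json(json.loads(line))
            except (ValueError, KeyError, TypeError) as exc:
                n_rejected += 1
                reasons.append(f"line {lineno}: {exc}")
                continue
            if not (start <= rec.timestamp.date() <= end):
                n_out_of_window += 1
                continue
            records.append(rec)
    if n_rejected:
        logger.warning("rejected %d malformed lines: %s", n_rejected, reasons[:5])
    if n_out_of_window:
        logger.info("dropped %d records outside window", n_out_of_window)
    read_corpus.last_report = {  # type: ignore[attr-defined]
        "n_read": len(records),
        "n_rejected": n_rejected,
        "n_out_of_window": n_out_of_window,
        "reasons": reasons,
    }
    return Corpus(tuple(records), start, end, frozenset(keywords))


def _record_to_json(rec: TweetRecord) -> dict:
    obj: dict = {}
    for f in fields(rec):
        val = getattr(rec, f.name)
        if f.name == "timestamp":
            val = val.isoformat()
        elif f.name == "hashtags":
            val = list(val)
        if val is None:
            continue
        obj[f.name] = val
    return obj


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as JSON-lines; ``read_corpus`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus:
            fh.write(json.dumps(_record_to_json(rec), ensure_ascii=False) + "\n")


def filter_by_keywords(corpus: Corpus, keywords: Iterable[str]) -> Corpus:
    """Retain records whose token set intersects ``keywords``.

    Matching is case-insensitive exact token match with hashtag sigils
    stripped ('#vaccine' matches 'vaccine'; 'vaxxed' does not match
    'vaxx'). Raises ValueError on an empty keyword set.
    """
    kws = frozenset(k.lower() for k in keywords)
    if not kws:
        raise ValueError("keyword set must be non-empty")
    kept = tuple(r for r in corpus if match_token_set(r.text) & kws)
    return replace(corpus, records=kept, keywords=kws)


def write_table(
    rows: Sequence[dict] | pd.DataFrame, path: str | Path, format: str = "csv"
) -> None:
    """Write tabular stage output as UTF-8 CSV/TSV with stable columns."""
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="," if format == "csv" else "\t", index=False,
              encoding="utf-8")


def load_populations(path: str | Path) -> dict[str, int]:
    """Read a region population table (columns region_code, population)."""
    df = pd.read_csv(path, dtype={"region_code": str})
    if not {"region_code", "population"} <= set(df.columns):
        raise ValueError("population table needs region_code, population columns")
    return dict(zip(df["region_code"], df["population"].astype(int)))
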