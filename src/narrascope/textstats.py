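"""Term frequency and corpus-characteristic statistics.

Terms are counted at tweet level (presence, not token multiplicity):
"mentions" of a term is the number of tweets containing it at least
once. Hashtag forms are distinct terms from bare words — ``#measles``
and ``measles`` are counted separately unless a merge is requested
explicitly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from statistics import median

from ._util import round_half_up, share_pct
from .corpus import Corpus
from .tokenizer import URL_TOKEN, tokenize

__all__ = [
    "StopWordPolicy", "TermStats", "tokenize", "term_frequencies",
    "share_pct", "per_user_stats", "daily_rate", "DEFAULT_STOP_WORDS",
    "DEFAULT_COMMON_WORDS",
]

# articles, prepositions, pronouns, auxiliaries and common verbs — the
# categories excluded from dominant-term counting; configurable
DEFAULT_STOP_WORDS = frozenset("""
a an the and or but if then than that this these those there here
i you he she it we they me him her us them my your his its our their
of in on at by for with from to into over under about after before
between through during above below up down out off again further
is are was were be been being am do does did doing have has had having
will would shall should can could may might must not no nor only own
same so too very s t don won just rt via amp as
""".split())

#: frequent topic-neutral words excluded from the dominant-term table
DEFAULT_COMMON_WORDS = frozenset({"new", "now", "people", "against"})


@dataclass(frozen=True)
class StopWordPolicy:
    """Which terms are excluded from frequency tables.

    ``excluded_terms`` is meant for the search keywords themselves
    (they appear in every tweet by construction); both bare and hashtag
    forms of an excluded term are removed.
    """

    stop_words: frozenset[str] = DEFAULT_STOP_WORDS
    common_words: frozenset[str] = DEFAULT_COMMON_WORDS
    excluded_terms: frozenset[str] = frozenset()

    def excludes(self, token: str) -> bool:
        bare = token.lstrip("#")
        return (
            token in self.stop_words
            or token in self.common_words
            or token in self.excluded_terms
            or bare in self.excluded_terms
        )


EMPTY_POLICY = StopWordPolicy(frozenset(), frozenset(), frozenset())


@dataclass(frozen=True)
class TermStats:
    term: str
    mentions: int
    share_pct: float


def _tweet_terms(text: str) -> set[str]:
    """Distinct countable terms of one tweet: words and '#'-form
    hashtags; URLs and @-mentions are not terms."""
    return {
        tok for tok in tokenize(text)
        if tok != URL_TOKEN and not tok.startswith("@")
    }


def term_frequencies(
    corpus: Corpus,
    policy: StopWordPolicy = EMPTY_POLICY,
    top_n: int | None = None,
    merged: dict[str, frozenset[str]] | None = None,
) -> list[TermStats]:
    """Ranked tweet-level term frequencies.

    Each term is counted once per tweet containing it; excluded terms
    are removed; ties in mentions break lexicographically. ``merged``
    maps a display label to a set of term forms counted jointly (a
    tweet containing any form counts once); the component forms are
    then dropped from individual listing.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    n = len(corpus)
    if n == 0:
        return []
    counts: Counter[str] = Counter()
    merged = merged or {}
    merge_members = {t for forms in merged.values() for t in forms}
    merge_counts: Counter[str] = Counter()
    for rec in corpus:
        terms = _tweet_terms(rec.text)
        for t in terms:
            if not policy.excludes(t) and t not in merge_members:
                counts[t] += 1
        for label, forms in merged.items():
            if terms & forms:
                merge_counts[label] += 1
    counts.update(merge_counts)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ranked = ranked[:top_n]
    return [TermStats(t, c, share_pct(c, n)) for t, c in ranked]


@dataclass(frozen=True)
class PerUserStats:
    n_users: int
    mean_tweets_per_user: float  # half-up, 2 decimals
    median_tweets_per_user: float
    top_counts: tuple[int, ...] = field(default=())


def per_user_stats(corpus: Corpus, top_k: int = 10) -> PerUserStats:
    """Participation summary: distinct users, mean/median tweets per
    user, and the top-k most prolific users' tweet counts."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    per_user: Counter[str] = Counter(r.author_id for r in corpus)
    counts = sorted(per_user.values(), reverse=True)
    return PerUserStats(
        n_users=len(per_user),
        mean_tweets_per_user=round_half_up(len(corpus) / len(per_user), 2),
        median_tweets_per_user=float(median(counts)),
        top_counts=tuple(counts[:top_k]),
    )


def daily_rate(count: int, n_days: int) -> int:
    """Whole tweets per day over an inclusive window: floor(count/n_days)."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count // n_days
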