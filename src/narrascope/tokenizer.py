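"""Tweet tokenization.

The tokenizer is deliberately simple and deterministic: lowercase
everything, keep ``#hashtag`` and ``@mention`` sigils attached so the
hashtag form of a word stays distinct from the bare word, collapse URLs
to a single typed token, and strip punctuation from token edges. No
stemming or language detection — variant spellings are distinct terms.
"""

from __future__ import annotations

URL_TOKEN = "<url>"

_URL_PREFIXES = ("http://", "https://", "www.")


def _clean_chunk(chunk: str) -> str | None:
    # peel leading punctuation but keep a single # or @ sigil
    i = 0
    n = len(chunk)
    while i < n and not (chunk[i].isalnum() or chunk[i] in "#@_"):
        i += 1
    chunk = chunk[i:]
    prefix = ""
    if chunk[:1] in ("#", "@"):
        prefix, chunk = chunk[0], chunk[1:]
    j = len(chunk)
    while j > 0 and not (chunk[j - 1].isalnum() or chunk[j - 1] == "_"):
        j -= 1
    chunk = chunk[:j]
    if not chunk:
        return None
    return prefix + chunk


def tokenize(text: str) -> list[str]:
    """Split tweet text into an ordered list of lowercase tokens.

    ``#tag`` is one token distinct from ``tag``; ``@user`` keeps its
    sigil; any URL becomes the single token ``<url>``; punctuation is
    stripped from word edges (internal apostrophes/hyphens survive).
    Empty text yields an empty list.
    """
    tokens: list[str] = []
    for chunk in text.lower().split():
        if chunk.startswith(_URL_PREFIXES):
            tokens.append(URL_TOKEN)
            continue
        tok = _clean_chunk(chunk)
        if tok is not None:
            tokens.append(tok)
    return tokens


def extract_hashtags(text: str) -> tuple[str, ...]:
    """Ordered de-duplicated lowercase hashtags (without '#') in text."""
    seen: dict[str, None] = {}
    for tok in tokenize(text):
        if tok.startswith("#") and len(tok) > 1:
            seen.setdefault(tok[1:], None)
    return tuple(seen)


def match_token_set(text: str) -> set[str]:
    """Token set used for keyword matching: sigils stripped, URLs dropped.

    '#vaccine' matches the keyword 'vaccine'; 'vaxxed' does not match
    'vaxx' (exact token match, not substring).
    """
    out: set[str] = set()
    for tok in tokenize(text):
        if tok == URL_TOKEN:
            continue
        out.add(tok.lstrip("#@"))
    return out
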