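# Methods

## Corpus model

A tweet record carries: text, author, UTC timestamp, retweet linkage,
and one of three geolocation tiers — `precise` (GPS coordinates),
`toponym` (a named place resolved to country and, for the US, state),
or `none`. Hashtags are always derived from the text by the package's
tokenizer, so the stored tag set can never disagree with the text. A
corpus is windowed (default collection window: 2015-02-01 through
2015-03-09, 37 days inclusive) and keyword-filtered.

Keyword matching is case-insensitive **exact token** matching, not
substring matching: `vaxxed` does not match the keyword `vaxx`. The
hashtag sigil is stripped for matching, so `#vaccine` matches the
keyword `vaccine`. Substring matching would change corpus composition
in ways that cannot be validated, so it is not offered.

Retweet identification: explicit source-tweet metadata wins; absent
metadata, a leading `RT @` marks a retweet whose source is unresolvable.
Such *dangling* retweets keep the record-level invariant (retweet ⇔
source id present) via a sentinel source id; they count toward retweet
shares and amplifier scores but cannot enter per-original retweet
distributions, which need the original record for attribution.

## Tokenization and term statistics

The tokenizer lowercases, keeps `#tag` and `@mention` sigils attached
(so the hashtag form of a word is a distinct term from the bare word),
collapses URLs to one typed token, and strips punctuation from token
edges. No stemming, lemmatization or language detection — variant
spellings are deliberately distinct terms.

Term frequencies are **tweet-level presence counts**: a term mentioned
three times in one tweet counts once. The stop-word policy removes a
standard English list of articles/prepositions/pronouns/auxiliaries
(configurable; the categories are standard but no canonical list
exists, so the default is ours), a small set of frequent topic-neutral
words (`new`, `now`, `people`, `against`), and the search keywords
themselves, whose presence in every tweet is an artifact of
collection. Explicitly requested term pairs (e.g. a word and its
hashtag form) can be merged into one jointly counted row; no merging
happens implicitly.

All reported percentages use round-half-up (via `decimal`), which is
what printed corpus-characteristic tables in this literature follow;
banker's rounding would differ on exact ties. Daily rates over the
inclusive window use floor division. "1 tweet per X persons" uses
half-up rounding of population/count.

## Co-occurrence network and Louvain

Nodes are hashtags with tweet-level frequencies; an edge's weight is
the number of tweets containing both endpoint tags (once per tweet,
regardless of repetition). Nodes below a frequency threshold (default
2, to suppress singleton tags) are pruned with their edges. Reported
strengths are weights normalized by the maximum weight; Louvain runs
on the **raw counts** — scaling all weights by a constant leaves
modularity unchanged, which the tests verify indirectly through the
rank-preservation property.

Louvain is implemented in full (two phases: greedy local moves
maximizing modularity gain, then community aggregation with
self-loops, iterated until no gain). Determinism and quality choices:

* node visit order is shuffled by a caller-supplied seed; equal-gain
  moves resolve to the lowest community id, so runs reproduce exactly;
* greedy Louvain is order-dependent and can stall in local optima on
  small graphs (single-run quality can drop to ~80% of the enumerated
  optimum on 8-node weighted graphs — the reference networkx
  implementation shows the same behaviour). The implementation
  therefore runs `n_restarts = 8` restarts with derived seeds and
  keeps the best-modularity partition. On a benchmark of 50 random
  graphs of ≤ 8 nodes this reaches the exhaustive-enumeration optimum
  on every graph; cost is negligible at hashtag-graph scale
  (tens of nodes);
* the resolution parameter defaults to 1.0 (classic modularity) and is
  exposed for exploration only;
* the per-level modularity trajectory is recorded and asserted
  non-decreasing; the result never falls below the singleton baseline.

Hashtags are compared case-insensitively (platform semantics).

## Retweet influence

`retweet_share` is the retweet percentage of an optionally
region-filtered corpus. Influencer and amplifier scores needed
explicit formulas (the concepts are usually described qualitatively):

* **influencer score** of region r = total in-corpus retweets received
  by originals authored in r, per 10,000 residents of r (population
  normalization mirrors the participation metric, making regions
  comparable);
* **amplifier score** of region r = fraction of tweets authored in r
  that are retweets (in [0, 1]).

Attribution uses the original author's tweet geolocation. Self-retweets
are not special-cased.

## Geographic participation

Geolocated tweets (both tiers by default; selectable) aggregate per
country or state. Participation per region is reported both as tweets
per 10,000 residents (2 decimals) and as "1 tweet per X persons"
(half-up integer); ranking ascending by X equals ranking descending by
rate, ties aside. Topic participation restricts the corpus to tweets
containing a term first — a bare term matches word and hashtag forms,
a `#`-prefixed term matches the hashtag form only. Populations are a
user-supplied CSV; the bundled `us_state_populations_2014_synthetic.csv`
is a hand-assembled stand-in with 2014-style state estimates, intended
for examples and tests, not for real analyses.

## Synthetic corpus generator

The generator emulates the statistical structure real keyword-collected
vaccination corpora exhibit, with defaults fixed at the stated world:

| parameter | default | meaning |
|---|---|---|
| `retweet_prob` | 0.4427 | expected retweet share |
| `geo_mixture` | (0.0094, 0.5260, 0.4646) | precise/toponym/none tiers |
| `activity_exponent` | 2.2 | zeta exponent of per-user tweet counts |
| `retweet_concentration` | 1.0 | preferential-attachment smoothing |
| `region_weights` | top-10 country shares + pooled rest | region attribution |
| `hashtag_communities` | 4 planted narrative clusters | political / health / pro-vaccination activism / HPV-cancer |
| `p_in`, `p_out` | 0.3, 0.02 | within/cross-community co-tagging |
| `n_tweets`, `n_users` | 100,000, 40,800 | keeps mean ≈ 2.45 tweets/user |

Mechanics: per-user activity is a zeta draw truncated and rescaled so
totals are exact (residual assigned round-robin, minimum one tweet per
user); tweets are generated in timestamp order; each tweet is a
retweet with probability `retweet_prob`, its target drawn with
probability proportional to (current retweet count +
`retweet_concentration`) over earlier originals — an urn scheme that
produces the observed "median 1, very large maximum" skew with one
knob. Originals carry one keyword token, optionally hashtags (primary
tag from a uniformly chosen community, others included with `p_in` /
`p_out`), and two filler words. `activity_exponent = 2.2` and the
`p_in`/`p_out` defaults are our choices of realistic values (social
media activity exponents are typically reported near 2–2.5); nothing
downstream is sensitive to them except community separability, which
the planted-recovery tests pin at the extreme `p_out = 0`.

What the generator does **not** emulate — so a green test does not
establish it: natural language (texts are token bags), temporal bursts
(timestamps are uniform in the window), bot behaviour, follower
structure, or a joint per-user mean of 2.45 with median 5 — those two
published summary statistics are mutually inconsistent for any single
count distribution with support ≥ 1, and the generator reproduces the
mean-level totals and power-law shape instead (its per-user median
is 1).

## Degenerate inputs and errors

Empty keyword sets, empty corpora for summary statistics, edgeless
graphs for strength normalization/modularity/Louvain, absent anchors,
zero or missing populations, and zero-length windows all raise typed
errors naming the problem; zero-tweet regions are excluded from
participation rankings rather than erroring. Malformed corpus lines
are rejected and counted, never silently dropped; out-of-window
records are dropped at info level by design.

## Known limitations

* Toponym→region resolution is assumed present in the input; the
  package does no geocoding and renders no maps or word clouds (it
  produces the numeric tables behind them).
* Reference-corpus-dependent results (which hashtags cluster together,
  state rankings, specific strength values) depend on the undeposited
  source data and are validated structurally, not numerically.
* Sentiment, demographics and follower-graph analyses are out of
  scope; influence is measured through retweets only.
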