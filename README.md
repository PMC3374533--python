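# healthtrust

Link-analysis trust scoring, search and evaluation for online health
communities.

## The problem

Health information on social platforms is uneven: alongside content from
health agencies and experienced patients sits advertising, spam and
outright misleading advice ("herbal cures"). Professional review does not
scale, but the community's own endorsement behavior carries signal —
members endorse trustworthy channels and content far more than misleading
ones. This package scores that signal. It is aimed at researchers in
consumer health informatics and at anyone building topic-community search
over user-generated content who wants a spam-resistant, community-internal
notion of trust rather than global popularity.

## The model

A community snapshot is a heterogeneous directed graph: **users**
(channels) own **content** items (e.g. videos), and two kinds of
endorsement link connect them — *subscriptions* (user → user) and
*favorites* (user → content). Two derived graphs are scored with the HITS
hubs-and-authorities algorithm:

* **user graph** — nodes are channels; an edge X→Y for every subscription
  X→Y and for every favorite by X of content authored by Y;
* **content graph** — nodes are channels and items; favorites give edges
  user → item, and a subscription X→Y expands to edges from X to every
  item authored by Y (so channels act as pure hubs).

HITS authority scores, min-max normalized to [0, 1] separately for users
(`a_u`) and content (`a_c`), are combined per item `c` with author `u`:

```
HealthTrust(c) = IF · a_u(u) + (1 − IF) · a_c(c),      IF ∈ [0, 1]
```

The **inheritance factor** `IF` (default 0.7) is the weight of the
author's standing: new, not-yet-endorsed content from a trusted channel
inherits most of that channel's trust. At `IF = 0` items stand only on
their own endorsements; at the channel level the trust score is simply
`a_u`. Search relevance is `match_weight · HealthTrust(c)`, where a query
occurring in the title weighs 1.0 and in the description only 0.2; tags
are never matched (too noisy). Rankings are evaluated with precision@K,
DCG (undiscounted first position, log₂ discount), Pearson correlation
(reported with df = n − 2) and Cohen's κ for inter-rater agreement.

Because authority is computed inside an extracted topic community (see
`extract_community`), the metric deliberately *strengthens* the
tightly-knit-community effect that general-purpose search engines
suppress: intra-community authority, not platform-wide popularity.

## Worked example

Generate a planted synthetic community (10 densely inter-endorsing core
channels, 30 weakly connected peripheral channels, 10 spam channels, 5
videos each), score it, and search it:

```sh
healthtrust simulate --seed 42 --out community.json \
    --truth truth.tsv --judgments judgments.tsv
healthtrust score --graph community.json --out-dir scores
```

`score` prints the fit summary:

```
HealthTrust model fit
========================================================
users: 50   content: 250   links: 869
inheritance_factor: 0.7
content graph mode: expansion
user HITS: converged in 9 iteration(s)
content HITS: converged in 10 iteration(s)
--------------------------------------------------------
top channels by trust:
  core_000                       1.0000
  core_009                       0.9984
  core_004                       0.9789
  ...
```

Every top channel is core-planted: the dense endorsement core accumulates
all the authority, while spam channels (whose sparse clique endorses only
itself) stay near 0. Searching combines this with text match:

```sh
healthtrust search --graph community.json --query "diabetic foot" --top-k 5
```

```
rank  content_id    title                           relevance       healthtrust     match_kind
1     core_001_v00  Managing diabetic foot: part 0  0.982732414381  0.982732414381  title
2     core_004_v04  Managing diabetic foot: part 4  0.945036583186  0.945036583186  title
3     core_009_v00  Managing diabetic foot: part 0  0.933249375464  0.933249375464  title
...
```

Title matches earn relevance equal to the full trust score; a
description-only match would earn 0.2× of it. Evaluating a top-10 ranking
against the synthetic two-reviewer judgments
(`healthtrust eval --ranking ranking.tsv --judgments judgments.tsv --ks 5,10 --dcg-cutoffs 5,10`)
gives, for example:

```
metric          mode            cutoff  value
precision_at_k  both_reviewers  10      0.8
precision_at_k  at_least_one    10      0.9
dcg             at_least_one    10      4.95346451611
bad_item_rate   none_recommend  10      0.1
```

i.e. 9 of the top 10 results are recommended by at least one reviewer and
only one is recommended by neither. The same operations are available as
a library (`HealthTrustModel(graph, TrustParameters()).fit()` returns a
results object with `content_scores`, `channel_scores`, `summary()` and
`search()`), plus `extract` for keyword subcommunity extraction and
GraphML/TSV/JSON serialization.

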