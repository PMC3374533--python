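# Methods

## Model and assumptions

The package treats an online health community as a heterogeneous directed
graph of users (channels) and content items joined by two endorsement
link types, subscriptions (user → user) and favorites (user → content).
The operating assumption is that community endorsement tracks content
quality: misleading producers find it hard to attract endorsements from a
topic community, so link-derived authority is a usable trust proxy. Trust
is *community-internal* — scoring is meant to run on a topic subgraph
(e.g. everything mentioning "diabetes"), not on the whole platform, so
the tightly-knit-community effect is a feature here, not a bias to
suppress.

Endorsement is modeled as binary: parallel links collapse to one, and
self-endorsements (self-subscriptions, favoriting one's own content) are
removed at validation because an endorsement of oneself carries no
community information and would trivially game the score. Friendship and
comment links are accepted in input files but ignored by scoring.
User and content ids must not collide; a collision is a validation error
rather than a silent rename, so score tables always carry the caller's
ids.

## Authority computation

HITS runs on two graphs. In the user graph, favorites are projected onto
the favorited item's author, so both link types become channel-level
endorsements. In the content graph (default `expansion` mode) a
subscription X→Y becomes edges from X to each of Y's items — channels are
pure hubs, items pure authorities. The subscription wording admits a
second reading in which the subscription stays a single user→user edge
inside the mixed graph; this is implemented as `content_graph_mode
="user-edge"` and changes nothing else in the pipeline. Expansion is the
default because it keeps the mixed graph bipartite and lets an item
inherit visibility from its channel's subscribers even before anyone
favorites it.

The iteration is the standard mutual reinforcement — authority(v) ← Σ
hub(u) over in-neighbors, hub(u) ← Σ authority(v) over out-neighbors —
with both vectors renormalized to unit Euclidean length each iteration,
uniform initialization, and termination when the maximum absolute
per-node change of either vector drops below `tolerance` (default 1e-10,
`max_iterations` 1000; non-convergence is reported via a flag, never an
exception). Per-iteration normalization only fixes the scale, and min-max
rescaling afterwards is scale-invariant, so any other normalization
convention would give identical final scores. Nodes with no in-edges get
authority exactly 0 — no smoothing prior is applied. All node orderings
are sorted by id and the linear algebra is deterministic, so identical
inputs give bit-identical scores.

Raw authority is min-max normalized to [0, 1], separately over users and
over content items (user nodes of the mixed graph are discarded before
normalizing content), so the two families occupy comparable ranges before
being combined. A degenerate range (all raw scores equal, e.g. a
link-free community) maps to all zeros: without endorsements there is no
link-based trust.

## Trust combination

`HealthTrust(c) = IF · a_u(author) + (1 − IF) · a_c(c)` with the
inheritance factor `IF` a single global constant, default 0.7 (author
70%, item 30%). The default reflects the common situation of new,
high-quality items that nobody has linked to yet: a lower `IF` would bury
them despite a trusted source. It is exposed as a parameter everywhere
(library, CLI, config file). A documented consequence is the tie
behavior: items with identical (including empty) endorsement profiles by
the same author receive exactly equal scores — at the top of a ranking
this surfaces whole channels at once.

Channel-level trust is defined as normalized user authority itself; there
is no separate channel formula.

## Search and evaluation

Relevance is `match_weight × HealthTrust`: 1.0 for a query occurring in
the title, 0.2 for description-only, 0 otherwise — title metadata is far
more reliable than descriptions or tags, and tags are excluded outright
because of tag spamming. Matching is case-folded substring containment of
the whole query; a token-AND mode exists behind a flag. Zero-relevance
items are excluded (an unmatched item is not a result), ties break by
ascending content id, output is truncated to `top_k`.

Evaluation metrics follow their textbook forms. Precision@K counts
relevance under three modes: both reviewers recommend, at least one
recommends, or mean rating ≥ threshold (default 3.5 on the 1–5 scale,
inclusive). DCG uses the classic binary formulation with position 1
undiscounted and a log₂ discount; the log base is a parameter because the
variant choice cannot be pinned down externally, and no normalized (nDCG)
variant is provided. Pearson r and its two-sided p come from the t
statistic with df = n − 2 (scipy), matching the subscript convention in
which r₁₀ denotes 12 pairs; Cohen's κ is delegated to scikit-learn behind
a surface that raises explicitly when both raters are constant and
identical (chance agreement 1, κ undefined). The bad-item rate (fraction
of top-K recommended by nobody) satisfies
`bad_item_rate = 1 − precision@K(at_least_one)` exactly, and report
formatters may truncate percentages toward zero for display, never in
computation.

## Synthetic communities

The generator plants the structure the scoring is designed to detect:
a trusted **core** (default 10 channels) that subscribes to itself
pairwise with probability 0.8 and whose videos are favorited by core and
peripheral channels with probability 0.3; **peripheral** channels
(default 30) that endorse the core but receive almost nothing; and
**spam** channels (default 10) forming their own sparse clique
(subscription probability 0.3) and otherwise receiving only background
links. A universal background layer adds any→any subscriptions and
favorites at probability 0.01. Each channel owns 5 videos; titles and
descriptions carry topic terms with probability 0.8 each (the same
parameter governs both fields). Spam channels do not endorse core
content: their defining behavior is mutual promotion.

Every random decision is drawn from a substream seeded by a stable hash
of the entities involved (pair-keyed for links, node-keyed for metadata),
so a fixed seed reproduces the community exactly and adding channels does
not perturb existing entities' draws.

Synthetic reviewer judgments anchor mean ratings at 4.2 (core), 3.2
(peripheral) and 1.8 (spam) on the 1–5 scale with Gaussian noise
(default SD 0.5), clipped to [1, 5]; per-reviewer ratings add independent
noise of the same scale around the item mean, and a rating ≥ 3.5 is a
recommendation. The anchors are generator conventions chosen to separate
the classes by roughly the plausible gap between solid and misleading
health content while leaving reviewer disagreement realistic (κ ≈ 0.6 at
the default noise).

What the generator does *not* emulate: heavy-tailed degree
distributions, channel-size heterogeneity, temporal dynamics, textual
variety beyond templated titles, or adversarial spam that mimics core
linking patterns. Passing the planted-recovery checks therefore shows the
metric separates densely endorsed cores from poorly endorsed producers
under clean conditions; it does not certify performance against adaptive
spam or real platform data.

## Numerical and design choices

* Tolerances: HITS 1e-10 on the max per-node change; trust combination is
  exact arithmetic on normalized scores.
* Determinism: sorted node order everywhere, fixed float formatting
  (`%.12g`) in TSV output, manifests without timestamps — CLI reruns are
  byte-identical for identical inputs.
* Degenerate inputs: empty graphs yield empty score maps; link-free
  communities yield all-zero trust and exit cleanly; `k` or cutoffs
  beyond the list length are argument errors.
* Problem sizes in the verification scripts — 100 random graphs of ≤ 50
  nodes for the eigendecomposition cross-check, 20 generator seeds for
  planted recovery — are the package's chosen defaults; the independent
  oracle computes the closed-form limit of the iteration (projection of
  the starting authority vector Aᵀ·1 onto the dominant eigenspace of
  AᵀA), which remains well-defined when the dominant eigenvalue is
  degenerate.

## Known limitations

Authority-based trust inherits HITS's weaknesses: channels that avoid
social features rank low regardless of quality, and scores are relative
to the extracted community, so community extraction quality bounds
scoring quality. The keyword extractor is a case-folded substring match
with no language handling or stemming. PageRank-style alternatives and
multi-community trust are extension points, not implemented. No live
platform harvesting is included; inputs are files or the generator.
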