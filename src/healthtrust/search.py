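"""Trust-weighted retrieval: rank content for a query.

Relevance combines a syntactic match against the item's metadata with the
item's trust score: a query occurring in the title earns the full trust
score, a query occurring only in the description earns 20% of it, and an
item matching nowhere is not a result. Tags are deliberately not matched —
tag fields on sharing platforms are too noisy (tag spamming) to signal
relevance.

Matching defaults to case-folded substring containment of the whole query;
``token_and=True`` instead requires every whitespace token of the query to
occur in the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .community import CommunityGraph
from .model import HealthTrustModel, HealthTrustResults, TrustParameters


@dataclass(frozen=True)
class RankedResult:
    """One search hit: 1-based rank, relevance and its ingredients."""

    content_id: str
    relevance: float
    rank: int
    healthtrust: float = 0.0
    match_kind: str = ""  # "title" or "description"
    title: str = ""


def _matches(query: str, text: str, token_and: bool) -> bool:
    q, t = query.casefold(), text.casefold()
    if token_and:
        return all(tok in t for tok in q.split())
    return q in t


def match_weight(
    query: str,
    title: str,
    description: str,
    params: TrustParameters | None = None,
    *,
    token_and: bool = False,
) -> float:
    """Match weight for one item: title hit -> 1.0, description-only -> 0.2, none -> 0."""
    if not query or not query.strip():
        raise ValueError("query must be non-empty")
    params = params or TrustParameters()
    if _matches(query, title, token_and):
        return params.title_match_weight
    if _matches(query, description, token_and):
        return params.description_match_weight
    return 0.0


def search_results(
    results: HealthTrustResults,
    query: str,
    top_k: int = 10,
    *,
    token_and: bool = False,
    author_allowlist: Sequence[str] | None = None,
) -> list[RankedResult]:
    """Rank content of a fitted model: relevance = match weight x trust score.

    Zero-relevance items are excluded; ties break by ascending content id;
    the list is truncated to ``top_k``. ``author_allowlist`` optionally
    restricts results to items by the given authors.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not query or not query.strip():
        raise ValueError("query must be non-empty")
    params = results.model.params
    graph = results.model.graph
    allow = set(author_allowlist) if author_allowlist is not None else None

    hits: list[tuple[float, str, str]] = []  # (relevance, content_id, match_kind)
    for cid, item in graph.content.items():
        if allow is not None and item.author_id not in allow:
            continue
        if _matches(query, item.title, token_and):
            weight, kind = params.title_match_weight, "title"
        elif _matches(query, item.description, token_and):
            weight, kind = params.description_match_weight, "description"
        else:
            continue
        relevance = weight * results.content_scores[cid]
        if relevance > 0:
            hits.append((relevance, cid, kind))

    hits.sort(key=lambda t: (-t[0], t[1]))
    return [
        RankedResult(
            content_id=cid,
            relevance=rel,
            rank=i,
            healthtrust=results.content_scores[cid],
            match_kind=kind,
            title=graph.content[cid].title,
        )
        for i, (rel, cid, kind) in enumerate(hits[:top_k], start=1)
    ]


def search(
    g: CommunityGraph,
    query: str,
    params: TrustParameters | None = None,
    top_k: int = 10,
    *,
    token_and: bool = False,
    author_allowlist: Sequence[str] | None = None,
) -> list[RankedResult]:
    """Fit the trust model on ``g`` and rank its content for ``query``."""
    results = HealthTrustModel(g, params).fit()
    return search_results(
        results, query, top_k, token_and=token_and, author_allowlist=author_allowlist
    )
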