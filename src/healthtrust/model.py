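"""The trust score: inheritance-weighted combination of link authority.

The trust score of a content item blends two normalized HITS authority
scores — the item's own and its author's:

    trust(c) = IF * userAuth(author(c)) + (1 - IF) * contentAuth(c)

where the inheritance factor IF in [0, 1] (default 0.7) is the weight on
the author. A high IF lets new, not-yet-endorsed content from a trusted
channel inherit most of that channel's standing; IF = 0 scores content
purely on its own endorsements. At the channel level the trust score *is*
the channel's normalized authority.

The module is organized around a model/results pair: build a
:class:`HealthTrustModel` from a community graph, call :meth:`fit` to run
the HITS iterations on both endorsement graphs, and read scores,
convergence diagnostics and ``summary()`` off the returned
:class:`HealthTrustResults`. ``healthtrust_content`` and
``healthtrust_channel`` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import authority
from .authority import AuthorityScores, ContentGraphMode
from .community import CommunityGraph


@dataclass(frozen=True)
class TrustParameters:
    """Tunable constants of the metric.

    inheritance_factor: weight of the author's authority in a content
        item's score (0.7 by default: author 70%, item 30%).
    title_match_weight / description_match_weight: fraction of the trust
        score awarded as search relevance for a title match (1.0) versus a
        description-only match (0.2).
    """

    inheritance_factor: float = 0.7
    title_match_weight: float = 1.0
    description_match_weight: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.inheritance_factor <= 1.0:
            raise ValueError(f"inheritance_factor must be in [0, 1], got {self.inheritance_factor}")
        for name in ("title_match_weight", "description_match_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.title_match_weight < self.description_match_weight:
            raise ValueError("title_match_weight must be >= description_match_weight")


@dataclass(frozen=True)
class HealthTrustScores:
    """Trust values in [0, 1] for every content item and channel."""

    content_scores: dict[str, float]
    channel_scores: dict[str, float]


class HealthTrustModel:
    """Trust model over a validated community graph.

    Parameters
    ----------
    graph : CommunityGraph
        The community to score.
    params : TrustParameters, optional
        Inheritance factor and search match weights.
    content_graph_mode : {"expansion", "user-edge"}
        How subscriptions enter the mixed content graph.
    tolerance, max_iterations :
        HITS stopping rule (max absolute per-node change).
    """

    def __init__(
        self,
        graph: CommunityGraph,
        params: TrustParameters | None = None,
        *,
        content_graph_mode: ContentGraphMode = "expansion",
        tolerance: float = 1e-10,
        max_iterations: int = 1000,
    ):
        self.graph = graph
        self.params = params or TrustParameters()
        self.content_graph_mode: ContentGraphMode = content_graph_mode
        self.tolerance = tolerance
        self.max_iterations = max_iterations

    def fit(self) -> "HealthTrustResults":
        """Run HITS on both endorsement graphs and combine the scores."""
        user_scores = authority.hits(
            authority.build_user_graph(self.graph), self.tolerance, self.max_iterations
        )
        content_hits = authority.hits(
            authority.build_content_graph(self.graph, self.content_graph_mode),
            self.tolerance,
            self.max_iterations,
        )
        # user and content scores are normalized as two separate ranges
        content_norm = authority.minmax_normalize(
            {cid: content_hits.raw[cid] for cid in self.graph.content}
        )
        if_ = self.params.inheritance_factor
        content_scores = {
            cid: if_ * user_scores.normalized[c.author_id] + (1.0 - if_) * content_norm[cid]
            for cid, c in self.graph.content.items()
        }
        return HealthTrustResults(
            model=self,
            scores=HealthTrustScores(
                content_scores=content_scores,
                channel_scores=dict(user_scores.normalized),
            ),
            user_authority=user_scores,
            content_authority_raw=content_hits,
            content_authority=content_norm,
        )


@dataclass(frozen=True)
class HealthTrustResults:
    """Fitted trust scores with the authority diagnostics behind them."""

    model: HealthTrustModel
    scores: HealthTrustScores
    user_authority: AuthorityScores
    content_authority_raw: AuthorityScores
    content_authority: dict[str, float]  # min-max over content nodes only

    @property
    def content_scores(self) -> dict[str, float]:
        return self.scores.content_scores

    @property
    def channel_scores(self) -> dict[str, float]:
        return self.scores.channel_scores

    @property
    def converged(self) -> bool:
        return self.user_authority.converged and self.content_authority_raw.converged

    def content_frame(self) -> pd.DataFrame:
        """Per-item table: content_id, author_id, user_auth, content_auth, healthtrust."""
        g = self.model.graph
        rows = [
            {
                "content_id": cid,
                "author_id": g.content[cid].author_id,
                "user_auth": self.channel_scores[g.content[cid].author_id],
                "content_auth": self.content_authority[cid],
                "healthtrust": self.content_scores[cid],
            }
            for cid in sorted(g.content)
        ]
        return pd.DataFrame(rows, columns=["content_id", "author_id", "user_auth", "content_auth", "healthtrust"])

    def channel_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node_id": uid,
                "node_class": "user",
                "raw_authority": self.user_authority.raw[uid],
                "normalized_authority": self.user_authority.normalized[uid],
                "hub": self.user_authority.hub[uid],
            }
            for uid in sorted(self.model.graph.users)
        ]
        return pd.DataFrame(rows, columns=["node_id", "node_class", "raw_authority", "normalized_authority", "hub"])

    def search(self, query: str, top_k: int = 10):
        """Rank content for a query using these fitted scores (see ``search`` module)."""
        from .search import search_results

        return search_results(self, query, top_k=top_k)

    def top_content(self, k: int = 10) -> list[str]:
        """The k highest-trust content ids (ties broken by ascending id)."""
        ranked = sorted(self.content_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return [cid for cid, _ in ranked[:k]]

    def summary(self) -> str:
        g = self.model.graph
        p = self.model.params
        lines = [
            "HealthTrust model fit",
            "=" * 56,
            f"users: {g.n_users}   content: {g.n_content}   links: {g.n_links}",
            f"inheritance_factor: {p.inheritance_factor}",
            f"content graph mode: {self.model.content_graph_mode}",
            (
                f"user HITS: {'converged' if self.user_authority.converged else 'NOT converged'}"
                f" in {self.user_authority.n_iterations} iteration(s)"
            ),
            (
                f"content HITS: {'converged' if self.content_authority_raw.converged else 'NOT converged'}"
                f" in {self.content_authority_raw.n_iterations} iteration(s)"
            ),
            "-" * 56,
            "top channels by trust:",
        ]
        top_ch = sorted(self.channel_scores.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        lines += [f"  {uid:<28s} {s:8.4f}" for uid, s in top_ch]
        lines.append("top content by trust:")
        top_ct = sorted(self.content_scores.items(), key=lambda kv: (-kv[1], kv[0]))[:5]
        lines += [f"  {cid:<28s} {s:8.4f}" for cid, s in top_ct]
        return "\n".join(lines)


def healthtrust_content(
    g: CommunityGraph,
    params: TrustParameters | None = None,
    *,
    content_graph_mode: ContentGraphMode = "expansion",
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> HealthTrustScores:
    """Content and channel trust scores for a community (functional form)."""
    return HealthTrustModel(
        g, params, content_graph_mode=content_graph_mode,
        tolerance=tolerance, max_iterations=max_iterations,
    ).fit().scores


def healthtrust_channel(g: CommunityGraph, tolerance: float = 1e-10, max_iterations: int = 1000) -> dict[str, float]:
    """Channel-level trust: identical to normalized user authoritativeness."""
    return authority.user_authoritativeness(g, tolerance, max_iterations)
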