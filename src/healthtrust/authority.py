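"""Link-analysis authority: endorsement-graph construction and HITS.

Two directed graphs are derived from a community snapshot:

* the **user graph** — nodes are channels; an edge X->Y exists when X
  subscribes to Y, or when X favorites any content authored by Y
  (favorites project onto the author);
* the **content graph** — nodes are channels and content; a favorite gives
  an edge user->item, and a subscription X->Y expands to an edge from X to
  every item authored by Y (so channels act as pure hubs and items as pure
  authorities). An alternative ``user-edge`` mode keeps the subscription as
  a single X->Y edge inside the mixed graph instead of expanding it.

Authoritativeness is the HITS authority score: hubs are nodes whose
outgoing endorsements point at authoritative nodes, authorities accrue
score from incoming endorsements by strong hubs. Scores are min-max
normalized to [0, 1] before being combined downstream; for the content
graph, normalization is computed over content nodes only so the two score
families occupy comparable ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import scipy.sparse as sp

from .community import CommunityGraph

ContentGraphMode = Literal["expansion", "user-edge"]


@dataclass(frozen=True)
class DirectedGraph:
    """A simple directed graph: deduplicated edges, no self-loops."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint outside the node set")
            if u == v:
                raise ValueError(f"self-loop on {u!r}")

    @classmethod
    def from_sets(cls, nodes, edges) -> "DirectedGraph":
        """Canonicalize: sort nodes and edges, drop duplicates and self-loops."""
        return cls(
            nodes=tuple(sorted(set(nodes))),
            edges=tuple(sorted({(u, v) for u, v in edges if u != v})),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class AuthorityScores:
    """HITS output: raw and [0,1]-normalized authority, plus hub scores."""

    raw: dict[str, float]
    normalized: dict[str, float]
    hub: dict[str, float]
    converged: bool = True
    n_iterations: int = 0


def build_user_graph(g: CommunityGraph) -> DirectedGraph:
    """Channel endorsement graph: subscriptions plus author-projected favorites."""
    edges: set[tuple[str, str]] = set()
    for l in g.subscriptions():
        edges.add((l.source, l.target))
    for l in g.favorites():
        author = g.content[l.target].author_id
        if author != l.source:
            edges.add((l.source, author))
    return DirectedGraph.from_sets(g.users.keys(), edges)


def build_content_graph(g: CommunityGraph, mode: ContentGraphMode = "expansion") -> DirectedGraph:
    """Mixed user/content endorsement graph used to score content.

    ``expansion`` (default): a subscription X->Y becomes edges X->w for
    every item w authored by Y. ``user-edge``: the subscription stays a
    single X->Y edge between the user nodes.
    """
    if mode not in ("expansion", "user-edge"):
        raise ValueError(f"unknown content-graph mode {mode!r}")
    by_author = g.content_by_author()
    edges: set[tuple[str, str]] = set()
    for l in g.favorites():
        edges.add((l.source, l.target))
    for l in g.subscriptions():
        if mode == "expansion":
            for cid in by_author.get(l.target, ()):
                edges.add((l.source, cid))
        else:
            edges.add((l.source, l.target))
    return DirectedGraph.from_sets(list(g.users) + list(g.content), edges)


def hits(
    graph: DirectedGraph,
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> AuthorityScores:
    """Hub/authority scores by the mutual-reinforcement power iteration.

    authority(v) <- sum of hub(u) over in-neighbors u;
    hub(u) <- sum of authority(v) over out-neighbors v; both vectors are
    renormalized to unit Euclidean length each iteration. Initialization is
    uniform and node order is sorted id, so results are bit-reproducible.
    Iteration stops when the max absolute per-node change of both vectors
    falls below ``tolerance``; ``converged`` is False if ``max_iterations``
    is exhausted first. Nodes with no incoming edges receive authority 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = graph.n_nodes
    if n == 0:
        return AuthorityScores(raw={}, normalized={}, hub={}, converged=True, n_iterations=0)

    index = {node: i for i, node in enumerate(graph.nodes)}  # nodes are sorted
    if graph.edges:
        rows = np.array([index[u] for u, v in graph.edges])
        cols = np.array([index[v] for u, v in graph.edges])
        data = np.ones(len(graph.edges))
        adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n))

    hub_v = np.full(n, 1.0 / np.sqrt(n))
    auth_v = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        new_auth = adj.T @ hub_v
        norm = np.linalg.norm(new_auth)
        if norm > 0:
            new_auth = new_auth / norm
        new_hub = adj @ new_auth
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub = new_hub / norm
        delta = max(np.max(np.abs(new_auth - auth_v)), np.max(np.abs(new_hub - hub_v)))
        auth_v, hub_v = new_auth, new_hub
        if delta < tolerance:
            converged = True
            break

    raw = {node: float(auth_v[i]) for node, i in index.items()}
    return AuthorityScores(
        raw=raw,
        normalized=minmax_normalize(raw),
        hub={node: float(hub_v[i]) for node, i in index.items()},
        converged=converged,
        n_iterations=iterations,
    )


def minmax_normalize(raw: Mapping[str, float]) -> dict[str, float]:
    """Rescale scores to [0, 1] by (x - min) / (max - min).

    Degenerate input (all values equal, including the all-zero link-free
    case) maps to all zeros so that an endorsement-free community confers
    no link-based trust.
    """
    if not raw:
        return {}
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi == lo:
        return {k: 0.0 for k in raw}
    span = hi - lo
    return {k: (v - lo) / span for k, v in raw.items()}


def user_authoritativeness(
    g: CommunityGraph,
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> dict[str, float]:
    """Normalized HITS authority of every channel in the community."""
    return hits(build_user_graph(g), tolerance, max_iterations).normalized


def content_authoritativeness(
    g: CommunityGraph,
    mode: ContentGraphMode = "expansion",
    tolerance: float = 1e-10,
    max_iterations: int = 1000,
) -> dict[str, float]:
    """Normalized HITS authority of every content item.

    HITS runs on the mixed user/content graph, but min-max normalization is
    computed over the content nodes only: user and content scores form two
    separately normalized ranges.
    """
    scores = hits(build_content_graph(g, mode), tolerance, max_iterations)
    content_raw = {cid: scores.raw[cid] for cid in g.content}
    return minmax_normalize(content_raw)
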