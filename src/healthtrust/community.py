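"""Community data model: users (channels), content items, endorsement links.

An online health community is modeled as a heterogeneous directed graph.
Users publish content items; two kinds of endorsement link are scored:

* ``subscription`` — user -> user ("I follow this channel"),
* ``favorite``     — user -> content ("I bookmark this item").

Other social links occasionally present in platform exports (friendships,
comments) are accepted on input but carry no weight in any score, so they
are dropped at validation time with a log message.

The module also provides keyword-based subcommunity extraction, so that
authority is measured *within* a topic community rather than against the
platform at large, and readers/writers for the JSON / TSV / GraphML
serializations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: link kinds that participate in scoring
SCORED_KINDS = ("subscription", "favorite")
#: link kinds tolerated in input files but ignored by all scoring
IGNORED_KINDS = ("friendship", "comment")


class GraphValidationError(ValueError):
    """Raised when input records cannot form a valid community graph.

    ``errors`` lists one message per offending record.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid record(s): {preview}{more}")


@dataclass(frozen=True)
class UserNode:
    """A community member (channel) that can publish and endorse."""

    id: str
    display_name: str = ""
    description: str = ""
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError(["user with empty id"])
        object.__setattr__(self, "keywords", tuple(self.keywords))


@dataclass(frozen=True)
class ContentNode:
    """A published item (e.g. a video) owned by exactly one user."""

    id: str
    author_id: str
    title: str = ""
    description: str = ""
    tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError(["content with empty id"])
        object.__setattr__(self, "tags", tuple(self.tags))


@dataclass(frozen=True)
class EndorsementLink:
    """A directed endorsement: subscription (user->user) or favorite (user->content)."""

    source: str
    kind: str
    target: str


@dataclass(frozen=True)
class CommunityGraph:
    """A validated community snapshot: all scoring operates on this object.

    Invariants (enforced by :func:`build_graph`):

    * every link endpoint resolves to an existing node of the right class,
    * links are deduplicated (binary endorsement, simple graph),
    * no self-subscriptions and no favorites of one's own content,
    * user and content ids live in disjoint namespaces.
    """

    users: Mapping[str, UserNode]
    content: Mapping[str, ContentNode]
    links: tuple[EndorsementLink, ...]

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_content(self) -> int:
        return len(self.content)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def subscriptions(self) -> list[EndorsementLink]:
        return [l for l in self.links if l.kind == "subscription"]

    def favorites(self) -> list[EndorsementLink]:
        return [l for l in self.links if l.kind == "favorite"]

    def content_by_author(self) -> dict[str, list[str]]:
        """Map each user id to the sorted ids of the content they authored."""
        out: dict[str, list[str]] = {uid: [] for uid in self.users}
        for cid in sorted(self.content):
            out[self.content[cid].author_id].append(cid)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CommunityGraph(users={self.n_users}, content={self.n_content}, "
            f"links={self.n_links})"
        )


def build_graph(
    users: Iterable[UserNode | Mapping],
    content: Iterable[ContentNode | Mapping],
    links: Iterable[EndorsementLink | Mapping],
) -> CommunityGraph:
    """Validate and canonicalize raw records into a :class:`CommunityGraph`.

    Duplicate links collapse to one; self-endorsements (self-subscriptions
    and favorites of one's own content) are dropped with a warning; links of
    ignored kinds (friendship, comment) are dropped silently. Hard errors —
    duplicate node ids, user/content id collisions, links whose endpoints do
    not resolve or whose kind is unknown — are collected and raised together
    as :class:`GraphValidationError` listing every offender.
    """
    errors: list[str] = []

    user_map: dict[str, UserNode] = {}
    for u in users:
        node = u if isinstance(u, UserNode) else UserNode(
            id=str(u["id"]),
            display_name=str(u.get("display_name", "")),
            description=str(u.get("description", "")),
            keywords=tuple(u.get("keywords", ())),
        )
        if node.id in user_map:
            errors.append(f"duplicate user id {node.id!r}")
        else:
            user_map[node.id] = node

    content_map: dict[str, ContentNode] = {}
    for c in content:
        node = c if isinstance(c, ContentNode) else ContentNode(
            id=str(c["id"]),
            author_id=str(c["author_id"]),
            title=str(c.get("title", "")),
            description=str(c.get("description", "")),
            tags=tuple(c.get("tags", ())),
        )
        if node.id in content_map:
            errors.append(f"duplicate content id {node.id!r}")
        elif node.id in user_map:
            errors.append(f"content id {node.id!r} collides with a user id")
        else:
            content_map[node.id] = node
    for cid, node in content_map.items():
        if node.author_id not in user_map:
            errors.append(f"content {cid!r} has unknown author {node.author_id!r}")

    kept: dict[tuple[str, str, str], EndorsementLink] = {}
    n_dup = n_self = n_ignored = 0
    for l in links:
        link = l if isinstance(l, EndorsementLink) else EndorsementLink(
            source=str(l["source"]), kind=str(l["kind"]), target=str(l["target"])
        )
        if link.kind in IGNORED_KINDS:
            n_ignored += 1
            continue
        if link.kind not in SCORED_KINDS:
            errors.append(f"link {link.source!r}->{link.target!r} has unknown kind {link.kind!r}")
            continue
        if link.source not in user_map:
            errors.append(f"{link.kind} from unknown user {link.source!r}")
            continue
        if link.kind == "subscription":
            if link.target not in user_map:
                errors.append(f"subscription {link.source!r}->{link.target!r}: unknown user target")
                continue
            if link.source == link.target:
                n_self += 1
                logger.warning("dropping self-subscription by %s", link.source)
                continue
        else:  # favorite
            if link.target not in content_map:
                errors.append(f"favorite {link.source!r}->{link.target!r}: unknown content target")
                continue
            if content_map[link.target].author_id == link.source:
                n_self += 1
                logger.warning("dropping self-favorite by %s of own content %s", link.source, link.target)
                continue
        key = (link.source, link.kind, link.target)
        if key in kept:
            n_dup += 1
        else:
            kept[key] = link

    if errors:
        raise GraphValidationError(errors)

    if n_dup or n_self or n_ignored:
        logger.info(
            "build_graph dropped %d duplicate, %d self-endorsement, %d ignored-kind link(s)",
            n_dup, n_self, n_ignored,
        )
    return CommunityGraph(
        users=dict(sorted(user_map.items())),
        content=dict(sorted(content_map.items())),
        links=tuple(kept[k] for k in sorted(kept)),
    )


def _user_text(u: UserNode) -> str:
    return " ".join([u.display_name, u.description, *u.keywords]).casefold()


def _content_text(c: ContentNode) -> str:
    return " ".join([c.title, c.description, *c.tags]).casefold()


def extract_community(graph: CommunityGraph, terms: Sequence[str]) -> CommunityGraph:
    """Induce the topic subcommunity whose members mention any of ``terms``.

    A user is retained when any term occurs, case-insensitively, in their
    display name, description or keywords. Content is retained when its
    author is retained; links are retained when both endpoints survive.
    The result is always a subgraph of the input and the operation is
    idempotent.
    """
    if not terms:
        raise ValueError("extract_community requires a non-empty term list")
    folded = [t.casefold() for t in terms]

    kept_users = {
        uid: u for uid, u in graph.users.items()
        if any(t in _user_text(u) for t in folded)
    }
    kept_content = {
        cid: c for cid, c in graph.content.items() if c.author_id in kept_users
    }
    kept_ids = set(kept_users) | set(kept_content)
    kept_links = tuple(
        l for l in graph.links if l.source in kept_ids and l.target in kept_ids
    )
    return CommunityGraph(users=kept_users, content=kept_content, links=kept_links)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_LIST_SEP = "|"  # separator for keywords/tags inside a single TSV cell


def load_json(path: str | Path) -> CommunityGraph:
    """Read a community JSON file (keys ``users``, ``content``, ``links``)."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return build_graph(doc.get("users", []), doc.get("content", []), doc.get("links", []))


def save_json(graph: CommunityGraph, path: str | Path) -> None:
    doc = {
        "users": [
            {
                "id": u.id,
                "display_name": u.display_name,
                "description": u.description,
                "keywords": list(u.keywords),
            }
            for u in graph.users.values()
        ],
        "content": [
            {
                "id": c.id,
                "author_id": c.author_id,
                "title": c.title,
                "description": c.description,
                "tags": list(c.tags),
            }
            for c in graph.content.values()
        ],
        "links": [
            {"source": l.source, "kind": l.kind, "target": l.target}
            for l in graph.links
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")


def _split_list(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    return tuple(s for s in str(cell).split(_LIST_SEP) if s)


def load_tsv(users_path: str | Path, content_path: str | Path, links_path: str | Path) -> CommunityGraph:
    """Read a community from three headered TSV node/edge tables."""
    users_df = pd.read_csv(users_path, sep="\t", dtype=str).fillna("")
    content_df = pd.read_csv(content_path, sep="\t", dtype=str).fillna("")
    links_df = pd.read_csv(links_path, sep="\t", dtype=str).fillna("")
    users = [
        UserNode(
            id=r["id"], display_name=r.get("display_name", ""),
            description=r.get("description", ""), keywords=_split_list(r.get("keywords", "")),
        )
        for r in users_df.to_dict("records")
    ]
    content = [
        ContentNode(
            id=r["id"], author_id=r["author_id"], title=r.get("title", ""),
            description=r.get("description", ""), tags=_split_list(r.get("tags", "")),
        )
        for r in content_df.to_dict("records")
    ]
    links = [
        EndorsementLink(source=r["source"], kind=r["kind"], target=r["target"])
        for r in links_df.to_dict("records")
    ]
    return build_graph(users, content, links)


def save_tsv(graph: CommunityGraph, users_path: str | Path, content_path: str | Path, links_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": u.id, "display_name": u.display_name,
                "description": u.description, "keywords": _LIST_SEP.join(u.keywords),
            }
            for u in graph.users.values()
        ],
        columns=["id", "display_name", "description", "keywords"],
    ).to_csv(users_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": c.id, "author_id": c.author_id, "title": c.title,
                "description": c.description, "tags": _LIST_SEP.join(c.tags),
            }
            for c in graph.content.values()
        ],
        columns=["id", "author_id", "title", "description", "tags"],
    ).to_csv(content_path, sep="\t", index=False)
    pd.DataFrame(
        [{"source": l.source, "kind": l.kind, "target": l.target} for l in graph.links],
        columns=["source", "kind", "target"],
    ).to_csv(links_path, sep="\t", index=False)


def to_networkx(graph: CommunityGraph) -> nx.DiGraph:
    """Export the heterogeneous community as a networkx DiGraph.

    Node attribute ``node_class`` is ``user`` or ``content``; edges carry
    their endorsement ``kind`` (or ``authorship`` for owner edges).
    """
    g = nx.DiGraph()
    for u in graph.users.values():
        g.add_node(u.id, node_class="user", display_name=u.display_name)
    for c in graph.content.values():
        g.add_node(c.id, node_class="content", title=c.title)
        g.add_edge(c.author_id, c.id, kind="authorship")
    for l in graph.links:
        g.add_edge(l.source, l.target, kind=l.kind)
    return g


def save_graphml(graph: CommunityGraph, path: str | Path) -> None:
    nx.write_graphml(to_networkx(graph), str(path))
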