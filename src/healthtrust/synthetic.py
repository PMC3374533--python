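"""Seeded synthetic communities with planted trust structure.

Emulates the shape of a topic community on a video-sharing platform:

* a densely inter-endorsing **core** of trusted channels (they subscribe
  to each other and favorite each other's videos),
* weakly connected legitimate **peripheral** channels (they endorse core
  content but receive almost no endorsement themselves),
* poorly endorsed **spam**/misleading channels that form their own sparse
  clique and otherwise receive only background links.

Every link and every piece of metadata is drawn from a substream keyed by
a stable hash of the entities involved, so the same seed always yields the
same community and adding channels does not perturb the draws of existing
ones. The generator also emits planted truth labels, and
:func:`generate_judgments` synthesizes reviewer ratings around per-class
quality anchors so the full score -> search -> evaluate pipeline runs
without any real platform data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import (
    CommunityGraph,
    ContentNode,
    EndorsementLink,
    UserNode,
    build_graph,
)

#: mean rating anchor per planted class on the 1-5 scale
CLASS_QUALITY = {"core": 4.2, "peripheral": 3.2, "spam": 1.8}

RECOMMEND_THRESHOLD = 3.5

_DEFAULT_TERMS = ("diabetes", "insulin", "blood sugar", "a1c", "diabetic foot")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the planted community.

    The default link probabilities give a tight core (pairwise subscription
    probability 0.8, favorite probability 0.3), a sparse spam clique (0.3)
    and a 1% background link rate connecting everything weakly.
    """

    n_core_channels: int = 10
    n_peripheral_channels: int = 30
    n_spam_channels: int = 10
    videos_per_channel: int = 5
    p_core_core_subscribe: float = 0.8
    p_any_core_favorite: float = 0.3
    p_spam_spam_subscribe: float = 0.3
    p_background_link: float = 0.01
    topic_terms: tuple[str, ...] = _DEFAULT_TERMS
    p_title_term: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_core_core_subscribe", "p_any_core_favorite",
            "p_spam_spam_subscribe", "p_background_link", "p_title_term",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_core_channels", "n_peripheral_channels", "n_spam_channels", "videos_per_channel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "topic_terms", tuple(self.topic_terms))


def _h32(*parts: str) -> int:
    """Stable 31-bit hash of a tuple of strings (order-sensitive)."""
    digest = hashlib.sha256("\x1f".join(parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _rng(seed: int, *parts: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, _h32(*parts)])


def generate_community(params: GeneratorParams) -> tuple[CommunityGraph, pd.DataFrame]:
    """Generate the planted community and its truth table.

    Returns the validated graph plus a DataFrame with columns
    ``node_id``, ``node_class`` (user/content), ``role``
    (core/peripheral/spam) and, for content, ``author_id``.
    """
    seed = params.seed
    roles: dict[str, str] = {}
    channel_ids: list[str] = []
    for role, count, prefix in (
        ("core", params.n_core_channels, "core"),
        ("peripheral", params.n_peripheral_channels, "peri"),
        ("spam", params.n_spam_channels, "spam"),
    ):
        for i in range(count):
            cid = f"{prefix}_{i:03d}"
            channel_ids.append(cid)
            roles[cid] = role

    users: list[UserNode] = []
    content: list[ContentNode] = []
    video_author: dict[str, str] = {}
    for ch in channel_ids:
        role = roles[ch]
        meta = _rng(seed, "channel-meta", ch)
        term = params.topic_terms[meta.integers(len(params.topic_terms))] if params.topic_terms else ""
        if role == "spam":
            desc = f"Amazing miracle cures, {term} secrets they do not want you to know"
        else:
            desc = f"A channel about living with {term}"
        users.append(
            UserNode(id=ch, display_name=ch.replace("_", " "), description=desc,
                     keywords=(term,) if term else ())
        )
        for j in range(params.videos_per_channel):
            vid = f"{ch}_v{j:02d}"
            video_author[vid] = ch
            vmeta = _rng(seed, "video-meta", vid)
            title_term = (
                params.topic_terms[vmeta.integers(len(params.topic_terms))]
                if params.topic_terms and vmeta.random() < params.p_title_term
                else None
            )
            desc_term = (
                params.topic_terms[vmeta.integers(len(params.topic_terms))]
                if params.topic_terms and vmeta.random() < params.p_title_term
                else None
            )
            if role == "spam":
                title = f"Miracle {title_term} cure #{j}" if title_term else f"Shocking secret #{j}"
                vdesc = f"Forget doctors, this fixes {desc_term} fast" if desc_term else "You will not believe this"
            else:
                title = f"Managing {title_term}: part {j}" if title_term else f"Video diary #{j}"
                vdesc = f"Practical advice about {desc_term} from {ch}" if desc_term else f"An update from {ch}"
            content.append(
                ContentNode(id=vid, author_id=ch, title=title, description=vdesc,
                            tags=tuple(t for t in (title_term, desc_term) if t))
            )

    links: list[EndorsementLink] = []
    # channel -> channel subscriptions
    for src in channel_ids:
        for dst in channel_ids:
            if src == dst:
                continue
            r = _rng(seed, "subscribe", src, dst)
            p = 0.0
            if roles[src] == "core" and roles[dst] == "core":
                p = params.p_core_core_subscribe
            elif roles[src] == "spam" and roles[dst] == "spam":
                p = params.p_spam_spam_subscribe
            # universal sparse background layer on top of the planted rules
            if r.random() < p or r.random() < params.p_background_link:
                links.append(EndorsementLink(source=src, kind="subscription", target=dst))
    # channel -> video favorites
    for src in channel_ids:
        for vid, author in video_author.items():
            if author == src:
                continue
            r = _rng(seed, "favorite", src, vid)
            p = 0.0
            if roles[author] == "core" and roles[src] in ("core", "peripheral"):
                p = params.p_any_core_favorite
            if r.random() < p or r.random() < params.p_background_link:
                links.append(EndorsementLink(source=src, kind="favorite", target=vid))

    graph = build_graph(users, content, links)
    truth_rows = [
        {"node_id": ch, "node_class": "user", "role": roles[ch], "author_id": ""}
        for ch in channel_ids
    ] + [
        {"node_id": vid, "node_class": "content", "role": roles[author], "author_id": author}
        for vid, author in video_author.items()
    ]
    truth = pd.DataFrame(truth_rows, columns=["node_id", "node_class", "role", "author_id"])
    return graph, truth


def generate_judgments(
    graph: CommunityGraph,
    truth: pd.DataFrame,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_reviewers: int = 2,
) -> pd.DataFrame:
    """Synthesize reviewer ratings around the per-class quality anchors.

    Each item's mean rating is its class anchor (core 4.2, peripheral 3.2,
    spam 1.8) plus zero-mean Gaussian noise of scale ``noise_sd``, clipped
    to [1, 5]; each reviewer's rating adds further noise of the same scale
    around that mean. A rating at or above 3.5 is a recommendation.

    Returns a long-format table: item_id, node_class, role, reviewer_id,
    rating, recommended, mean_rating, mean_recommended.
    """
    if truth.empty:
        return pd.DataFrame(
            columns=["item_id", "node_class", "role", "reviewer_id",
                     "rating", "recommended", "mean_rating", "mean_recommended"]
        )
    rows = []
    for rec in truth.to_dict("records"):
        item, role = str(rec["node_id"]), str(rec["role"])
        r = _rng(seed, "judgment", item)
        mean_rating = float(np.clip(CLASS_QUALITY[role] + r.normal(0.0, noise_sd), 1.0, 5.0))
        for k in range(1, n_reviewers + 1):
            rating = float(np.clip(mean_rating + r.normal(0.0, noise_sd), 1.0, 5.0))
            rows.append({
                "item_id": item,
                "node_class": rec["node_class"],
                "role": role,
                "reviewer_id": f"reviewer_{k}",
                "rating": rating,
                "recommended": int(rating >= RECOMMEND_THRESHOLD),
                "mean_rating": mean_rating,
                "mean_recommended": int(mean_rating >= RECOMMEND_THRESHOLD),
            })
    return pd.DataFrame(rows)
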