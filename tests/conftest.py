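import pytest

from healthtrust import (
    ContentNode,
    EndorsementLink,
    GeneratorParams,
    UserNode,
    build_graph,
    generate_community,
)


def user(uid, name="", desc="", keywords=()):
    return UserNode(id=uid, display_name=name or uid, description=desc, keywords=tuple(keywords))


def video(vid, author, title="", desc="", tags=(), description=None):
    return ContentNode(
        id=vid, author_id=author, title=title,
        description=description if description is not None else desc,
        tags=tuple(tags),
    )


def sub(src, dst):
    return EndorsementLink(source=src, kind="subscription", target=dst)


def fav(src, dst):
    return EndorsementLink(source=src, kind="favorite", target=dst)


@pytest.fixture
def star_community():
    """Three hub channels all subscribing to one center channel.

    The center is the unique authority; it owns two videos that nobody has
    favorited.
    """
    return build_graph(
        users=[user("center"), user("h1"), user("h2"), user("h3")],
        content=[
            video("center_v1", "center", title="Video one"),
            video("center_v2", "center", title="Video two"),
        ],
        links=[sub("h1", "center"), sub("h2", "center"), sub("h3", "center")],
    )


@pytest.fixture(scope="session")
def preset_community():
    """The default planted community (10 core / 30 peripheral / 10 spam)."""
    graph, truth = generate_community(GeneratorParams(seed=42))
    return graph, truth
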