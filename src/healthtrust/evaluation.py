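"""Ranked-retrieval evaluation: precision@K, DCG, Pearson, Cohen kappa.

A ranked list joined with reviewer judgments is the unit of evaluation
(:class:`JudgedRanking`). Binary relevance can be derived three ways —
both reviewers recommend, at least one recommends, or mean rating above a
threshold (the rating scale runs 1–5 and the conventional cutoff is 3.5).

DCG uses the classic formulation with an undiscounted first position:

    DCG_i = rel_1 + sum_{j=2..i} rel_j / log_b(j),   b = 2 by default.

Pearson correlation reports (r, p, df) with df = n - 2 — the subscript
convention in which r_10 denotes a sample of 12 pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

RelevanceMode = Literal["both_reviewers", "at_least_one", "rating_threshold"]

RATING_THRESHOLD = 3.5  # a mean rating at or above this counts as relevant


@dataclass(frozen=True)
class JudgedRanking:
    """A ranked item list with per-reviewer binary labels and/or mean ratings.

    ``reviewer_labels`` maps each reviewer id to a 0/1 vector aligned with
    ``item_ids`` (position j = rank j+1). ``mean_ratings``, when present,
    is the per-item mean reviewer rating on the 1–5 scale.
    """

    item_ids: tuple[str, ...]
    reviewer_labels: dict[str, tuple[int, ...]]
    mean_ratings: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.item_ids)
        for reviewer, labels in self.reviewer_labels.items():
            if len(labels) != n:
                raise ValueError(f"labels of reviewer {reviewer!r} do not cover every ranked item")
            if any(l not in (0, 1) for l in labels):
                raise ValueError(f"labels of reviewer {reviewer!r} must be binary")
        if self.mean_ratings is not None and len(self.mean_ratings) != n:
            raise ValueError("mean_ratings do not cover every ranked item")

    def __len__(self) -> int:
        return len(self.item_ids)

    def relevance(self, mode: RelevanceMode, threshold: float = RATING_THRESHOLD) -> tuple[int, ...]:
        """Binary relevance per position under the given counting mode."""
        if mode in ("both_reviewers", "at_least_one"):
            if not self.reviewer_labels:
                raise ValueError("no reviewer labels available")
            mat = np.array([self.reviewer_labels[r] for r in sorted(self.reviewer_labels)])
            agg = mat.min(axis=0) if mode == "both_reviewers" else mat.max(axis=0)
            return tuple(int(v) for v in agg)
        if mode == "rating_threshold":
            if self.mean_ratings is None:
                raise ValueError("no ratings available for rating_threshold mode")
            return tuple(int(r >= threshold) for r in self.mean_ratings)
        raise ValueError(f"unknown relevance mode {mode!r}")


def precision_at_k(
    jr: JudgedRanking,
    k: int,
    mode: RelevanceMode = "both_reviewers",
    threshold: float = RATING_THRESHOLD,
) -> float:
    """Fraction of the top-k items judged relevant under ``mode``."""
    if k < 1 or k > len(jr):
        raise ValueError(f"k must be in [1, {len(jr)}], got {k}")
    rel = jr.relevance(mode, threshold)[:k]
    return sum(rel) / k


def dcg(
    jr: JudgedRanking | Sequence[float],
    i: int,
    mode: RelevanceMode = "at_least_one",
    threshold: float = RATING_THRESHOLD,
    base: float = 2.0,
) -> float:
    """Discounted cumulative gain at cutoff ``i``.

    Accepts either a :class:`JudgedRanking` (relevance derived via
    ``mode``) or a raw relevance-gain sequence. Position 1 is undiscounted;
    position j >= 2 is discounted by log_base(j).
    """
    if i < 1:
        raise ValueError("cutoff i must be >= 1")
    rel = jr.relevance(mode, threshold) if isinstance(jr, JudgedRanking) else tuple(jr)
    if i > len(rel):
        raise ValueError(f"cutoff i={i} exceeds list length {len(rel)}")
    total = float(rel[0])
    for j in range(2, i + 1):
        total += rel[j - 1] / math.log(j, base)
    return total


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson correlation with two-sided p-value and df = n - 2.

    p comes from the t statistic t = r * sqrt(df / (1 - r^2)); a perfect
    correlation gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("pearson requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n - 2


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), with the chance agreement p_e taken
    from the raters' marginal label frequencies. Raises when p_e = 1 (both
    raters constant and identical), where kappa is undefined.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if not a:
        raise ValueError("label vectors must be non-empty")
    categories = sorted(set(a) | set(b), key=str)
    n = len(a)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in categories)
    if p_e == 1.0:
        raise ValueError("kappa undefined: both raters constant and identical (p_e = 1)")
    return float(cohen_kappa_score(a, b, labels=categories))


def bad_item_rate(jr: JudgedRanking, k: int) -> float:
    """Fraction of top-k items recommended by *no* reviewer (misleading items).

    Complements precision under the at-least-one rule:
    bad_item_rate = 1 - precision_at_k(at_least_one).
    """
    if k < 1 or k > len(jr):
        raise ValueError(f"k must be in [1, {len(jr)}], got {k}")
    if not jr.reviewer_labels:
        raise ValueError("no reviewer labels available")
    mat = np.array([jr.reviewer_labels[r] for r in sorted(jr.reviewer_labels)])[:, :k]
    return float(np.mean(mat.max(axis=0) == 0))


# ---------------------------------------------------------------------------
# joining rankings with judgment tables
# ---------------------------------------------------------------------------

def judged_ranking_from_frames(
    ranking: pd.DataFrame,
    judgments: pd.DataFrame,
    *,
    item_col: str = "content_id",
    drop_unjudged: bool = True,
) -> tuple[JudgedRanking, list[str]]:
    """Join a ranking table with a long-format judgments table.

    ``ranking`` must be ordered (best first) with an ``item_col`` column.
    ``judgments`` has columns item_id, reviewer_id and recommended (0/1)
    and/or rating (1-5). Returns the JudgedRanking plus the ids of ranked
    items missing from the judgments (excluded when ``drop_unjudged``,
    an error otherwise).
    """
    if judgments.empty:
        raise ValueError("judgments table is empty")
    judged_ids = set(judgments["item_id"].astype(str))
    ordered = [str(i) for i in ranking[item_col]]
    unjudged = [i for i in ordered if i not in judged_ids]
    if unjudged and not drop_unjudged:
        raise ValueError(f"{len(unjudged)} ranked item(s) have no judgments: {unjudged[:5]}")
    kept = [i for i in ordered if i in judged_ids]

    labels: dict[str, tuple[int, ...]] = {}
    if "recommended" in judgments.columns:
        wide = judgments.pivot_table(
            index="item_id", columns="reviewer_id", values="recommended", aggfunc="first"
        )
        for reviewer in wide.columns:
            col = wide[reviewer]
            labels[str(reviewer)] = tuple(int(col.loc[i]) for i in kept)
    ratings = None
    if "rating" in judgments.columns:
        means = judgments.groupby("item_id")["rating"].mean()
        ratings = tuple(float(means.loc[i]) for i in kept)
    return JudgedRanking(item_ids=tuple(kept), reviewer_labels=labels, mean_ratings=ratings), unjudged


def metrics_table(
    jr: JudgedRanking,
    ks: Sequence[int] = (5, 10, 20),
    dcg_cutoffs: Sequence[int] = (5, 10, 20),
    modes: Sequence[RelevanceMode] = ("both_reviewers", "at_least_one"),
    threshold: float = RATING_THRESHOLD,
) -> pd.DataFrame:
    """Tabulate precision@K, DCG and bad-item rate for the requested cutoffs.

    Values are exact floats; any truncated-percentage display is left to
    report formatters.
    """
    rows = []
    usable_modes = [
        m for m in modes
        if (m == "rating_threshold" and jr.mean_ratings is not None)
        or (m != "rating_threshold" and jr.reviewer_labels)
    ]
    for mode in usable_modes:
        for k in ks:
            if k <= len(jr):
                rows.append({"metric": "precision_at_k", "mode": mode, "cutoff": k,
                             "value": precision_at_k(jr, k, mode, threshold)})
        for i in dcg_cutoffs:
            if i <= len(jr):
                rows.append({"metric": "dcg", "mode": mode, "cutoff": i,
                             "value": dcg(jr, i, mode, threshold)})
    if jr.reviewer_labels:
        for k in ks:
            if k <= len(jr):
                rows.append({"metric": "bad_item_rate", "mode": "none_recommend", "cutoff": k,
                             "value": bad_item_rate(jr, k)})
    return pd.DataFrame(rows, columns=["metric", "mode", "cutoff", "value"])


def truncate_percent(fraction: float) -> int:
    """Display helper: a fraction as a whole percentage truncated toward zero."""
    return math.trunc(fraction * 100)
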