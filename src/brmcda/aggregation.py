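"""Weighted additive aggregation of preference scores into scorecards.

Within a category the score is the swing-weighted average of the member
criteria's preferences, Σ w_j p_j / Σ w_j. Across categories the total
benefit-risk value is the category-weighted sum,
total = benefit_weight * benefit_value + risk_weight * risk_value.
Because the risk partial value function already reverses the scale
(higher preference = safer), the total is a *sum*, never a difference.

All comparisons and differences are computed on unrounded values;
rounding (half-up, to integers) is display-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .model_config import Category, ValueTree, normalize_weights
from .scoring import PreferenceMatrix

__all__ = [
    "AggregationError",
    "ScoreCard",
    "Ranking",
    "round_half_up",
    "aggregate_category",
    "aggregate_total",
    "score_card",
    "score_cards",
    "rank_alternatives",
]


class AggregationError(ValueError):
    pass


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties rounding up."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScoreCard:
    """Benefit, risk and total benefit-risk value for one alternative."""

    alternative: str
    benefit_value: float
    risk_value: float
    total_value: float

    @property
    def benefit_display(self) -> int:
        return round_half_up(self.benefit_value)

    @property
    def risk_display(self) -> int:
        return round_half_up(self.risk_value)

    @property
    def total_display(self) -> int:
        return round_half_up(self.total_value)


@dataclass(frozen=True)
class Ranking:
    """Alternatives ordered by descending total value, with pairwise gaps."""

    order: tuple[ScoreCard, ...]
    differences: tuple[float, ...]  # order[i].total - order[i+1].total
    tied: bool

    @property
    def best(self) -> ScoreCard:
        return self.order[0]


def aggregate_category(preferences: Sequence[float],
                       swing_weights: Sequence[float]) -> float:
    """Swing-weighted average Σ w_j p_j / Σ w_j of one category's preferences."""
    if len(preferences) != len(swing_weights):
        raise AggregationError(
            f"{len(preferences)} preferences vs {len(swing_weights)} weights")
    if not preferences:
        raise AggregationError("empty category")
    total_w = float(sum(swing_weights))
    if total_w <= 0:
        raise AggregationError("swing weights must sum to > 0")
    # works elementwise on arrays of preferences, so the Monte Carlo layer
    # can aggregate whole sample vectors through the same code path
    out = sum(w * p for w, p in zip(swing_weights, preferences)) / total_w
    return float(out) if not hasattr(out, "__len__") else out


def aggregate_total(benefit: float, risk: float, tree: ValueTree,
                    alternative: str = "") -> ScoreCard:
    """Combine category scores with the tree's top-level weights."""
    total = tree.benefit_weight * benefit + tree.risk_weight * risk
    return ScoreCard(alternative=alternative, benefit_value=benefit,
                     risk_value=risk, total_value=total)


def score_card(preferences: Mapping[str, float], tree: ValueTree,
               alternative: str = "") -> ScoreCard:
    """Full scorecard for one alternative from its per-criterion preferences."""
    cat_scores: dict[Category, float] = {}
    for cat in (Category.BENEFIT, Category.RISK):
        members = tree.category_criteria(cat)
        if not members:
            cat_scores[cat] = 0.0
            continue
        try:
            prefs = [preferences[c.id] for c in members]
        except KeyError as exc:
            raise AggregationError(f"missing preference for criterion {exc}")
        cat_scores[cat] = aggregate_category(
            prefs, [c.swing_weight for c in members])
    return aggregate_total(cat_scores[Category.BENEFIT],
                           cat_scores[Category.RISK], tree, alternative)


def score_cards(matrix: PreferenceMatrix, tree: ValueTree) -> list[ScoreCard]:
    return [score_card(matrix.row(alt), tree, alternative=alt)
            for alt in matrix.alternatives]


def total_from_weight_vector(preferences: Mapping[str, float],
                             tree: ValueTree) -> float:
    """Total value via the flat normalized weight vector, Σ relative_j p_j.

    Algebraically identical to the hierarchical two-stage aggregation;
    kept as an independent code path for cross-validation.
    """
    wv = normalize_weights(tree)
    return float(sum(w * preferences[cid] for cid, w in wv.items()))


def rank_alternatives(cards: Sequence[ScoreCard]) -> Ranking:
    """Order alternatives by total value (descending).

    Ties on the total are broken by benefit value, then lexicographic id,
    and flagged. Pairwise differences are computed on unrounded totals.
    """
    if len(cards) < 2:
        raise AggregationError("ranking needs at least two alternatives")
    order = tuple(sorted(
        cards, key=lambda c: (-c.total_value, -c.benefit_value, c.alternative)))
    diffs = tuple(order[i].total_value - order[i + 1].total_value
                  for i in range(len(order) - 1))
    tied = any(abs(d) < 1e-12 for d in diffs)
    return Ranking(order=order, differences=diffs, tied=tied)
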