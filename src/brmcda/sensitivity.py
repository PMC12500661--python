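"""Weight-perturbation sensitivity analysis and rank-crossover weights.

A perturbation scales one criterion's swing weight, or one category's
top-level weight, by (1 + delta) ("relative" mode) or shifts it by delta
points ("absolute" mode); sibling weights are renormalized proportionally
so the tree stays valid. A sweep applies a grid of perturbations to a set
of targets and reports, for each, whether the ranking of alternatives
changes relative to baseline.

For two alternatives the crossover weight — the value of a target's
weight at which the totals become equal — has a closed form because the
total is affine in any single weight once the others are renormalized
proportionally. The solved crossover is reported only when it falls
inside [0, 1]; when one alternative weakly dominates the other on every
criterion no crossover exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence

from .model_config import Category, ValueTree, normalize_weights
from .scoring import PreferenceMatrix
from .aggregation import Ranking, ScoreCard, rank_alternatives, score_cards

__all__ = [
    "SensitivityError",
    "SensitivityResult",
    "Crossover",
    "perturb_weight",
    "sweep",
    "crossover_weight",
]

PerturbMode = Literal["relative", "absolute"]

CATEGORY_TARGETS = ("benefit", "risk")


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class SensitivityResult:
    """Outcome of one (target, delta) perturbation."""

    target: str  # criterion id, "benefit" or "risk"
    delta: float
    scorecards: tuple[ScoreCard, ...]
    ranking: Ranking
    rank_changed: bool


class Crossover(NamedTuple):
    """Crossover weight for one target; ``degenerate`` marks an exact tie
    at every weight (identical alternatives)."""

    weight: float | None
    degenerate: bool = False


def _is_category(target: str) -> bool:
    return target in CATEGORY_TARGETS


def perturb_weight(tree: ValueTree, target: str, delta: float,
                   mode: PerturbMode = "relative") -> ValueTree:
    """Return a new tree with the target's weight perturbed.

    ``target`` is a criterion id or a category name ("benefit"/"risk").
    In "relative" mode the weight is scaled by (1 + delta); in "absolute"
    mode delta is added on the weight's own scale (points out of 100 for
    swings, a fraction for category weights). Category perturbations
    renormalize the other category so the top-level weights still sum to
    one; swing perturbations need no renormalization because category
    scores divide by the swing total.
    """
    if abs(delta) > 1.0 and mode == "relative":
        raise SensitivityError(f"|delta| must be <= 1, got {delta}")
    if _is_category(target):
        w0 = tree.category_weight(target)
        w = w0 * (1.0 + delta) if mode == "relative" else w0 + delta
        if w < 0:
            raise SensitivityError(
                f"perturbation drives {target} weight below zero ({w:.4f})")
        if w > 1:
            raise SensitivityError(
                f"perturbation drives {target} weight above one ({w:.4f})")
        benefit = w if target == "benefit" else 1.0 - w
        return ValueTree(benefit_weight=benefit, risk_weight=1.0 - benefit,
                         criteria=tree.criteria)
    crit = tree.criterion(target)  # KeyError for unknown targets
    s = (crit.swing_weight * (1.0 + delta) if mode == "relative"
         else crit.swing_weight + delta)
    if s <= 0:
        raise SensitivityError(
            f"perturbation drives swing weight of {target!r} to {s:.4f}")
    swings = {c.id: (s if c.id == target else c.swing_weight)
              for c in tree.criteria if c.category == crit.category}
    # swings are ratio-scale within a category: rescale so the largest is
    # back on the 0-100 convention, which changes no aggregate score
    scale = 100.0 / max(swings.values()) if max(swings.values()) > 100 else 1.0
    new_criteria = tuple(
        replace(c, swing_weight=swings[c.id] * scale)
        if c.category == crit.category else c
        for c in tree.criteria)
    return ValueTree(benefit_weight=tree.benefit_weight,
                     risk_weight=tree.risk_weight, criteria=new_criteria)


def sweep(tree: ValueTree, matrix: PreferenceMatrix,
          targets: Sequence[str] | None = None,
          deltas: Sequence[float] = (-0.20, 0.20),
          mode: PerturbMode = "relative") -> list[SensitivityResult]:
    """Perturb each target by each delta and flag ranking changes.

    Default targets are every criterion plus both categories; default
    deltas are +/-20%, the conventional robustness band for MCDA weight
    sensitivity.
    """
    if targets is None:
        targets = list(tree.ids) + list(CATEGORY_TARGETS)
    baseline = rank_alternatives(score_cards(matrix, tree))
    base_order = [c.alternative for c in baseline.order]
    results = []
    for target in targets:
        for delta in deltas:
            ptree = perturb_weight(tree, target, delta, mode)
            cards = score_cards(matrix, ptree)
            ranking = rank_alternatives(cards)
            changed = [c.alternative for c in ranking.order] != base_order
            results.append(SensitivityResult(
                target=target, delta=delta, scorecards=tuple(cards),
                ranking=ranking, rank_changed=changed))
    return results


def crossover_weight(tree: ValueTree, matrix: PreferenceMatrix,
                     target: str) -> Crossover:
    """Weight of ``target`` at which two alternatives' totals are equal.

    For a criterion target the solved quantity is its *relative* (global)
    weight w, with all other criteria's relative weights scaled by
    (1 - w)/(1 - w0); for a category target it is the category weight
    itself. Returns ``Crossover(None)`` when the crossover lies outside
    [0, 1] or does not exist; identical alternatives give a degenerate
    result (tied at every weight).
    """
    alts = matrix.alternatives
    if len(alts) != 2:
        raise SensitivityError(
            f"crossover analysis supports exactly two alternatives, got {len(alts)}")
    a, b = alts
    pa, pb = matrix.row(a), matrix.row(b)

    if _is_category(target):
        cards = {alt: _category_pair(matrix.row(alt), tree) for alt in alts}
        d_ben = cards[a][0] - cards[b][0]
        d_risk = cards[a][1] - cards[b][1]
        # total_i(W) = W*B_i + (1-W)*R_i with W the target category weight
        if target == "risk":
            d_ben, d_risk = d_risk, d_ben
        denom = d_ben - d_risk
        if abs(denom) < 1e-12:
            if abs(d_risk) < 1e-12:
                return Crossover(None, degenerate=True)
            return Crossover(None)
        w = -d_risk / denom
        return Crossover(w if 0.0 <= w <= 1.0 else None)

    wv = normalize_weights(tree)
    w0 = wv[target]
    if w0 >= 1.0 - 1e-12:
        # single-criterion tree: totals equal the lone preference
        return Crossover(None, degenerate=abs(pa[target] - pb[target]) < 1e-12)
    dp = pa[target] - pb[target]
    t_a = sum(wv[c] * pa[c] for c in wv)
    t_b = sum(wv[c] * pb[c] for c in wv)
    d_t0 = t_a - t_b
    # total difference as a function of the target's global weight w:
    #   D(w) = w*dp + (1-w)/(1-w0) * (d_t0 - w0*dp)
    rest = (d_t0 - w0 * dp) / (1.0 - w0)
    denom = dp - rest
    if abs(denom) < 1e-12:
        if abs(rest) < 1e-12:
            return Crossover(None, degenerate=True)
        return Crossover(None)
    w = -rest / denom
    return Crossover(w if 0.0 <= w <= 1.0 else None)


def _category_pair(preferences: dict[str, float], tree: ValueTree) -> tuple[float, float]:
    from .aggregation import aggregate_category
    out = []
    for cat in (Category.BENEFIT, Category.RISK):
        members = tree.category_criteria(cat)
        if not members:
            out.append(0.0)
            continue
        out.append(aggregate_category(
            [preferences[c.id] for c in members],
            [c.swing_weight for c in members]))
    return out[0], out[1]
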