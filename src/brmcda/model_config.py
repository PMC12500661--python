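"""Value-tree configuration: criteria, swing weights, anchors, hierarchical weights.

The decision model is a two-level value tree: a *benefit* and a *risk*
category, each holding one or more leaf criteria. Category weights are
fractions summing to one; within a category each criterion carries a swing
weight on the 0-100 convention (the most important criterion in a category
gets 100, the rest are scaled against it). Each criterion also carries the
anchors of its partial value function: the *optimal* outcome value (mapped
to preference 100) and the *worst* (mapped to 0).

Hierarchical normalization turns swing weights into relative weights over
the whole tree::

    relative_j = category_weight_c * swing_j / sum(swing_k for k in c)

so the relative weights sum to one and are invariant to rescaling all
swings within a category by a common factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Category",
    "Direction",
    "Criterion",
    "ValueTree",
    "WeightVector",
    "ConfigError",
    "load_value_tree",
    "normalize_weights",
]

_WEIGHT_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a value-tree document violates the schema or an invariant."""


class Category(str, Enum):
    BENEFIT = "benefit"
    RISK = "risk"


class Direction(str, Enum):
    """Orientation of the raw outcome before anchoring.

    ``higher_is_better`` — larger raw values are clinically preferable
    (e.g. a performance-status improvement); ``lower_is_better`` — smaller
    raw values are preferable (e.g. an adverse-event incidence).
    """

    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


@dataclass(frozen=True)
class Criterion:
    """One leaf of the value tree.

    Parameters
    ----------
    id : str
        Short unique identifier used to join against evidence tables.
    label : str
        Human-readable display name.
    category : Category
        Whether the criterion counts as a benefit or a risk.
    swing_weight : float
        Swing weight in (0, 100]; ratio-scaled within the category.
    optimal : float
        Outcome value mapped to preference 100 (units of the outcome).
    worst : float
        Outcome value mapped to preference 0. Must differ from ``optimal``.
    direction : Direction
        Orientation of the raw outcome before anchoring.
    """

    id: str
    label: str
    category: Category
    swing_weight: float
    optimal: float
    worst: float
    direction: Direction

    def __post_init__(self) -> None:
        if not self.id:
            raise ConfigError("criterion id must be non-empty")
        if not (0 < self.swing_weight <= 100):
            raise ConfigError(
                f"criterion {self.id!r}: swing_weight {self.swing_weight} "
                "outside (0, 100]"
            )
        if self.optimal == self.worst:
            raise ConfigError(
                f"criterion {self.id!r}: optimal and worst anchors are equal "
                f"({self.optimal})"
            )


@dataclass(frozen=True)
class ValueTree:
    """Two-level benefit/risk value tree with top-level category weights."""

    benefit_weight: float
    risk_weight: float
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        for w, name in ((self.benefit_weight, "benefit_weight"),
                        (self.risk_weight, "risk_weight")):
            if not (0.0 <= w <= 1.0):
                raise ConfigError(f"{name} {w} outside [0, 1]")
        if abs(self.benefit_weight + self.risk_weight - 1.0) > _WEIGHT_TOL:
            raise ConfigError(
                "benefit_weight + risk_weight must equal 1, got "
                f"{self.benefit_weight} + {self.risk_weight}"
            )
        ids = [c.id for c in self.criteria]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ConfigError(f"duplicate criterion ids: {sorted(dupes)}")
        if not self.criteria:
            raise ConfigError("value tree has no criteria")
        for cat, w in ((Category.BENEFIT, self.benefit_weight),
                       (Category.RISK, self.risk_weight)):
            if w > _WEIGHT_TOL and not any(c.category == cat for c in self.criteria):
                raise ConfigError(
                    f"category {cat.value!r} has weight {w} but no criteria"
                )

    def category_criteria(self, category: Category | str) -> tuple[Criterion, ...]:
        category = Category(category)
        return tuple(c for c in self.criteria if c.category == category)

    def category_weight(self, category: Category | str) -> float:
        return (self.benefit_weight if Category(category) == Category.BENEFIT
                else self.risk_weight)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion relative weights over the whole tree; sums to one."""

    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError("relative weights must be non-negative")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigError(f"relative weights sum to {total}, expected 1")

    def __getitem__(self, criterion_id: str) -> float:
        return self.weights[criterion_id]

    def __iter__(self):
        return iter(self.weights)

    def items(self):
        return self.weights.items()


_KNOWN_TOP_KEYS = {"version", "benefit_weight", "risk_weight", "criteria"}
_KNOWN_CRIT_KEYS = {"id", "label", "category", "swing_weight", "optimal",
                    "worst", "direction"}
_REQUIRED_CRIT_KEYS = {"id", "category", "swing_weight", "optimal", "worst"}


def load_value_tree(source: str | Path | Mapping) -> ValueTree:
    """Load and validate a value tree from YAML/JSON text, a file, or a dict.

    The document must carry ``benefit_weight``, ``risk_weight`` and a
    ``criteria`` list; each criterion needs id, category, swing_weight and
    the two anchors. Unknown keys trigger a warning, never silent
    acceptance. Any invariant violation raises :class:`ConfigError` naming
    the offending entry.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError("value-tree document must be a mapping")

    unknown = set(doc) - _KNOWN_TOP_KEYS
    if unknown:
        warnings.warn(f"unknown top-level keys ignored: {sorted(unknown)}",
                      stacklevel=2)
    for key in ("benefit_weight", "risk_weight", "criteria"):
        if key not in doc:
            raise ConfigError(f"missing required field {key!r}")

    raw_criteria = doc["criteria"]
    if not isinstance(raw_criteria, Iterable) or isinstance(raw_criteria, (str, bytes)):
        raise ConfigError("'criteria' must be a list")

    criteria = []
    for i, entry in enumerate(raw_criteria):
        if not isinstance(entry, Mapping):
            raise ConfigError(f"criteria[{i}] is not a mapping")
        if "criteria" in entry or "children" in entry:
            raise ConfigError(
                f"criteria[{i}]: nested criteria are not supported; the tree "
                "has exactly two levels (category -> criterion)"
            )
        missing = _REQUIRED_CRIT_KEYS - set(entry)
        if missing:
            raise ConfigError(
                f"criteria[{i}] ({entry.get('id', '?')!r}): missing fields "
                f"{sorted(missing)}"
            )
        unknown = set(entry) - _KNOWN_CRIT_KEYS
        if unknown:
            warnings.warn(
                f"criteria[{i}] ({entry['id']!r}): unknown keys ignored: "
                f"{sorted(unknown)}", stacklevel=2)
        try:
            category = Category(entry["category"])
        except ValueError as exc:
            raise ConfigError(
                f"criteria[{i}] ({entry['id']!r}): invalid category "
                f"{entry['category']!r}"
            ) from exc
        direction = Direction(entry.get(
            "direction",
            Direction.HIGHER_IS_BETTER if category == Category.BENEFIT
            else Direction.LOWER_IS_BETTER,
        ))
        criteria.append(Criterion(
            id=str(entry["id"]),
            label=str(entry.get("label", entry["id"])),
            category=category,
            swing_weight=float(entry["swing_weight"]),
            optimal=float(entry["optimal"]),
            worst=float(entry["worst"]),
            direction=direction,
        ))

    return ValueTree(
        benefit_weight=float(doc["benefit_weight"]),
        risk_weight=float(doc["risk_weight"]),
        criteria=tuple(criteria),
    )


def normalize_weights(tree: ValueTree) -> WeightVector:
    """Hierarchically normalized relative weights.

    For criterion *j* in category *c*::

        relative_j = category_weight_c * swing_j / sum(swing_k, k in c)

    The result sums to one over the whole tree.
    """
    weights: dict[str, float] = {}
    for cat in (Category.BENEFIT, Category.RISK):
        members = tree.category_criteria(cat)
        cat_w = tree.category_weight(cat)
        if not members:
            continue
        total_swing = sum(c.swing_weight for c in members)
        if total_swing <= 0:
            raise ConfigError(
                f"category {cat.value!r} has zero total swing weight"
            )
        for c in members:
            weights[c.id] = cat_w * c.swing_weight / total_swing
    return WeightVector(weights)
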