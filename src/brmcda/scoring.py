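"""Linear partial value functions mapping pooled outcomes to 0-100 preferences.

Each criterion's single-attribute value function is linear between its two
anchors. For a benefit criterion the optimal anchor U_max maps to 100 and
the worst anchor U_min to 0::

    U_benefit = (U - U_min) / (U_max - U_min) * 100

For a risk criterion the scale is reversed — a *low* raw value (little
risk) earns a *high* preference::

    U_risk = (U_max - U) / (U_max - U_min) * 100

Values outside the anchored range are clamped to the boundary (preference
0 or 100) with a warning, since the function is defined only between the
anchors.

Some continuous outcomes are reported as signed changes whose sign is a
bookkeeping convention of the contrast rather than a direction of effect
(a change of -9.38 against positive anchors means a 9.38-point shift).
The default ``auto`` orientation policy takes the magnitude of the pooled
value whenever its sign is opposite to the anchor range; ``signed`` and
``magnitude`` force either behaviour.

All partial-value functions accept scalars or numpy arrays, so the Monte
Carlo layer can push whole sample vectors through the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_config import Criterion, ValueTree
from .evidence_pooling import PooledEstimate

__all__ = [
    "ScoringError",
    "partial_value_benefit",
    "partial_value_risk",
    "orient",
    "preference_value",
    "score_alternative",
    "score_alternatives",
    "PreferenceMatrix",
]

OrientationPolicy = Literal["auto", "signed", "magnitude"]


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PreferenceMatrix:
    """Alternatives x criteria preference scores on the 0-100 scale.

    ``values`` is a DataFrame indexed by alternative with one column per
    criterion id. ``provenance`` records whether the scores were computed
    by the partial value functions or asserted from an external source.
    """

    values: pd.DataFrame
    provenance: str = "computed"  # "computed" | "asserted"

    def __post_init__(self) -> None:
        if self.provenance not in ("computed", "asserted"):
            raise ScoringError(f"invalid provenance {self.provenance!r}")
        v = self.values.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ScoringError("preference matrix is incomplete")
        if (v < -1e-9).any() or (v > 100 + 1e-9).any():
            raise ScoringError("preferences must lie in [0, 100]")

    @property
    def alternatives(self) -> list[str]:
        return list(self.values.index)

    def row(self, alternative: str) -> dict[str, float]:
        return self.values.loc[alternative].to_dict()


def _check_anchors(u_min: float, u_max: float) -> None:
    if u_max == u_min:
        raise ScoringError(f"degenerate anchors: u_min == u_max == {u_min}")
    if u_max < u_min:
        raise ScoringError(f"anchors reversed: u_min={u_min} > u_max={u_max}")


def _clamp(u, u_min: float, u_max: float, label: str = "", warn: bool = True):
    below = np.any(np.asarray(u) < u_min)
    above = np.any(np.asarray(u) > u_max)
    if (below or above) and warn:
        warnings.warn(
            f"value(s) outside anchor range [{u_min}, {u_max}]"
            + (f" for {label}" if label else "") + "; clamped",
            stacklevel=3)
    return np.clip(u, u_min, u_max)


def partial_value_benefit(u, u_min: float, u_max: float, *, clamp: bool = True):
    """Linear benefit value: (u - u_min)/(u_max - u_min) * 100.

    Accepts scalars or arrays; out-of-range inputs are clamped to the
    anchors (with a warning) unless ``clamp=False``.
    """
    _check_anchors(u_min, u_max)
    if clamp:
        u = _clamp(u, u_min, u_max)
    out = (np.asarray(u, dtype=float) - u_min) / (u_max - u_min) * 100.0
    return float(out) if out.ndim == 0 else out


def partial_value_risk(u, u_min: float, u_max: float, *, clamp: bool = True):
    """Linear risk value: (u_max - u)/(u_max - u_min) * 100.

    The best case (u = u_min, minimal risk) scores 100; the worst
    (u = u_max) scores 0.
    """
    _check_anchors(u_min, u_max)
    if clamp:
        u = _clamp(u, u_min, u_max)
    out = (u_max - np.asarray(u, dtype=float)) / (u_max - u_min) * 100.0
    return float(out) if out.ndim == 0 else out


def orient(u, criterion: Criterion, policy: OrientationPolicy = "auto"):
    """Resolve the sign convention of a raw pooled value before anchoring.

    ``auto`` takes the magnitude when the anchor range and the value have
    opposite signs (both anchors >= 0 with a negative value, or both <= 0
    with a positive value); ``signed`` passes the value through;
    ``magnitude`` always takes the absolute value.
    """
    u = np.asarray(u, dtype=float)
    if policy == "signed":
        out = u
    elif policy == "magnitude":
        out = np.abs(u)
    elif policy == "auto":
        lo, hi = sorted((criterion.worst, criterion.optimal))
        if lo >= 0:
            out = np.where(u < 0, -u, u)
        elif hi <= 0:
            out = np.where(u > 0, -u, u)
        else:
            out = u
    else:
        raise ScoringError(f"unknown orientation policy {policy!r}")
    return float(out) if out.ndim == 0 else out


def preference_value(u, criterion: Criterion,
                     policy: OrientationPolicy = "auto", *,
                     clamp: bool = True, warn: bool = True):
    """Preference score of raw value(s) ``u`` on one criterion.

    Applies the orientation policy, then the linear value function that
    maps the worst anchor to 0 and the optimal anchor to 100. When the
    optimal anchor is the upper end this is the increasing benefit form;
    when it is the lower end (typical for risk criteria such as an
    adverse-event incidence) it is the decreasing risk form.
    """
    u = orient(u, criterion, policy)
    lo, hi = sorted((criterion.worst, criterion.optimal))
    if clamp:
        u = _clamp(u, lo, hi, label=criterion.id, warn=warn)
    if criterion.optimal > criterion.worst:
        return partial_value_benefit(u, criterion.worst, criterion.optimal,
                                     clamp=False)
    return partial_value_risk(u, criterion.optimal, criterion.worst,
                              clamp=False)


def score_alternative(pooled: Sequence[PooledEstimate] | Mapping[str, float],
                      tree: ValueTree,
                      policy: OrientationPolicy = "auto") -> dict[str, float]:
    """Preference row for one alternative: one score per tree criterion.

    ``pooled`` is either a list of pooled estimates or a plain mapping of
    criterion id to raw value. A criterion without evidence raises.
    """
    if isinstance(pooled, Mapping):
        raw = dict(pooled)
    else:
        raw = {p.criterion_id: p.estimate for p in pooled}
    row = {}
    for crit in tree.criteria:
        if crit.id not in raw:
            raise ScoringError(f"no pooled estimate for criterion {crit.id!r}")
        row[crit.id] = float(preference_value(raw[crit.id], crit, policy))
    return row


def score_alternatives(pooled: Sequence[PooledEstimate], tree: ValueTree,
                       policy: OrientationPolicy = "auto") -> PreferenceMatrix:
    """Full preference matrix from pooled estimates for every arm present."""
    arms: dict[str, list[PooledEstimate]] = {}
    for p in pooled:
        arms.setdefault(p.arm, []).append(p)
    rows = {arm: score_alternative(ests, tree, policy)
            for arm, ests in arms.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(tree.ids)]
    return PreferenceMatrix(values=df, provenance="computed")
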