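"""Monte Carlo propagation of effect-estimate uncertainty through the model.

Each pooled effect is represented by a triangular distribution whose
minimum and maximum are the 95% CI bounds and whose mode is the point
estimate — the standard way to turn a point-estimate-plus-interval into
a samplable distribution when nothing more is known about its shape.
Every (arm, criterion) effect is sampled independently; each iteration
scores both arms with the partial value functions (inheriting the
clamping policy of the scoring layer), aggregates to benefit, risk and
total values, and records the experimental-minus-control differences.

Outputs are equal-tailed percentile intervals on the three difference
distributions and the probability of superiority — the fraction of
iterations in which the experimental total exceeds the control total.
A single seeded generator drives all sampling, so a run is reproducible
bit-for-bit from (model, n_iter, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model_config import ValueTree
from .evidence_pooling import PooledEstimate
from .scoring import OrientationPolicy, PreferenceMatrix, preference_value
from .aggregation import score_card

__all__ = [
    "UncertaintyError",
    "TriangularSpec",
    "MCResult",
    "sample_triangular",
    "specs_from_pooled",
    "run_mc",
    "summarize_mc",
]

DEFAULT_N_ITER = 10_000


class UncertaintyError(ValueError):
    pass


@dataclass(frozen=True)
class TriangularSpec:
    """Triangular(low, mode, high) distribution for one arm x criterion effect."""

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mode <= self.high):
            raise UncertaintyError(
                f"invalid triangular spec: need low <= mode <= high, got "
                f"({self.low}, {self.mode}, {self.high})")

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0


def sample_triangular(spec: TriangularSpec, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. samples by inverse-CDF transform of uniforms.

    Handles the degenerate cases (mode at an endpoint, or a point mass
    when low == high) exactly.
    """
    if n < 1:
        raise UncertaintyError("n must be >= 1")
    lo, m, hi = spec.low, spec.mode, spec.high
    width = hi - lo
    if width == 0:
        return np.full(n, m, dtype=float)
    u = rng.random(n)
    f_mode = (m - lo) / width
    left = u < f_mode
    out = np.empty(n, dtype=float)
    if m > lo:
        out[left] = lo + np.sqrt(u[left] * width * (m - lo))
    else:
        out[left] = lo  # no mass to the left of the mode
    if hi > m:
        out[~left] = hi - np.sqrt((1.0 - u[~left]) * width * (hi - m))
    else:
        out[~left] = hi
    return out


def specs_from_pooled(pooled: Sequence[PooledEstimate]
                      ) -> dict[tuple[str, str], TriangularSpec]:
    """Map each pooled estimate to its triangular spec keyed by (arm, criterion)."""
    return {(p.arm, p.criterion_id): TriangularSpec(p.ci_low, p.estimate, p.ci_high)
            for p in pooled}


@dataclass(frozen=True)
class MCResult:
    """Sampled difference distributions (experimental - control) and summaries."""

    n_iter: int
    seed: int
    benefit_diff: np.ndarray = field(repr=False)
    risk_diff: np.ndarray = field(repr=False)
    total_diff: np.ndarray = field(repr=False)
    p_superiority: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_superiority <= 1.0):
            raise UncertaintyError("p_superiority outside [0, 1]")


def run_mc(tree: ValueTree,
           specs: Mapping[tuple[str, str], TriangularSpec],
           n_iter: int = DEFAULT_N_ITER,
           seed: int = 0,
           policy: OrientationPolicy = "auto",
           arms: tuple[str, str] = ("experimental", "control"),
           preference_override: PreferenceMatrix | None = None) -> MCResult:
    """Propagate triangular effect uncertainty to score differences.

    ``specs`` must hold one triangular spec per (arm, criterion) pair.
    Each iteration samples all effects independently, converts them to
    preferences (values falling outside the anchor range are clamped at
    scoring time, not truncated in the distribution), aggregates both
    arms, and records benefit/risk/total differences between the two
    arms in ``arms`` order. ``preference_override`` pins the named cells
    to fixed preference values instead of computing them from samples —
    useful for replaying an externally asserted preference table through
    the aggregation stage.

    p_superiority is the fraction of iterations with total difference > 0.
    """
    rng = np.random.default_rng(seed)
    for arm in arms:
        for crit in tree.criteria:
            if (arm, crit.id) not in specs:
                raise UncertaintyError(f"missing spec for ({arm}, {crit.id})")

    # sample per (arm, criterion) then score vectorized; ordering of rng
    # draws is fixed by (arms x tree order) so runs are seed-deterministic
    pref_samples: dict[str, dict[str, np.ndarray]] = {}
    for arm in arms:
        cols = {}
        for crit in tree.criteria:
            if (preference_override is not None
                    and arm in preference_override.values.index
                    and crit.id in preference_override.values.columns):
                cols[crit.id] = np.full(
                    n_iter, float(preference_override.values.loc[arm, crit.id]))
                continue
            draws = sample_triangular(specs[(arm, crit.id)], n_iter, rng)
            cols[crit.id] = np.asarray(
                preference_value(draws, crit, policy, warn=False), dtype=float)
        pref_samples[arm] = cols

    cards = {}
    for arm in arms:
        # score_card works elementwise because aggregation is linear
        cards[arm] = score_card(pref_samples[arm], tree, alternative=arm)
    exp, ctl = cards[arms[0]], cards[arms[1]]
    benefit_diff = np.asarray(exp.benefit_value - ctl.benefit_value, dtype=float)
    risk_diff = np.asarray(exp.risk_value - ctl.risk_value, dtype=float)
    total_diff = np.asarray(exp.total_value - ctl.total_value, dtype=float)
    p_sup = float(np.mean(total_diff > 0))
    return MCResult(n_iter=n_iter, seed=seed, benefit_diff=benefit_diff,
                    risk_diff=risk_diff, total_diff=total_diff,
                    p_superiority=p_sup)


def summarize_mc(result: MCResult) -> pd.DataFrame:
    """Mean and equal-tailed 95% percentile interval per difference quantity.

    Returns one row per quantity (benefit, risk, total) plus the
    probability of superiority as a percentage rounded to two decimals.
    """
    if result.n_iter < 2:
        raise UncertaintyError("need n_iter >= 2 to summarize")
    rows = []
    for name, arr in (("benefit_difference", result.benefit_diff),
                      ("risk_difference", result.risk_diff),
                      ("total_difference", result.total_diff)):
        rows.append({
            "quantity": name,
            "mean": float(np.mean(arr)),
            "ci_low": float(np.quantile(arr, 0.025)),
            "ci_high": float(np.quantile(arr, 0.975)),
        })
    rows.append({
        "quantity": "p_superiority_percent",
        "mean": round(result.p_superiority * 100.0, 2),
        "ci_low": np.nan,
        "ci_high": np.nan,
    })
    return pd.DataFrame(rows)
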