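"""Per-arm inverse-variance pooling of trial summaries with heterogeneity.

Evidence arrives as arm-level summaries: for continuous outcomes the
per-arm sample size, mean change and SD; for binary outcomes events out of
n. Each (criterion, arm) cell is pooled separately — the model scores the
two treatment arms as alternatives, so the evidence layer produces one
pooled estimate per arm rather than a between-arm contrast.

Continuous outcomes are pooled by inverse variance with study variance
sd^2/n; binary outcomes on the raw proportion scale with variance
p(1-p)/n. Between-study variance tau^2 uses the DerSimonian-Laird moment
estimator; the default model policy is fixed effect when I^2 <= 50% and
random effects otherwise, overridable per call. Confidence intervals are
normal-approximation at the 95% level (z = 1.959964).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmSummary",
    "PooledEstimate",
    "Heterogeneity",
    "PoolingError",
    "heterogeneity",
    "pool_continuous",
    "pool_binary",
    "pool_all",
    "load_arm_summaries",
    "arm_summaries_to_frame",
]

Z_95 = 1.959964
I2_RANDOM_THRESHOLD = 50.0

ModelRule = Literal["auto", "fixed", "random"]


class PoolingError(ValueError):
    """Raised on invalid or inconsistent evidence records."""


@dataclass(frozen=True)
class ArmSummary:
    """One study x arm x outcome evidence record.

    Continuous records carry ``mean`` and ``sd`` (of the change score);
    binary records carry ``events``. Exactly the fields for the record's
    kind must be present.
    """

    study_id: str
    arm: str  # "experimental" | "control"
    criterion_id: str
    kind: str  # "continuous" | "binary"
    n: int
    mean: float | None = None
    sd: float | None = None
    events: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("experimental", "control"):
            raise PoolingError(
                f"{self.study_id}: arm must be 'experimental' or 'control', "
                f"got {self.arm!r}")
        if self.n < 1:
            raise PoolingError(f"{self.study_id}: n must be positive")
        if self.kind == "continuous":
            if self.mean is None or self.sd is None or self.events is not None:
                raise PoolingError(
                    f"{self.study_id}/{self.criterion_id}: continuous record "
                    "needs mean and sd, and no events")
            if self.sd <= 0:
                raise PoolingError(
                    f"{self.study_id}/{self.criterion_id}: sd must be > 0")
            if self.n < 2:
                raise PoolingError(
                    f"{self.study_id}/{self.criterion_id}: continuous record "
                    "needs n >= 2")
        elif self.kind == "binary":
            if self.events is None or self.mean is not None or self.sd is not None:
                raise PoolingError(
                    f"{self.study_id}/{self.criterion_id}: binary record "
                    "needs events, and no mean/sd")
            if not (0 <= self.events <= self.n):
                raise PoolingError(
                    f"{self.study_id}/{self.criterion_id}: events "
                    f"{self.events} outside [0, n={self.n}]")
        else:
            raise PoolingError(
                f"{self.study_id}/{self.criterion_id}: unknown kind "
                f"{self.kind!r}")


@dataclass(frozen=True)
class PooledEstimate:
    """Pooled point estimate with 95% CI and heterogeneity for one arm x criterion."""

    criterion_id: str
    arm: str
    estimate: float
    ci_low: float
    ci_high: float
    k: int
    Q: float
    I2: float
    tau2: float
    model: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate + 1e-12
                and self.estimate <= self.ci_high + 1e-12):
            raise PoolingError(
                f"{self.criterion_id}/{self.arm}: CI ({self.ci_low}, "
                f"{self.ci_high}) does not bracket estimate {self.estimate}")


class Heterogeneity(NamedTuple):
    Q: float
    I2: float
    tau2: float


def _check_homogeneous(summaries: Sequence[ArmSummary], kind: str) -> None:
    if not summaries:
        raise PoolingError("no summaries to pool")
    crit = {s.criterion_id for s in summaries}
    arms = {s.arm for s in summaries}
    if len(crit) > 1 or len(arms) > 1:
        raise PoolingError(
            f"mixed criteria/arms in one pool: criteria={sorted(crit)}, "
            f"arms={sorted(arms)}")
    if any(s.kind != kind for s in summaries):
        raise PoolingError(f"expected only {kind} records")


def _het_from_moments(y: np.ndarray, v: np.ndarray) -> Heterogeneity:
    """Cochran's Q, I^2 and DerSimonian-Laird tau^2 from study estimates/variances."""
    k = len(y)
    if k < 2:
        return Heterogeneity(0.0, 0.0, 0.0)
    w = 1.0 / v
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return Heterogeneity(q, i2, tau2)


def _continuous_moments(summaries: Sequence[ArmSummary]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.mean for s in summaries], dtype=float)
    v = np.array([s.sd**2 / s.n for s in summaries], dtype=float)
    if np.any(v <= 0):
        raise PoolingError("zero within-study variance")
    return y, v


def _binary_moments(summaries: Sequence[ArmSummary]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.events / s.n for s in summaries], dtype=float)
    # 0.5-corrected proportion for the variance only, so boundary studies
    # (0 or n events) keep a finite weight without moving the estimate
    p_var = np.array([(s.events + 0.5) / (s.n + 1.0) for s in summaries])
    v = p_var * (1.0 - p_var) / np.array([s.n for s in summaries], dtype=float)
    return y, v


def heterogeneity(summaries: Sequence[ArmSummary]) -> Heterogeneity:
    """Cochran's Q, I^2 (%) and DerSimonian-Laird tau^2 for one arm x criterion.

    A single study returns (0, 0, 0) by convention.
    """
    kind = summaries[0].kind if summaries else "continuous"
    _check_homogeneous(summaries, kind)
    moments = _continuous_moments if kind == "continuous" else _binary_moments
    return _het_from_moments(*moments(summaries))


def _wilson_interval(events: int, n: int) -> tuple[float, float]:
    p = events / n
    z2 = Z_95**2
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = Z_95 * math.sqrt(p * (1 - p) / n + z2 / (4 * n**2)) / denom
    return center - half, center + half


def _pool(y: np.ndarray, v: np.ndarray, model_rule: ModelRule) -> tuple[float, float, Heterogeneity, str]:
    het = _het_from_moments(y, v)
    if model_rule == "auto":
        model = "random" if het.I2 > I2_RANDOM_THRESHOLD else "fixed"
    elif model_rule in ("fixed", "random"):
        model = model_rule
    else:
        raise PoolingError(f"unknown model rule {model_rule!r}")
    tau2 = het.tau2 if model == "random" else 0.0
    w = 1.0 / (v + tau2)
    est = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return est, se, het, model


def pool_continuous(summaries: Sequence[ArmSummary],
                    model_rule: ModelRule = "auto") -> PooledEstimate:
    """Inverse-variance pooled mean change for one arm x criterion.

    Weights are 1/(sd^2/n + tau^2); tau^2 is zero for the fixed-effect
    model and the DerSimonian-Laird estimate for random effects. With the
    default ``auto`` rule, random effects kicks in when I^2 > 50%.
    """
    _check_homogeneous(summaries, "continuous")
    y, v = _continuous_moments(summaries)
    est, se, het, model = _pool(y, v, model_rule)
    return PooledEstimate(
        criterion_id=summaries[0].criterion_id, arm=summaries[0].arm,
        estimate=est, ci_low=est - Z_95 * se, ci_high=est + Z_95 * se,
        k=len(summaries), Q=het.Q, I2=het.I2, tau2=het.tau2, model=model)


def pool_binary(summaries: Sequence[ArmSummary],
                model_rule: ModelRule = "auto") -> PooledEstimate:
    """Pooled incidence (proportion) for one arm x criterion.

    Inverse-variance pooling on the raw proportion scale; a single study
    gets a Wilson score interval instead of the normal approximation.
    The estimate and CI are clipped to [0, 1].
    """
    _check_homogeneous(summaries, "binary")
    s0 = summaries[0]
    if len(summaries) == 1:
        est = s0.events / s0.n
        lo, hi = _wilson_interval(s0.events, s0.n)
        return PooledEstimate(
            criterion_id=s0.criterion_id, arm=s0.arm, estimate=est,
            ci_low=max(0.0, lo), ci_high=min(1.0, hi),
            k=1, Q=0.0, I2=0.0, tau2=0.0, model="fixed")
    y, v = _binary_moments(summaries)
    est, se, het, model = _pool(y, v, model_rule)
    est = min(1.0, max(0.0, est))
    return PooledEstimate(
        criterion_id=s0.criterion_id, arm=s0.arm, estimate=est,
        ci_low=max(0.0, est - Z_95 * se), ci_high=min(1.0, est + Z_95 * se),
        k=len(summaries), Q=het.Q, I2=het.I2, tau2=het.tau2, model=model)


def pool_all(summaries: Sequence[ArmSummary],
             model_rule: ModelRule = "auto") -> list[PooledEstimate]:
    """Pool every (criterion, arm) group found in a mixed summary table."""
    groups: dict[tuple[str, str], list[ArmSummary]] = {}
    for s in summaries:
        groups.setdefault((s.criterion_id, s.arm), []).append(s)
    pooled = []
    for (_, _), group in sorted(groups.items()):
        fn = pool_continuous if group[0].kind == "continuous" else pool_binary
        pooled.append(fn(group, model_rule))
    return pooled


_CSV_COLUMNS = ["study_id", "arm", "criterion_id", "kind", "n", "mean", "sd", "events"]


def load_arm_summaries(path: str | Path) -> list[ArmSummary]:
    """Read a trial-summary CSV (columns study_id, arm, criterion_id, kind,
    n, mean, sd, events) into validated records."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise PoolingError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(ArmSummary(
                study_id=str(row["study_id"]),
                arm=str(row["arm"]),
                criterion_id=str(row["criterion_id"]),
                kind=str(row["kind"]),
                n=int(row["n"]),
                mean=None if pd.isna(row.get("mean")) else float(row["mean"]),
                sd=None if pd.isna(row.get("sd")) else float(row["sd"]),
                events=None if pd.isna(row.get("events")) else int(row["events"]),
            ))
        except (PoolingError, ValueError) as exc:
            raise PoolingError(f"{path} row {i + 2}: {exc}") from exc
    return out


def arm_summaries_to_frame(summaries: Sequence[ArmSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame in the trial-summary CSV column order."""
    return pd.DataFrame(
        [{c: getattr(s, c) for c in _CSV_COLUMNS} for s in summaries],
        columns=_CSV_COLUMNS)
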