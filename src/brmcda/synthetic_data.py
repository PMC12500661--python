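"""Synthetic two-arm RCT evidence with the structure the pipeline assumes.

The generator emulates a small evidence base of two-arm trials reporting
a mix of continuous change scores and binary adverse-event counts, with
configurable true effects, between-study heterogeneity, arm sizes and
per-study outcome availability (real trial sets rarely report every
outcome in every study). It exists so pooling, scoring, aggregation,
sensitivity and Monte Carlo can all be exercised end to end without any
external data.

The packaged reference model — ``nsclc_case_study()`` — is the published
benefit-risk evaluation of adjunctive herbal therapy added to
platinum-based chemotherapy for non-small cell lung cancer: a five-
criterion value tree (KPS change, CA211, CEA, Cancer Fatigue Scale change
as benefits; gastrointestinal adverse-reaction incidence as the risk),
per-arm pooled estimates with 95% CIs from six small RCTs, and the
preference table reported alongside them. ``default_scenario()`` is
calibrated so the generator's true effects equal that case study's
pooled point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model_config import ValueTree, load_value_tree
from .evidence_pooling import ArmSummary, PooledEstimate
from .scoring import PreferenceMatrix

__all__ = [
    "ContinuousEffect",
    "BinaryEffect",
    "TrialScenario",
    "generate_trials",
    "default_scenario",
    "CaseStudy",
    "nsclc_case_study",
]

_ARMS = ("experimental", "control")


@dataclass(frozen=True)
class ContinuousEffect:
    """True per-arm mean change and shared within-arm SD for one criterion."""

    experimental: float
    control: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("within-arm sd must be positive")


@dataclass(frozen=True)
class BinaryEffect:
    """True per-arm event rates for one criterion."""

    experimental: float
    control: float

    def __post_init__(self) -> None:
        for r in (self.experimental, self.control):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass(frozen=True)
class TrialScenario:
    """Generating conditions for a synthetic evidence base.

    Parameters
    ----------
    n_studies : int
        Number of two-arm trials.
    continuous : mapping criterion id -> ContinuousEffect
    binary : mapping criterion id -> BinaryEffect
    tau : float
        Between-study SD of the true mean change (continuous criteria),
        in outcome units.
    tau_binary : float
        Between-study SD of the true event rate on the probability scale.
    arm_sizes : sequence of (n_experimental, n_control)
        Per-study arm sizes; cycled if shorter than ``n_studies``.
    masks : sequence of criterion-id sets or None
        Outcomes reported by each study (None = all studies report all).
    seed : int
    """

    n_studies: int
    continuous: Mapping[str, ContinuousEffect] = field(default_factory=dict)
    binary: Mapping[str, BinaryEffect] = field(default_factory=dict)
    tau: float = 0.0
    tau_binary: float = 0.0
    arm_sizes: Sequence[tuple[int, int]] = ((30, 30),)
    masks: Sequence[frozenset[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if self.tau < 0 or self.tau_binary < 0:
            raise ValueError("between-study sds must be non-negative")
        for ne, nc in self.arm_sizes:
            if ne < 2 or nc < 2:
                raise ValueError("arm sizes must be >= 2")
        if self.masks is not None and len(self.masks) < self.n_studies:
            raise ValueError("masks must cover every study")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(self.continuous) + tuple(self.binary)


def generate_trials(scenario: TrialScenario) -> list[ArmSummary]:
    """Simulate an arm-level summary table under the scenario.

    For each study and continuous criterion, the study-level true mean is
    drawn Normal(true effect, tau^2); the reported per-arm mean and SD
    are the sample moments of n Normal(study mean, sd^2) draws. Binary
    criteria report Binomial(n, study rate) events with the study rate
    drawn Normal(true rate, tau_binary^2) clipped to [0, 1]. Studies only
    emit records for the criteria in their mask.
    """
    rng = np.random.default_rng(scenario.seed)
    out: list[ArmSummary] = []
    for i in range(scenario.n_studies):
        study_id = f"study_{i + 1:02d}"
        n_by_arm = dict(zip(_ARMS, scenario.arm_sizes[i % len(scenario.arm_sizes)]))
        reported = (scenario.masks[i] if scenario.masks is not None
                    else frozenset(scenario.criterion_ids))
        for cid, eff in scenario.continuous.items():
            for arm in _ARMS:
                true_mean = getattr(eff, arm)
                study_mean = rng.normal(true_mean, scenario.tau)
                n = n_by_arm[arm]
                draws = rng.normal(study_mean, eff.sd, size=n)
                if cid not in reported:
                    continue  # draws still consumed: masking never shifts the stream
                out.append(ArmSummary(
                    study_id=study_id, arm=arm, criterion_id=cid,
                    kind="continuous", n=n,
                    mean=float(np.mean(draws)),
                    sd=float(max(np.std(draws, ddof=1), 1e-9))))
        for cid, eff in scenario.binary.items():
            for arm in _ARMS:
                rate = float(np.clip(
                    rng.normal(getattr(eff, arm), scenario.tau_binary), 0.0, 1.0))
                n = n_by_arm[arm]
                events = int(rng.binomial(n, rate))
                if cid not in reported:
                    continue
                out.append(ArmSummary(
                    study_id=study_id, arm=arm, criterion_id=cid,
                    kind="binary", n=n, events=events))
    return out


# Table-3-style reporting pattern of the reference evidence base: six
# trials, four reporting the performance-status outcome, two reporting
# the tumor markers + adverse reactions, two reporting the fatigue scale.
_DEFAULT_MASKS = (
    frozenset({"fatigue"}),
    frozenset({"kps", "ca211", "cea", "gi_adverse"}),
    frozenset({"kps", "ca211", "cea", "gi_adverse"}),
    frozenset({"kps"}),
    frozenset({"fatigue"}),
    frozenset({"kps"}),
)
_DEFAULT_ARM_SIZES = ((45, 45), (29, 28), (30, 30), (20, 20), (30, 30), (24, 24))


def default_scenario(seed: int = 0, tau: float = 0.5,
                     masked: bool = True) -> TrialScenario:
    """Scenario calibrated to the reference case study's pooled estimates.

    True mean changes (and event rates) equal the case study's per-arm
    pooled point estimates; within-arm SDs are back-calculated from the
    reported CI widths and study sizes; arm sizes and the outcome-
    reporting pattern follow the six source trials. ``tau`` adds mild
    between-study heterogeneity in outcome units (0.5 by default).
    """
    return TrialScenario(
        n_studies=6,
        continuous={
            "kps": ContinuousEffect(-9.38, -3.63, sd=8.0),
            "ca211": ContinuousEffect(4.98, 3.89, sd=2.9),
            "cea": ContinuousEffect(9.96, 7.58, sd=5.0),
            "fatigue": ContinuousEffect(14.58, 3.70, sd=15.0),
        },
        binary={"gi_adverse": BinaryEffect(0.44, 0.76)},
        tau=tau,
        tau_binary=0.02,
        arm_sizes=_DEFAULT_ARM_SIZES,
        masks=_DEFAULT_MASKS if masked else None,
        seed=seed,
    )


class CaseStudy(NamedTuple):
    """Reference model: value tree, per-arm pooled estimates, and the
    preference table asserted by the source evaluation."""

    tree: ValueTree
    pooled: list[PooledEstimate]
    asserted_preferences: PreferenceMatrix


def _data_path(name: str):
    return resources.files("brmcda.data").joinpath(name)


def nsclc_case_study() -> CaseStudy:
    """Load the packaged NSCLC combination-therapy benefit-risk model.

    Returns the five-criterion value tree (top-level weights 0.75/0.25),
    the ten per-arm pooled estimates with their 95% CIs, and the
    preference matrix as asserted in the source evaluation (provenance
    ``asserted`` — some of its cells are not recovered by the partial
    value functions; see the reproduction report).
    """
    tree = load_value_tree(_data_path("value_tree_nsclc.yaml").read_text())
    est = pd.read_csv(_data_path("pooled_estimates_nsclc.csv"))
    pooled = [
        PooledEstimate(
            criterion_id=r.criterion_id, arm=r.arm, estimate=r.estimate,
            ci_low=r.ci_low, ci_high=r.ci_high, k=int(r.k),
            Q=0.0, I2=0.0, tau2=0.0, model="reported")
        for r in est.itertuples()
    ]
    prefs = pd.read_csv(_data_path("preferences_nsclc.csv"), index_col=0)
    return CaseStudy(
        tree=tree, pooled=pooled,
        asserted_preferences=PreferenceMatrix(values=prefs.astype(float),
                                              provenance="asserted"))
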