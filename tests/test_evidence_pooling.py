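import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brmcda.evidence_pooling import (ArmSummary, PoolingError, Z_95,
                                     heterogeneity, pool_binary,
                                     pool_continuous)


def cont(study, mean, sd, n, criterion="kps", arm="experimental"):
    return ArmSummary(study_id=study, arm=arm, criterion_id=criterion,
                      kind="continuous", n=n, mean=mean, sd=sd)


def binry(study, events, n, criterion="gi", arm="experimental"):
    return ArmSummary(study_id=study, arm=arm, criterion_id=criterion,
                      kind="binary", n=n, events=events)


class TestArmSummaryValidation:
    @pytest.mark.parametrize("kwargs, match", [
        (dict(kind="binary", n=10, events=12), "outside"),
        (dict(kind="continuous", n=10, mean=1.0, sd=0.0), "sd must be"),
        (dict(kind="continuous", n=1, mean=1.0, sd=1.0), "n >= 2"),
        (dict(kind="continuous", n=10, mean=1.0, sd=1.0, events=3), "no events"),
        (dict(kind="binary", n=10), "needs events"),
        (dict(kind="poisson", n=10, events=3), "unknown kind"),
    ])
    def test_invalid_records(self, kwargs, match):
        with pytest.raises(PoolingError, match=match):
            ArmSummary(study_id="s", arm="experimental", criterion_id="c",
                       **kwargs)


class TestContinuousPooling:
    def test_single_study_identity(self):
        p = pool_continuous([cont("s1", 9.4, 4.0, 30)])
        assert p.estimate == pytest.approx(9.4)
        half = Z_95 * 4.0 / math.sqrt(30)
        assert p.ci_low == pytest.approx(9.4 - half)
        assert p.ci_high == pytest.approx(9.4 + half)
        assert (p.Q, p.I2, p.tau2) == (0.0, 0.0, 0.0)

    def test_two_identical_studies_narrow_ci_by_sqrt2(self):
        one = pool_continuous([cont("s1", 5.0, 2.0, 40)])
        two = pool_continuous([cont("s1", 5.0, 2.0, 40),
                               cont("s2", 5.0, 2.0, 40)], model_rule="fixed")
        assert two.estimate == pytest.approx(one.estimate)
        assert (two.ci_high - two.ci_low) == pytest.approx(
            (one.ci_high - one.ci_low) / math.sqrt(2))

    def test_inverse_variance_mean_against_hand_arithmetic(self):
        # oracle: explicit inverse-variance arithmetic on two studies
        w1, w2 = 30 / 4.0**2, 60 / 4.0**2
        expected = (w1 * 10 + w2 * 8) / (w1 + w2)
        expected_se = 1 / math.sqrt(w1 + w2)
        p = pool_continuous([cont("s1", 10, 4.0, 30), cont("s2", 8, 4.0, 60)],
                            model_rule="fixed")
        assert p.estimate == pytest.approx(expected)
        assert p.ci_high - p.estimate == pytest.approx(Z_95 * expected_se)

    def test_mixed_criteria_rejected(self):
        with pytest.raises(PoolingError, match="mixed"):
            pool_continuous([cont("s1", 1, 1, 10, criterion="a"),
                             cont("s2", 1, 1, 10, criterion="b")])

    def test_agrees_with_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects
        y = np.array([10.0, 8.0, 12.5])
        sd = np.array([4.0, 3.0, 5.0])
        n = np.array([30, 60, 25])
        v = sd**2 / n
        res = combine_effects(y, v, method_re="dl")
        summaries = [cont(f"s{i}", y[i], sd[i], int(n[i])) for i in range(3)]
        fixed = pool_continuous(summaries, model_rule="fixed")
        random = pool_continuous(summaries, model_rule="random")
        frame = res.summary_frame()
        assert fixed.estimate == pytest.approx(
            frame.loc["fixed effect", "eff"])
        assert random.estimate == pytest.approx(
            frame.loc["random effect", "eff"])
        assert random.tau2 == pytest.approx(res.tau2)


class TestBinaryPooling:
    def test_single_study_proportion_with_wilson_interval(self):
        p = pool_binary([binry("s1", 22, 50)])
        assert p.estimate == pytest.approx(0.44)
        # Wilson interval brackets the estimate and stays in [0, 1]
        assert 0 <= p.ci_low < 0.44 < p.ci_high <= 1

    def test_all_zero_events_boundary(self):
        p = pool_binary([binry("s1", 0, 20), binry("s2", 0, 30)])
        assert p.estimate == 0.0
        assert p.ci_low == 0.0

    def test_pooled_proportion_against_hand_arithmetic(self):
        # oracle: inverse-variance on raw proportions (uncorrected weights)
        p1, p2 = 13 / 29, 13 / 30
        w1 = 29 / (p1 * (1 - p1))
        w2 = 30 / (p2 * (1 - p2))
        expected = (w1 * p1 + w2 * p2) / (w1 + w2)
        p = pool_binary([binry("s1", 13, 29), binry("s2", 13, 30)])
        assert p.estimate == pytest.approx(expected, abs=1e-3)


class TestHeterogeneity:
    def test_single_study_is_zero(self):
        assert heterogeneity([cont("s1", 3.0, 1.0, 10)]) == (0.0, 0.0, 0.0)

    def test_identical_estimates_no_heterogeneity(self):
        het = heterogeneity([cont(f"s{i}", 5.0, 2.0, 30) for i in range(4)])
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0

    def test_q_matches_brute_force_summation(self):
        y = [1.0, 2.5, 4.0]
        sd = [1.0, 2.0, 1.5]
        n = [20, 30, 25]
        w = [ni / si**2 for ni, si in zip(n, sd)]
        y_fix = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
        q = sum(wi * (yi - y_fix) ** 2 for wi, yi in zip(w, y))
        c = sum(w) - sum(wi**2 for wi in w) / sum(w)
        expected_tau2 = max(0.0, (q - 2) / c)
        het = heterogeneity([cont(f"s{i}", y[i], sd[i], n[i])
                             for i in range(3)])
        assert het.Q == pytest.approx(q)
        assert het.I2 == pytest.approx(max(0.0, (q - 2) / q) * 100)
        assert het.tau2 == pytest.approx(expected_tau2)


@st.composite
def study_sets(draw):
    k = draw(st.integers(2, 8))
    return [cont(f"s{i}",
                 draw(st.floats(-20, 20)),
                 draw(st.floats(0.5, 10)),
                 draw(st.integers(5, 200)))
            for i in range(k)]


class TestPoolingProperties:
    @given(studies=study_sets())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_estimate_bounded_and_random_ci_never_narrower(self, studies):
        means = [s.mean for s in studies]
        fixed = pool_continuous(studies, model_rule="fixed")
        random = pool_continuous(studies, model_rule="random")
        for p in (fixed, random):
            assert min(means) - 1e-9 <= p.estimate <= max(means) + 1e-9
        assert (random.ci_high - random.ci_low
                >= fixed.ci_high - fixed.ci_low - 1e-9)

    def test_parameter_recovery_at_k20(self):
        """Pooled mean lands within 3 SE of the truth in >=95% of replicates."""
        rng = np.random.default_rng(42)
        mu, tau, sd, n, k = 5.0, 0.8, 4.0, 40, 20
        hits = 0
        reps = 200
        for _ in range(reps):
            studies = []
            for i in range(k):
                theta = rng.normal(mu, tau)
                x = rng.normal(theta, sd, size=n)
                studies.append(cont(f"s{i}", float(x.mean()),
                                    float(x.std(ddof=1)), n))
            p = pool_continuous(studies, model_rule="random")
            se = (p.ci_high - p.ci_low) / (2 * Z_95)
            hits += abs(p.estimate - mu) < 3 * se
        assert hits / reps >= 0.95
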