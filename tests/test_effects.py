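"""Contrast computation, pairwise pooling, and the combined-group formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmaudit.datamodel import ArmRecord, ComparisonKey, TrialRecord
from nmaudit.effects import (
    CannotImputeError, Contrast, MissingSDError, NoEvidenceError,
    combined_mean, combined_sd, contrast_from_arms, contrasts_from_trial,
    impute_sd, pool_pairwise,
)


def arm(code, n, mean=None, sd=None, events=None):
    return ArmRecord(intervention=code, n=n, mean=mean, sd=sd, events=events)


class TestContrastFromArms:
    def test_identical_continuous_arms(self):
        c = contrast_from_arms(arm("HA", 25, 50, 10), arm("NOP", 25, 50, 10), "continuous")
        assert c.estimate == 0.0
        assert c.se == pytest.approx(math.sqrt(8.0))

    def test_log_odds_ratio_hand_arithmetic(self):
        # (5/50) vs (10/50): OR = (10/40)/(5/45) = 2.25
        c = contrast_from_arms(arm("HA", 50, events=5), arm("NOP", 50, events=10), "binary")
        assert c.estimate == pytest.approx(math.log(2.25), abs=1e-12)
        assert c.se == pytest.approx(math.sqrt(1 / 5 + 1 / 45 + 1 / 10 + 1 / 40))

    def test_continuity_correction_only_on_zero_cell(self):
        c = contrast_from_arms(arm("HA", 20, events=0), arm("NOP", 20, events=5), "binary")
        # all four cells shifted by 0.5
        expected = math.log((5.5 / 15.5) / (0.5 / 20.5))
        assert c.estimate == pytest.approx(expected)

    def test_missing_sd_raises(self):
        with pytest.raises(MissingSDError):
            contrast_from_arms(arm("HA", 30, 60, None), arm("NOP", 30, 55, 12), "continuous")

    def test_degenerate_all_zero_table(self):
        with pytest.raises(Exception):
            contrast_from_arms(arm("HA", 20, events=0), arm("NOP", 20, events=0), "binary")

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(1, 30), s2=st.floats(1, 30),
        n1=st.integers(5, 200), n2=st.integers(5, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_direction_antisymmetry(self, m1, m2, s1, s2, n1, n2):
        a1, a2 = arm("HA", n1, m1, s1), arm("NOP", n2, m2, s2)
        c_fwd = contrast_from_arms(a1, a2, "continuous")
        c_rev = contrast_from_arms(a2, a1, "continuous")
        # canonical orientation makes both identical; oriented views negate
        assert c_fwd.oriented("HA", "NOP") == pytest.approx(-c_rev.oriented("NOP", "HA"))
        assert c_fwd.se == pytest.approx(c_rev.se)

    def test_three_arm_trial_emits_full_pairwise_set(self):
        t = TrialRecord("t", [arm("HA", 30, 60, 10), arm("NOP", 30, 55, 10),
                              arm("RSA", 30, 65, 10)])
        cs = contrasts_from_trial(t, "continuous")
        assert {str(c.pair) for c in cs} == {"HA:NOP", "HA:RSA", "NOP:RSA"}


class TestPoolPairwise:
    def one(self, est, se, tid="t"):
        return Contrast(tid, ComparisonKey("HA", "NOP"), est, se)

    def test_single_contrast_identity(self):
        p = pool_pairwise([self.one(3.0, 1.0)], model="common")
        assert (p.estimate, p.se, p.tau2, p.i2, p.k) == (3.0, 1.0, 0.0, 0.0, 1)

    def test_common_effects_closed_form(self):
        p = pool_pairwise([self.one(2, 1, "a"), self.one(4, 1, "b")], model="common")
        assert p.estimate == pytest.approx(3.0)
        assert p.se == pytest.approx(math.sqrt(0.5))

    def test_identical_contrasts_no_heterogeneity(self):
        p = pool_pairwise([self.one(2, 1, "a"), self.one(2, 1, "b")], model="random")
        assert p.q == pytest.approx(0.0)
        assert p.tau2 == 0.0 and p.i2 == 0.0

    def test_common_equals_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        ests = rng.normal(0, 2, size=6)
        ses = rng.uniform(0.5, 2, size=6)
        cs = [self.one(e, s, f"t{i}") for i, (e, s) in enumerate(zip(ests, ses))]
        p = pool_pairwise(cs, model="common")
        # oracle: explicit WLS solve of the one-parameter model
        X = np.ones((6, 1))
        W = np.diag(1 / ses**2)
        theta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ests)
        assert p.estimate == pytest.approx(float(theta[0]), abs=1e-12)

    def test_random_se_at_least_common_se(self):
        rng = np.random.default_rng(4)
        for rep in range(20):
            cs = [self.one(float(rng.normal(0, 3)), float(rng.uniform(0.3, 2)), f"t{i}")
                  for i in range(int(rng.integers(2, 8)))]
            assert pool_pairwise(cs, "random").se >= pool_pairwise(cs, "common").se - 1e-12

    def test_dersimonian_laird_tau2_closed_form(self):
        cs = [self.one(0, 1, "a"), self.one(4, 1, "b")]
        p = pool_pairwise(cs, model="random")
        # w=1 each: Q = 8, C = 2 - 2/2 = 1, tau2 = (8-1)/1 = 7
        assert p.q == pytest.approx(8.0)
        assert p.tau2 == pytest.approx(7.0)

    def test_empty_raises(self):
        with pytest.raises(NoEvidenceError):
            pool_pairwise([])

    def test_mixed_pairs_rejected(self):
        other = Contrast("x", ComparisonKey("HA", "RSA"), 1.0, 1.0)
        with pytest.raises(Exception):
            pool_pairwise([self.one(1, 1), other])


class TestCombinedMean:
    def test_equal_weights(self):
        assert combined_mean([(10, 70), (10, 80)]) == pytest.approx(75.0)

    def test_hand_arithmetic(self):
        assert combined_mean([(50, 80.0), (55, 75.0)]) == pytest.approx(8125 / 105)

    def test_single_group_identity(self):
        assert combined_mean([(124, 75.2)]) == pytest.approx(75.2)

    @given(st.lists(st.tuples(st.integers(1, 100), st.floats(0, 100)), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, groups):
        assert combined_mean(groups) == pytest.approx(combined_mean(groups[::-1]))

    def test_splitting_a_group_in_half_changes_nothing(self):
        whole = combined_mean([(40, 62.0), (20, 70.0)])
        split = combined_mean([(20, 62.0), (20, 62.0), (20, 70.0)])
        assert whole == pytest.approx(split)

    def test_empty_raises(self):
        with pytest.raises(NoEvidenceError):
            combined_mean([])


def reconstruct_group(n, mean, sd):
    """Exact sample with the requested n, mean, and (ddof=1) SD."""
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= base.std(ddof=1)
    return base * sd + mean


class TestCombinedSD:
    def test_identical_groups_approach_common_sd(self):
        # exactly: sqrt(2(n-1)/(2n-1)) * s, from the N-1 denominator of the
        # pooled sample; converges to s as n grows
        assert combined_sd([(10, 5.0, 2.0), (10, 5.0, 2.0)]) == pytest.approx(
            2.0 * math.sqrt(18 / 19)
        )
        assert combined_sd([(5000, 5.0, 2.0), (5000, 5.0, 2.0)]) == pytest.approx(2.0, abs=1e-3)

    def test_matches_sd_of_reconstructed_pooled_sample(self):
        groups = [(10, 0.0, 1.0), (10, 10.0, 1.0)]
        pooled = np.concatenate([reconstruct_group(*g) for g in groups])
        oracle = float(np.std(pooled, ddof=1))
        assert combined_sd(groups) == pytest.approx(oracle, abs=1e-10)
        assert oracle == pytest.approx(math.sqrt(518 / 19))

    @given(
        st.lists(
            st.tuples(st.integers(3, 40), st.floats(-50, 50), st.floats(0.1, 20)),
            min_size=1, max_size=4,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_oracle_agreement_on_random_groups(self, groups):
        pooled = np.concatenate([reconstruct_group(*g) for g in groups])
        assert combined_sd(groups) == pytest.approx(float(np.std(pooled, ddof=1)), rel=1e-9)

    def test_absent_sd_raises(self):
        with pytest.raises(MissingSDError):
            combined_sd([(10, 5.0, 2.0), (12, 6.0, None)])


class TestImputeSD:
    def trial(self, tid, sds):
        arms = [arm(c, 30, 60.0, s) for c, s in zip(["HA", "NOP", "RSA"], sds)]
        return TrialRecord(tid, arms[: len(sds)])

    def test_mean_of_reported_sds(self):
        trials = [self.trial("a", [10.0, 14.0]), self.trial("b", [None, 12.0])]
        out = impute_sd(trials)
        imputed = out[1].arms[0]
        assert imputed.sd == pytest.approx((10 + 14 + 12) / 3)
        assert imputed.sd_imputed

    def test_noop_when_complete(self):
        trials = [self.trial("a", [10.0, 14.0])]
        assert impute_sd(trials) == trials

    def test_single_reported_sd_propagates(self):
        trials = [self.trial("a", [12.3, None]), self.trial("b", [None, None])]
        out = impute_sd(trials)
        assert all(
            a.sd == pytest.approx(12.3) for t in out for a in t.arms
        )

    def test_reported_sds_untouched(self):
        trials = [self.trial("a", [10.0, None])]
        out = impute_sd(trials)
        assert out[0].arms[0].sd == 10.0 and not out[0].arms[0].sd_imputed

    def test_no_sds_anywhere(self):
        with pytest.raises(CannotImputeError):
            impute_sd([self.trial("a", [None, None])])
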