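"""Network estimation against closed-form and symbolic GLS oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import sympy

from nmaudit.datamodel import ArmRecord, ComparisonKey, TrialRecord
from nmaudit.effects import Contrast, contrasts_from_trial, pool_pairwise
from nmaudit.nma import (
    ConnectivityError, comparison_contributions, contribution_matrix,
    fit_network, league_table,
)
from conftest import random_two_arm_network


def symbolic_gls(contrasts, nodes, reference):
    """Independent oracle: exact-rational GLS solve of the consistency model
    for two-arm-trial networks (diagonal weights), via sympy."""
    cols = [n for n in nodes if n != reference]
    X = sympy.zeros(len(contrasts), len(cols))
    y = sympy.zeros(len(contrasts), 1)
    W = sympy.zeros(len(contrasts), len(contrasts))
    for i, c in enumerate(contrasts):
        if c.pair.b != reference:
            X[i, cols.index(c.pair.b)] = 1
        if c.pair.a != reference:
            X[i, cols.index(c.pair.a)] = -1
        y[i] = sympy.Rational(Fraction(c.estimate).limit_denominator(10**6))
        W[i, i] = 1 / sympy.Rational(Fraction(c.se**2).limit_denominator(10**6))
    xtwx = X.T * W * X
    theta = xtwx.solve(X.T * W * y)
    vcov = xtwx.inv()
    return {n: float(theta[j]) for j, n in enumerate(cols)}, vcov, cols


class TestFitNetwork:
    def test_single_edge_reduces_to_contrast(self):
        c = Contrast("t", ComparisonKey("A", "B"), 3.0, 1.0)
        fit = fit_network([c], model="common")
        est, se = fit.estimate("A", "B")
        assert (est, se) == pytest.approx((3.0, 1.0))

    def test_single_edge_reduces_to_pairwise_pooling(self):
        cs = [Contrast(f"t{i}", ComparisonKey("A", "B"), e, s)
              for i, (e, s) in enumerate([(2.0, 1.0), (4.0, 0.5), (1.0, 2.0)])]
        for model in ("common", "random"):
            fit = fit_network(cs, model=model)
            pooled = pool_pairwise(cs, model=model)
            est, se = fit.estimate("A", "B")
            assert est == pytest.approx(pooled.estimate, abs=1e-10)
            assert se == pytest.approx(pooled.se, abs=1e-10)
            assert fit.tau2 == pytest.approx(pooled.tau2, abs=1e-10)

    def test_chain_additivity(self, chain_contrasts):
        fit = fit_network(chain_contrasts, model="common")
        est, se = fit.estimate("A", "C")
        assert est == pytest.approx(7.0)
        assert se == pytest.approx(math.sqrt(2.0))

    def test_triangle_closed_form(self, triangle_contrasts):
        # explicit 3-equation weighted least squares: with all se = 1 the
        # direct A:C gets weight 2/3, the indirect chain 1/3
        fit = fit_network(triangle_contrasts, model="common")
        est, se = fit.estimate("A", "C")
        assert est == pytest.approx(7.0)
        assert se == pytest.approx(math.sqrt(2 / 3))

    def test_consistency_equations_hold_exactly(self):
        rng = np.random.default_rng(5)
        cs = random_two_arm_network(rng, 4, 6)
        fit = fit_network(cs, model="random")
        for a, b, c in itertools.permutations(fit.nodes, 3):
            ab, _ = fit.estimate(a, b)
            bc, _ = fit.estimate(b, c)
            ac, _ = fit.estimate(a, c)
            assert ab + bc == pytest.approx(ac, abs=1e-10)

    @pytest.mark.parametrize("n_nodes,n_trials", [(2, 2), (3, 3), (3, 5), (4, 4), (4, 6)])
    def test_matches_symbolic_gls_on_enumerated_networks(self, n_nodes, n_trials):
        rng = np.random.default_rng(100 * n_nodes + n_trials)
        for rep in range(3):
            cs = random_two_arm_network(rng, n_nodes, n_trials)
            fit = fit_network(cs, model="common")
            theta, vcov, cols = symbolic_gls(cs, fit.nodes, fit.reference)
            for node, val in theta.items():
                assert fit.basic[node] == pytest.approx(val, abs=1e-8)
            for i, ni in enumerate(cols):
                for j, nj in enumerate(cols):
                    assert fit.vcov.loc[ni, nj] == pytest.approx(float(vcov[i, j]), abs=1e-8)

    def test_three_arm_trial_exact_covariance(self):
        """A single 3-arm trial: the GLS with shared-arm covariance must
        reproduce the arm-level estimates exactly (each pairwise effect is
        the difference of arm means, with its two-arm SE)."""
        t = TrialRecord("t3arm", [
            ArmRecord(intervention="HA", n=25, mean=50.0, sd=10.0),
            ArmRecord(intervention="NOP", n=20, mean=44.0, sd=8.0),
            ArmRecord(intervention="RSA", n=30, mean=57.0, sd=12.0),
        ])
        cs = contrasts_from_trial(t, "continuous")
        fit = fit_network(cs, model="common")
        est, se = fit.estimate("HA", "NOP")
        assert est == pytest.approx(-6.0, abs=1e-8)
        assert se == pytest.approx(math.sqrt(100 / 25 + 64 / 20), abs=1e-8)
        est, se = fit.estimate("NOP", "RSA")
        assert est == pytest.approx(13.0, abs=1e-8)
        assert se == pytest.approx(math.sqrt(64 / 20 + 144 / 30), abs=1e-8)

    def test_q_decomposition_identity(self):
        rng = np.random.default_rng(17)
        for rep in range(10):
            cs = random_two_arm_network(rng, 4, 8)
            fit = fit_network(cs, model="common")
            assert fit.q_total == pytest.approx(
                fit.q_heterogeneity + fit.q_inconsistency, abs=1e-8
            )
            assert fit.df_total == fit.df_heterogeneity + fit.df_inconsistency

    def test_disconnected_network_raises(self):
        cs = [
            Contrast("t1", ComparisonKey("A", "B"), 1.0, 1.0),
            Contrast("t2", ComparisonKey("C", "D"), 1.0, 1.0),
        ]
        with pytest.raises(ConnectivityError):
            fit_network(cs)

    def test_random_tau2_inflates_se(self):
        rng = np.random.default_rng(23)
        cs = random_two_arm_network(rng, 3, 9)
        common = fit_network(cs, model="common")
        rand = fit_network(cs, model="random")
        if rand.tau2 > 0:
            for a, b in itertools.combinations(rand.nodes, 2):
                assert rand.estimate(a, b)[1] >= common.estimate(a, b)[1] - 1e-10


class TestLeagueTable:
    def test_subtraction_of_basic_estimates(self, triangle_contrasts):
        fit = fit_network(triangle_contrasts, model="common")
        lt = league_table(fit).set_index(["first", "second"])
        assert lt.loc[("A", "C"), "estimate"] == pytest.approx(7.0)
        assert lt.loc[("B", "C"), "estimate"] == pytest.approx(5.0)

    def test_anti_symmetry(self, triangle_contrasts):
        fit = fit_network(triangle_contrasts, model="common")
        lt = league_table(fit).set_index(["first", "second"])
        for a, b in itertools.permutations(fit.nodes, 2):
            assert lt.loc[(a, b), "estimate"] == pytest.approx(
                -lt.loc[(b, a), "estimate"], abs=1e-12
            )
            assert lt.loc[(a, b), "se"] == pytest.approx(lt.loc[(b, a), "se"])

    def test_ci_half_width_on_chain(self, chain_contrasts):
        fit = fit_network(chain_contrasts, model="common")
        lt = league_table(fit).set_index(["first", "second"])
        row = lt.loc[("A", "C")]
        assert row["ci_high"] - row["estimate"] == pytest.approx(
            1.959963984540054 * math.sqrt(2.0), abs=1e-9
        )


class TestContributionMatrix:
    def test_single_trial_edge_contributes_everything(self):
        c = Contrast("only", ComparisonKey("A", "B"), 3.0, 1.0)
        cm = contribution_matrix(fit_network([c], model="common"))
        assert cm.loc["A:B", "only"] == pytest.approx(100.0)

    def test_equal_se_trials_split_evenly(self):
        cs = [Contrast(t, ComparisonKey("A", "B"), e, 1.0) for t, e in
              [("t1", 2.0), ("t2", 4.0)]]
        cm = contribution_matrix(fit_network(cs, model="common"))
        assert cm.loc["A:B", "t1"] == pytest.approx(50.0)
        assert cm.loc["A:B", "t2"] == pytest.approx(50.0)

    def test_triangle_flow_decomposition(self, triangle_contrasts):
        # equal-weight triangle: direct trial 2/3; each indirect-path trial
        # carries the 1/3 indirect stream over its 2 edges -> 1/6 each
        cm = contribution_matrix(fit_network(triangle_contrasts, model="common"))
        assert cm.loc["A:C", "t3"] == pytest.approx(100 * 2 / 3, abs=1e-6)
        assert cm.loc["A:C", "t1"] == pytest.approx(100 / 6, abs=1e-6)
        assert cm.loc["A:C", "t2"] == pytest.approx(100 / 6, abs=1e-6)

    def test_rows_sum_to_100_on_random_networks(self):
        rng = np.random.default_rng(31)
        for rep in range(100):
            n_nodes = int(rng.integers(2, 5))
            n_trials = int(rng.integers(n_nodes - 1, 8))
            cs = random_two_arm_network(rng, n_nodes, max(n_trials, n_nodes - 1))
            cm = contribution_matrix(fit_network(cs, model="common"))
            assert np.allclose(cm.sum(axis=1), 100.0, atol=0.1)
            assert (cm.to_numpy() >= -1e-9).all()

    def test_zero_contribution_trial_removal_is_invariant(self):
        # a D:E appendage cannot reach A:B once D-E's only path is through it
        cs = [
            Contrast("t1", ComparisonKey("A", "B"), 2.0, 1.0),
            Contrast("t2", ComparisonKey("B", "C"), 5.0, 1.0),
            Contrast("t3", ComparisonKey("C", "D"), 1.0, 1.0),
        ]
        fit_full = fit_network(cs, model="common")
        row = comparison_contributions(fit_full, ComparisonKey("A", "B"))
        assert row["t3"] == pytest.approx(0.0, abs=1e-9)
        fit_reduced = fit_network(cs[:2], model="common")
        assert fit_full.estimate("A", "B") == pytest.approx(fit_reduced.estimate("A", "B"))
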