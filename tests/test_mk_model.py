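"""Mk transition probabilities, pruning likelihood and ML rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hostarrow as ha
from hostarrow.mk_model import RateModel, fit_ml, pruning_log_likelihood

from conftest import brute_force_log_likelihood, random_topology


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        m = RateModel.free(3, rates=(0.3, 1.2, 0.1, 2.0, 0.5, 0.9))
        assert np.allclose(ha.transition_matrix(m, 0.0), np.eye(3))

    def test_long_time_symmetric_reaches_uniform(self):
        m = RateModel.symmetric(2, 1.0)
        assert np.allclose(ha.transition_matrix(m, 50.0), 0.5, atol=1e-12)

    def test_asymmetric_closed_form(self):
        """q01=1, q10=2 at t=1: P01 = (1/3)(1 - e^-3)."""
        m = RateModel.free(2, rates=(1.0, 2.0))
        P = ha.transition_matrix(m, 1.0)
        assert P[0, 1] == pytest.approx((1 / 3) * (1 - np.exp(-3)), abs=1e-9)
        assert P[0, 0] == pytest.approx(1 - (1 / 3) * (1 - np.exp(-3)), abs=1e-9)

    def test_matches_series_expansion_oracle(self):
        """Scaled Taylor-series exponential as an independent oracle."""
        m = RateModel.free(3, rates=(0.4, 1.1, 0.2, 0.8, 1.5, 0.3))
        Q = m.q_matrix()
        t = 0.7
        # scaling and squaring with a plain Taylor series
        s = 8
        A = Q * t / 2 ** s
        T = np.eye(3)
        term = np.eye(3)
        for i in range(1, 25):
            term = term @ A / i
            T = T + term
        for _ in range(s):
            T = T @ T
        assert np.allclose(ha.transition_matrix(m, t), T, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ha.transition_matrix(RateModel.symmetric(2), -0.1)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(a=st.floats(0, 5), b=st.floats(0, 5), s=st.floats(0, 3), t=st.floats(0, 3),
           k=st.integers(2, 4))
    def test_chapman_kolmogorov_and_row_stochastic(self, a, b, s, t, k):
        rng = np.random.default_rng(int(a * 100 + b * 10 + k))
        n_off = k * (k - 1)
        m = RateModel.free(k, rates=tuple(rng.uniform(0, 3, n_off)))
        if k == 2:
            m = RateModel.free(2, rates=(a, b))
        Pst = ha.transition_matrix(m, s + t)
        assert np.allclose(Pst.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(
            Pst, ha.transition_matrix(m, s) @ ha.transition_matrix(m, t),
            atol=1e-10)


class TestPruningLikelihood:
    def test_two_tip_closed_form(self, cherry):
        char = ha.CharacterMatrix({"A": "0", "B": "1"})
        m = RateModel.symmetric(2, 1.0)
        P = ha.transition_matrix(m, 1.0)
        expected = np.log(0.5 * (P[0, 0] * P[0, 1] + P[1, 0] * P[1, 1]))
        assert pruning_log_likelihood(cherry, m, char) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(-1.4048, abs=5e-5)

    def test_all_missing_gives_likelihood_one(self, cherry):
        char = ha.CharacterMatrix({"A": None, "B": None}, state_labels=("0", "1"))
        m = RateModel.symmetric(2, 1.0)
        assert pruning_log_likelihood(cherry, m, char) == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_no_change(self, quartet):
        char = ha.CharacterMatrix({t: "0" for t in "ABCD"}, state_labels=("0", "1"))
        m = RateModel.symmetric(2, 0.0)
        assert pruning_log_likelihood(quartet, m, char) == pytest.approx(
            np.log(0.5), abs=1e-12)

    def test_matches_brute_force_enumeration_small_trees(self):
        """Pruning == exhaustive sum over interior assignments, trees <= 6
        tips, k <= 3, random rates and data (tolerance 1e-10)."""
        rng = np.random.default_rng(42)
        for rep in range(40):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 4))
            tree = random_topology(n, rng)
            labels = sorted(tree.tip_labels())
            states = {l: (None if rng.uniform() < 0.2
                          else str(rng.integers(k))) for l in labels}
            char = ha.CharacterMatrix(states,
                                      state_labels=tuple(str(i) for i in range(k)))
            m = RateModel.free(k, rates=tuple(rng.uniform(0.05, 3, k * (k - 1))))
            got = pruning_log_likelihood(tree, m, char)
            want = brute_force_log_likelihood(tree, m, char)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_tip_can_be_pruned(self):
        """A missing tip carries no information: its removal (keeping the
        unary root pass-through) leaves the likelihood unchanged."""
        full = ha.parse_newick("((A:0.4,B:0.9):0.6,C:1.2);")
        charf = ha.CharacterMatrix({"A": "0", "B": "1", "C": None},
                                   state_labels=("0", "1"))
        # same tree minus C: root keeps its single remaining child
        pruned = ha.RootedTree([-1, 0, 1, 1], [0.0, 0.6, 0.4, 0.9],
                               [None, None, "A", "B"])
        charp = ha.CharacterMatrix({"A": "0", "B": "1"}, state_labels=("0", "1"))
        m = RateModel.free(2, rates=(0.7, 1.9))
        assert pruning_log_likelihood(full, m, charf) == pytest.approx(
            pruning_log_likelihood(pruned, m, charp), abs=1e-12)

    def test_tip_absent_from_matrix_is_error(self, cherry):
        char = ha.CharacterMatrix({"A": "0"}, state_labels=("0", "1"))
        with pytest.raises(KeyError):
            pruning_log_likelihood(cherry, RateModel.symmetric(2), char)

    def test_k_mismatch_is_error(self, cherry):
        char = ha.CharacterMatrix({"A": "0", "B": "1"})
        with pytest.raises(ValueError):
            pruning_log_likelihood(cherry, RateModel.symmetric(3), char)


class TestFitMl:
    def test_monomorphic_boundary_solution(self, quartet):
        """All tips in one state: under the shared-rate model the rate goes
        to the lower bound and lnL to ln(1/k) (the uniform root prior)."""
        char = ha.CharacterMatrix({t: "0" for t in "ABCD"}, state_labels=("0", "1"))
        fit = fit_ml(quartet, char, RateModel.symmetric(2))
        assert fit.log_likelihood == pytest.approx(np.log(0.5), abs=1e-4)
        assert all(r < 1e-4 for r in fit.rates)

    def test_beats_exhaustive_grid_oracle(self):
        """On a 4-tip tree the fitted lnL must reach the best of a dense
        rate grid (within 1e-4)."""
        tree = ha.parse_newick("((A:0.5,B:1.5):0.5,(C:1.0,D:0.7):0.9);")
        char = ha.CharacterMatrix({"A": "0", "B": "1", "C": "1", "D": "0"})
        template = RateModel.free(2)
        grid = np.geomspace(0.01, 10, 25)
        best = max(
            pruning_log_likelihood(tree, template.with_rates((a, b)), char)
            for a in grid for b in grid)
        fit = fit_ml(tree, char, template)
        assert fit.log_likelihood >= best - 1e-4

    def test_nested_models_monotone(self):
        """Bidirectional max lnL >= each one-way max lnL on any dataset."""
        rng = np.random.default_rng(7)
        tree = random_topology(8, rng)
        char, _ = ha.simulate_mk_character(
            tree, RateModel.free(2, rates=(1.0, 0.5)), seed=11,
            state_labels=("0", "1"))
        bi = fit_ml(tree, char, RateModel.free(2)).log_likelihood
        for oneway in (RateModel.one_way(0, 1), RateModel.one_way(1, 0)):
            assert bi >= fit_ml(tree, char, oneway).log_likelihood - 1e-6


class TestMeanOverSample:
    def test_single_tree_equals_fit(self, cherry):
        char = ha.CharacterMatrix({"A": "0", "B": "1"})
        sample = ha.TreeSample.from_trees([cherry])
        one = fit_ml(cherry, char, RateModel.symmetric(2)).log_likelihood
        assert ha.mean_lnL_over_sample(sample, char, RateModel.symmetric(2)) == \
            pytest.approx(one, abs=1e-9)

    def test_repeated_tree_mean_unchanged(self, cherry):
        char = ha.CharacterMatrix({"A": "0", "B": "1"})
        one = ha.mean_lnL_over_sample(ha.TreeSample.from_trees([cherry]),
                                      char, RateModel.symmetric(2))
        five = ha.mean_lnL_over_sample(ha.TreeSample.from_trees([cherry] * 5),
                                       char, RateModel.symmetric(2))
        assert five == pytest.approx(one, abs=1e-9)

    def test_two_trees_mean_of_oracle_values(self):
        """Mean over two hand-checkable cherries equals the mean of the two
        per-tree brute-force maxima."""
        t1 = ha.parse_newick("(A:0.5,B:0.5);")
        t2 = ha.parse_newick("(A:2.0,B:2.0);")
        char = ha.CharacterMatrix({"A": "0", "B": "1"})
        template = RateModel.symmetric(2)
        grid = np.geomspace(1e-4, 50, 3000)
        per_tree = []
        for t in (t1, t2):
            per_tree.append(max(
                pruning_log_likelihood(t, template.with_rates((r,)), char)
                for r in grid))
        got = ha.mean_lnL_over_sample(ha.TreeSample.from_trees([t1, t2]),
                                      char, template)
        assert got == pytest.approx(np.mean(per_tree), abs=1e-5)
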