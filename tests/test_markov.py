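"""Gain/loss chain: transition probabilities, pruning likelihood, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

import coevonet as cn
from coevonet.errors import ValidationError
from coevonet.markov import _gamma_multipliers
from coevonet.simulate import random_tree

from conftest import brute_force_loglik

rates = st.floats(min_value=0.05, max_value=10.0)
times = st.floats(min_value=0.0, max_value=5.0)


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(cn.transition_matrix(1.0, 1.0, 0.0), np.eye(2))

    def test_long_time_reaches_stationarity(self):
        P = cn.transition_matrix(1.0, 3.0, 200.0)
        assert np.allclose(P, [[0.75, 0.25], [0.75, 0.25]], atol=1e-12)

    def test_matches_matrix_exponential(self):
        g, l, t = 2.0, 1.0, 0.5
        P = cn.transition_matrix(g, l, t)
        Q = np.array([[-g, g], [l, -l]])
        assert np.abs(P - expm(Q * t)).max() < 1e-10
        assert math.isclose(P[0, 1], (2 / 3) * (1 - math.exp(-1.5)), rel_tol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            cn.transition_matrix(1.0, 1.0, -0.1)

    @settings(max_examples=50, deadline=None)
    @given(g=rates, l=rates, t1=times, t2=times)
    def test_chapman_kolmogorov(self, g, l, t1, t2):
        P1 = cn.transition_matrix(g, l, t1)
        P2 = cn.transition_matrix(g, l, t2)
        P12 = cn.transition_matrix(g, l, t1 + t2)
        assert np.abs(P1 @ P2 - P12).max() < 1e-10

    @settings(max_examples=50, deadline=None)
    @given(g=rates, l=rates, t=times)
    def test_rows_stochastic_and_stationary(self, g, l, t):
        P = cn.transition_matrix(g, l, t)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert ((P >= -1e-15) & (P <= 1 + 1e-15)).all()
        pi = np.array([l / (g + l), g / (g + l)])
        assert np.abs(pi @ P - pi).max() < 1e-12


class TestRateCategories:
    @pytest.mark.parametrize("alpha,k", [(0.5, 4), (1.0, 4), (2.0, 8)])
    def test_multipliers_positive_mean_near_one(self, alpha, k):
        m = _gamma_multipliers(alpha, k)
        assert (m > 0).all()
        assert abs(m.mean() - 1.0) < 0.25  # discretization error only

    def test_single_category_is_unit(self):
        assert _gamma_multipliers(3.0, 1).tolist() == [1.0]

    def test_stationary_frequencies_sum_to_one(self, model_k4):
        for k in range(4):
            assert math.isclose(model_k4.stationary(k).sum(), 1.0)

    def test_json_roundtrip(self, model_k4):
        again = cn.GainLossModel.from_json(model_k4.to_json())
        assert again == model_k4


class TestLikelihood:
    def test_all_present_triple_closed_form(self):
        # ((B:1,C:1):0,A:1) with g=l=1: the zero-length branch pins the
        # cherry's ancestor to the root state, so
        # L(1,1,1) = sum_s pi_s * P_{s1}(1)^3
        tree = cn.read_newick("((B:1,C:1):0,A:1);")
        model = cn.GainLossModel(gain=1.0, loss=1.0)
        res = cn.log_likelihood(np.array([[1, 1, 1]]), tree, model)
        p01 = 0.5 * (1 - math.exp(-2.0))
        p11 = 0.5 + 0.5 * math.exp(-2.0)
        expected = 0.5 * p01**3 + 0.5 * p11**3
        assert math.isclose(res.per_gene[0], math.log(expected), abs_tol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_pruning_equals_enumeration(self, seed, model_skew):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng.integers(3, 7), rng, mean_length=0.5)
        X = rng.integers(0, 2, size=(4, tree.n_leaves))
        res = cn.log_likelihood(X, tree, model_skew)
        for i in range(4):
            assert math.isclose(
                res.per_gene[i], brute_force_loglik(X[i], tree, model_skew), abs_tol=1e-10
            )

    def test_mixture_enumeration_with_categories(self, tree6, model_k4):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(3, 6))
        res = cn.log_likelihood(X, tree6, model_k4)
        for i in range(3):
            assert math.isclose(
                res.per_gene[i], brute_force_loglik(X[i], tree6, model_k4), abs_tol=1e-10
            )
        assert np.allclose(res.category_posterior.sum(axis=1), 1.0)

    def test_total_is_sum_of_per_gene(self, tree6, model_k1):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(6, 6))
        res = cn.log_likelihood(X, tree6, model_k1)
        assert math.isclose(res.total, res.per_gene.sum())

    def test_scale_invariance(self, model_k1):
        # multiplying branch lengths by c and dividing rho by c leaves L unchanged
        t1 = random_tree(10, np.random.default_rng(0), mean_length=0.4)
        scaled = cn.Phylogeny(
            parent=t1.parent,
            children=t1.children,
            lengths=t1.lengths * 3.0,
            leaf_labels=t1.leaf_labels,
        )
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(5, 10))
        m_scaled = cn.GainLossModel(gain=1.0, loss=1.0, rho=1.0 / 3.0)
        a = cn.log_likelihood(X, t1, model_k1).total
        b = cn.log_likelihood(X, scaled, m_scaled).total
        assert math.isclose(a, b, abs_tol=1e-9)


@pytest.fixture(scope="module")
def fitted(tree32):
    true = cn.GainLossModel(gain=2 / 3, loss=4 / 3, rho=1.0, n_categories=1)
    sim = cn.simulate_genes(tree32, true, 300, np.random.default_rng(11))
    model, lik = cn.fit_model(sim.leaf_states, tree32, n_categories=1)
    return true, sim, model, lik


class TestFit:
    def test_recovers_gain_fraction(self, fitted):
        true, _, model, _ = fitted
        p_true = true.gain / (true.gain + true.loss)
        p_fit = model.gain / (model.gain + model.loss)
        assert abs(p_fit - p_true) < 0.1

    def test_refit_is_fixed_point(self, fitted, tree32):
        _, sim, model, lik = fitted
        start = {
            "p": model.gain / (model.gain + model.loss),
            "rho": model.rho,
            "alpha_gain": model.alpha_gain,
            "alpha_loss": model.alpha_loss,
        }
        model2, lik2 = cn.fit_model(sim.leaf_states, tree32, n_categories=1, start=start)
        assert abs(lik2.total - lik.total) < 1e-4

    def test_dominates_wrong_model(self, fitted, tree32):
        _, sim, model, lik = fitted
        wrong = cn.GainLossModel(gain=10.0, loss=10.0, rho=1.0, n_categories=1)
        assert lik.total >= cn.log_likelihood(sim.leaf_states, tree32, wrong).total

    def test_deterministic(self, tree32, model_k1):
        sim = cn.simulate_genes(tree32, model_k1, 60, np.random.default_rng(2))
        m1, _ = cn.fit_model(sim.leaf_states, tree32, n_categories=1)
        m2, _ = cn.fit_model(sim.leaf_states, tree32, n_categories=1)
        assert m1 == m2
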