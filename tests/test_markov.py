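"""Generator construction, transition probabilities, pruning likelihood
and ML fitting of the 4-state joint model."""

import numpy as np
import pytest
import scipy.linalg

import coevoscan as cs
from coevoscan.errors import ValidationError
from coevoscan.markov import MODELS, _expm_edges

from conftest import enumeration_loglik, random_topology_newick


class TestGenerator:
    def test_row_sums_zero_and_diagonal(self):
        Q = cs.build_generator(np.ones(8))
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert np.allclose(np.diag(Q), -2.0)

    def test_forbidden_double_transitions_are_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            Q = cs.build_generator(rng.uniform(0, 10, 8))
            assert Q[0, 3] == Q[3, 0] == Q[1, 2] == Q[2, 1] == 0.0

    def test_independent_model_tying(self):
        """Gain/loss of each character must land in the tied slots
        q12=q34, q21=q43, q13=q24, q31=q42."""
        gain_h, loss_h, gain_x, loss_x = 1.0, 2.0, 3.0, 4.0
        free = np.array([gain_h, loss_h, gain_x, loss_x])
        rates = MODELS["independent"].expand(free)
        r = cs.RateParameters.from_array(rates)
        assert r.q12 == r.q34 == gain_h
        assert r.q21 == r.q43 == loss_h
        assert r.q13 == r.q24 == gain_x
        assert r.q31 == r.q42 == loss_x

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            cs.build_generator(np.array([1, 1, 1, -0.1, 1, 1, 1, 1.0]))

    def test_model_constraint_checked(self):
        rates = np.array([1, 2, 3, 4, 5, 6, 7, 8.0])
        with pytest.raises(ValidationError):
            cs.build_generator(rates, model="independent")


@pytest.mark.parametrize(
    "model,expected",
    [("independent", 4), ("mutual", 8),
     ("partner_follows_focal", 6), ("focal_follows_partner", 6)],
)
def test_free_parameter_counts(model, expected):
    assert cs.count_free_params(model) == expected


def test_unknown_model_rejected():
    with pytest.raises(ValidationError):
        cs.count_free_params("pagel")


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = cs.build_generator(np.arange(1.0, 9.0))
        assert np.allclose(cs.transition_probabilities(Q, 0.0), np.eye(4))

    def test_rows_are_distributions(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            Q = cs.build_generator(rng.uniform(0, 5, 8))
            P = cs.transition_probabilities(Q, rng.uniform(0, 3))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= -1e-12).all() and (P <= 1 + 1e-12).all()

    def test_symmetric_rates_long_time_limit(self):
        """With all eight rates equal the chain mixes to uniform; the limit
        is cross-checked by repeated squaring of a short-time matrix."""
        Q = cs.build_generator(np.full(8, 1.3))
        P_long = cs.transition_probabilities(Q, 64.0)
        P_sq = cs.transition_probabilities(Q, 0.5)
        for _ in range(7):  # 0.5 * 2^7 = 64
            P_sq = P_sq @ P_sq
        assert np.allclose(P_long, 0.25, atol=1e-9)
        assert np.allclose(P_long, P_sq, atol=1e-9)

    def test_negative_time_rejected(self):
        Q = cs.build_generator(np.ones(8))
        with pytest.raises(ValidationError):
            cs.transition_probabilities(Q, -0.1)

    def test_semigroup_property(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            Q = cs.build_generator(rng.uniform(0, 4, 8))
            s, t = rng.uniform(0.05, 2.0, 2)
            lhs = cs.transition_probabilities(Q, s + t)
            rhs = (cs.transition_probabilities(Q, s)
                   @ cs.transition_probabilities(Q, t))
            assert np.allclose(lhs, rhs, atol=1e-8)

    def test_batched_edges_match_scipy(self):
        rng = np.random.default_rng(21)
        lengths = rng.uniform(0.01, 5.0, 30)
        for _ in range(5):
            Q = cs.build_generator(rng.uniform(0, 6, 8))
            P = _expm_edges(Q, lengths)
            for i, t in enumerate(lengths):
                assert np.allclose(P[i], scipy.linalg.expm(Q * t), atol=1e-10)


class TestPruningLikelihood:
    def test_matches_enumeration_on_random_small_trees(self):
        """Pruning equals brute-force summation over ancestral states on
        200 random instances with <=5 leaves."""
        rng = np.random.default_rng(42)
        for rep in range(200):
            n = int(rng.integers(3, 6))
            tree = cs.load_tree(random_topology_newick(n, rng))
            rates = rng.uniform(0.05, 4.0, 8)
            tips = rng.integers(0, 4, n)
            ll = cs.log_likelihood(tree, tips, rates)
            oracle = enumeration_loglik(tree, tips, rates)
            assert ll == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_zero_length_limit(self):
        """As all branches shrink the tip distribution collapses onto the
        root prior: identical tip states approach prior[state]."""
        tree = cs.load_tree("(a:0.000001,b:0.000001,c:0.000001);")
        ll = cs.log_likelihood(tree, np.array([3, 3, 3]), np.ones(8))
        assert ll == pytest.approx(np.log(0.25), abs=1e-4)

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        rates = rng.uniform(0.1, 2.0, 8)
        t1 = cs.load_tree("((a:0.3,b:0.5):0.2,(c:0.4,d:0.1):0.6);")
        t2 = cs.load_tree("((d:0.1,c:0.4):0.6,(b:0.5,a:0.3):0.2);")
        tips1 = {"a": 0, "b": 1, "c": 2, "d": 3}
        tl1 = cs.TreeLikelihood(t1)
        tl2 = cs.TreeLikelihood(t2)
        v1 = np.array([tips1[l] for l in tl1.leaf_labels])
        v2 = np.array([tips1[l] for l in tl2.leaf_labels])
        assert cs.log_likelihood(t1, v1, rates) == pytest.approx(
            cs.log_likelihood(t2, v2, rates), abs=1e-10
        )

    def test_loglik_nonpositive(self):
        rng = np.random.default_rng(9)
        tree = cs.load_tree(random_topology_newick(5, rng))
        for _ in range(10):
            ll = cs.log_likelihood(
                tree, rng.integers(0, 4, 5), rng.uniform(0.01, 5, 8)
            )
            assert ll <= 0.0


class TestFitML:
    def test_same_seed_bit_identical(self, small_tree):
        tips = np.array([0, 1, 2, 3])
        a = cs.fit_ml(small_tree, tips, "independent", n_restarts=2, seed=123)
        b = cs.fit_ml(small_tree, tips, "independent", n_restarts=2, seed=123)
        assert a.log_likelihood == b.log_likelihood
        assert a.rates == b.rates
        assert a.aic == b.aic

    def test_mutual_dominates_independent(self, tree200):
        """The independent model nests in the mutual model, so the mutual
        fit can never have a lower maximized likelihood."""
        tips = cs.simulate_pair(
            tree200, cs.simulate.MUTUAL_RATES, model="mutual", seed=4
        )
        from coevoscan.screen import fit_lrt_pair

        fit_i, fit_m = fit_lrt_pair(tree200, tips, seed=0)
        assert fit_m.log_likelihood >= fit_i.log_likelihood - 1e-9
        assert fit_i.aic == pytest.approx(2 * 4 - 2 * fit_i.log_likelihood)
        assert fit_m.aic == pytest.approx(2 * 8 - 2 * fit_m.log_likelihood)

    def test_aic_sanity_under_independence(self, tree200):
        """On data simulated under independence the mutual model's AIC can
        undercut the independent model's by at most its parameter cost."""
        tips = cs.simulate_pair(
            tree200, cs.simulate.INDEPENDENT_RATES, model="independent", seed=5
        )
        from coevoscan.screen import fit_lrt_pair

        fit_i, fit_m = fit_lrt_pair(tree200, tips, seed=1)
        assert fit_m.aic >= fit_i.aic - 8.0
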