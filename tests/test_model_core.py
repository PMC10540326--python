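"""Likelihood, posterior and M-step updates against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq, minimize
from scipy.special import expit, logit

from happi import (
    FixedCurve,
    HappiConfig,
    ISplineBasis,
    ModelParameters,
    expected_penalized_loglik,
    observed_loglik,
    posterior_presence,
    update_beta_firth,
    update_f_isotone,
    update_f_ispline,
)
from happi.curves import DetectionCurve
from happi.model import _weighted_logistic_obj, firth_penalty


class VectorCurve(DetectionCurve):
    """Test helper: detection probabilities supplied per genome."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def eval_prob(self, m):
        return self.probs

    def eval_logit(self, m):
        return np.clip(logit(self.probs), -10.0, 10.0)


def brute_force_loglik(Y, pi, f, eps):
    """Enumerate the latent presence indicator per genome."""
    total = 0.0
    for yi, pii, fi in zip(Y, pi, f):
        acc = 0.0
        for lam in (0, 1):
            p_y = (fi if lam else eps) if yi == 1 else ((1 - fi) if lam else 1 - eps)
            acc += p_y * (pii if lam else 1 - pii)
        total += np.log(acc)
    return total


class TestObservedLoglik:
    def test_perfect_detection_reduces_to_bernoulli(self):
        # eps=0, f=1, beta=0: each genome contributes log(1/2) whatever Y is
        params = ModelParameters(beta=np.zeros(1), curve=FixedCurve(prob=1.0))
        X, M = np.ones((4, 1)), np.zeros(4)
        for Y in ([1, 1, 0, 0], [1, 0, 1, 1]):
            ll = observed_loglik(params, Y, X, M, epsilon=0.0)
            assert ll == pytest.approx(4 * np.log(0.5), abs=1e-12)

    def test_uninformative_detection_is_free_of_beta(self):
        eps = 0.3
        Y = np.array([1, 0, 0, 1, 0])
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        expected = np.sum(Y * np.log(eps) + (1 - Y) * np.log(1 - eps))
        for beta in ([0.0, 0.0], [1.5, -2.0]):
            params = ModelParameters(beta=beta, curve=FixedCurve(prob=eps))
            ll = observed_loglik(params, Y, X, np.zeros(5), eps)
            assert ll == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 6)
        Y = rng.binomial(1, 0.5, n).astype(float)
        f = rng.uniform(0.05, 0.95, n)
        eps = float(rng.uniform(0.0, 0.2))
        beta = rng.normal(size=2)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        params = ModelParameters(beta=beta, curve=VectorCurve(f))
        ll = observed_loglik(params, Y, X, np.zeros(n), eps)
        oracle = brute_force_loglik(Y, expit(X @ beta), f, eps)
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_fixed_toy_case(self):
        params = ModelParameters(beta=np.zeros(1),
                                 curve=VectorCurve([0.9, 0.5, 0.2]))
        Y = np.array([1.0, 0.0, 1.0])
        ll = observed_loglik(params, Y, np.ones((3, 1)), np.zeros(3), 0.05)
        oracle = brute_force_loglik(Y, [0.5] * 3, [0.9, 0.5, 0.2], 0.05)
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_zero_probability_datum_gives_minus_inf(self):
        params = ModelParameters(beta=np.zeros(1), curve=FixedCurve(prob=0.0))
        with pytest.warns(RuntimeWarning):
            ll = observed_loglik(params, [1], np.ones((1, 1)), [0.0], 0.0)
        assert ll == -np.inf


class TestPosterior:
    def test_detection_cannot_be_contamination_when_eps_zero(self):
        params = ModelParameters(beta=np.array([-1.2]),
                                 curve=FixedCurve(prob=0.3))
        p = posterior_presence(params, [1, 1], np.ones((2, 1)), np.zeros(2), 0.0)
        assert np.all(p == 1.0)

    def test_hand_computed_bayes_rule(self):
        # Y=0, f=0.8, eps=0.05, prior 1/2: (0.2*0.5)/(0.2*0.5 + 0.95*0.5)
        params = ModelParameters(beta=np.zeros(1), curve=FixedCurve(prob=0.8))
        p = posterior_presence(params, [0], np.ones((1, 1)), [0.0], 0.05)
        assert p[0] == pytest.approx(0.2 * 0.5 / (0.2 * 0.5 + 0.95 * 0.5),
                                     abs=1e-12)

    def test_posterior_equals_prior_when_detection_uninformative(self, rng):
        eps = 0.2
        X = np.column_stack([np.ones(6), rng.normal(size=6)])
        beta = np.array([0.4, -1.0])
        params = ModelParameters(beta=beta, curve=FixedCurve(prob=eps))
        Y = rng.binomial(1, 0.5, 6)
        p = posterior_presence(params, Y, X, np.zeros(6), eps)
        assert np.allclose(p, expit(X @ beta), atol=1e-12)

    def test_clamping(self):
        params = ModelParameters(beta=np.zeros(1), curve=FixedCurve(prob=1.0))
        p = posterior_presence(params, [1], np.ones((1, 1)), [0.0], 0.0,
                               clamp=True)
        assert p[0] == 1.0 - 1e-10


class TestExpectedPenalizedLoglik:
    def test_weights_collapse_when_posterior_is_one(self, rng):
        n = 12
        Y = rng.binomial(1, 0.6, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        M = rng.uniform(10, 40, n)
        beta = np.array([0.2, 0.5])
        curve = VectorCurve(rng.uniform(0.2, 0.9, n))
        val = expected_penalized_loglik(beta, curve, 0.37, np.ones(n), Y, X, M)
        ftil = curve.eval_logit(M)
        eta = X @ beta
        two_logistic = (np.sum(Y * ftil - np.logaddexp(0, ftil))
                        + np.sum(eta - np.logaddexp(0, eta)))
        assert val == pytest.approx(two_logistic + firth_penalty(beta, X),
                                    abs=1e-10)

    @pytest.mark.parametrize("n", [5, 20, 100])
    def test_firth_term_closed_form_intercept_only(self, n):
        # beta=0 intercept-only: 0.5 * log(n * 0.25)
        assert firth_penalty(np.zeros(1), np.ones((n, 1))) == pytest.approx(
            0.5 * np.log(n * 0.25), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_m_step_blocks_never_decrease_their_terms(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        config = HappiConfig(epsilon=0.0)
        Y = rng.binomial(1, 0.5, n).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        M = np.sort(rng.uniform(10, 40, n))
        p = np.clip(rng.uniform(size=n), 1e-10, 1 - 1e-10)
        basis = ISplineBasis.from_data(M, config.spline_df, config.spline_degree)
        curve0 = update_f_ispline(M, np.ones(n) * 0.5, 1 - Y, config, basis=basis)
        beta0 = rng.normal(size=2) * 0.1

        def objective(beta, curve):
            return expected_penalized_loglik(beta, curve, 0.0, p, Y, X, M)

        beta1, _ = update_beta_firth(X, p, beta0=beta0)
        assert objective(beta1, curve0) >= objective(beta0, curve0) - 1e-8
        curve1 = update_f_ispline(M, p, Y, config, basis=basis)
        assert objective(beta1, curve1) >= objective(beta1, curve0) - 1e-8


class TestFirthUpdate:
    def test_symmetric_fractional_outcomes_give_zero(self):
        beta, conv = update_beta_firth(np.ones((8, 1)), np.full(8, 0.5))
        assert conv and beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_finite_under_perfect_separation(self):
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        p = np.array([0.01, 0.01, 0.99, 0.99])
        beta, _ = update_beta_firth(X, p)
        assert np.all(np.isfinite(beta)) and abs(beta[1]) < 20

    def test_matches_grid_search_oracle(self, rng):
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        p = np.clip(rng.uniform(size=n), 0.01, 0.99)
        beta, conv = update_beta_firth(X, p)
        assert conv

        def neg_obj(b):
            eta = X @ b
            return -(np.sum(p * eta - np.logaddexp(0, eta))
                     + firth_penalty(b, X))

        res = minimize(neg_obj, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        assert beta == pytest.approx(res.x, abs=1e-6)

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError):
            update_beta_firth(X, np.full(5, 0.5))


class TestISplineUpdate:
    def test_recovers_constant_truth(self, rng):
        n = 200
        config = HappiConfig()
        M = np.linspace(10, 40, n)
        # Y independent of M, balanced halves
        Y = np.tile([1.0, 1.0, 0.0, 1.0], n // 4)
        curve = update_f_ispline(M, np.ones(n), Y, config)
        probs = curve.eval_prob(np.linspace(10, 40, 21))
        assert np.all(np.abs(probs - Y.mean()) < 1e-3)

    def test_all_detected_hits_logit_cap(self):
        config = HappiConfig()
        n = 30
        curve = update_f_ispline(np.linspace(10, 40, n), np.ones(n),
                                 np.ones(n), config)
        assert np.all(curve.eval_prob(np.linspace(10, 40, 7))
                      >= expit(config.logit_cap - 1e-6))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_general_constrained_optimizer(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        config = HappiConfig()
        M = rng.uniform(10, 40, n)
        p = rng.uniform(0.05, 1.0, n)
        Y = rng.binomial(1, 0.6, n).astype(float)
        curve = update_f_ispline(M, p, Y, config)
        D = np.column_stack([np.ones(n), curve.basis.design(M)])
        res = minimize(
            lambda a: -_weighted_logistic_obj(a, D, p, Y),
            np.zeros(D.shape[1]),
            bounds=[(None, None)] + [(0, None)] * curve.basis.n_basis,
            method="L-BFGS-B",
            options={"maxfun": 50000, "ftol": 1e-15, "gtol": 1e-12},
        )
        mine = _weighted_logistic_obj(curve.alpha, D, p, Y)
        assert mine >= -res.fun - 1e-6


class TestIsotoneUpdate:
    def test_pooled_constant_solution_matches_root_find(self):
        config = HappiConfig()
        n = 16
        M = np.linspace(10, 40, n)
        p = np.full(n, 0.6)
        Y = np.ones(n)
        curve = update_f_isotone(M, p, Y, config)
        assert np.ptp(curve.values) == 0.0
        a = config.cosh_a

        def pooled_score(v):
            return (np.sum(p * (Y - expit(v)))
                    - n * np.sinh((v / a) ** 2) * 2 * v / a**2)

        root = brentq(pooled_score, -60, 60, xtol=1e-10)
        assert curve.values[0] == pytest.approx(root, abs=1e-8)

    def test_no_violators_keeps_pointwise_solutions(self):
        # increasing p*Y pattern whose per-point optima are already sorted
        config = HappiConfig()
        M = np.array([10.0, 20.0, 30.0])
        p = np.ones(3)
        Y = np.array([0.0, 1.0, 1.0])
        curve = update_f_isotone(M, p, Y, config)
        # every fitted value equals its isolated (unpooled) solution
        for j in range(3):
            single = update_f_isotone(M[j:j + 1], p[j:j + 1], Y[j:j + 1],
                                      config)
            assert curve.values[j] == pytest.approx(single.values[0], abs=1e-8)
        assert np.all(np.diff(curve.values) >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_and_ties_share_values(self, seed):
        rng = np.random.default_rng(seed)
        config = HappiConfig()
        M = rng.choice(np.linspace(10, 40, 8), size=40)  # forced ties
        p = rng.uniform(0.01, 1.0, 40)
        Y = rng.binomial(1, 0.5, 40).astype(float)
        curve = update_f_isotone(M, p, Y, config)
        assert np.all(np.diff(curve.values) >= 0)
        assert curve.breakpoints.size == np.unique(M).size

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_general_constrained_optimizer(self, seed):
        from scipy.optimize import LinearConstraint

        rng = np.random.default_rng(seed)
        config = HappiConfig()
        n = 20
        M = np.sort(rng.uniform(10, 40, n))
        p = rng.uniform(0.05, 1.0, n)
        Y = rng.binomial(1, 0.6, n).astype(float)
        curve = update_f_isotone(M, p, Y, config)

        def neg_obj(v):
            return -np.sum(p * (Y * v - np.logaddexp(0, v))
                           - np.cosh((v / config.cosh_a) ** 2))

        A = np.eye(n - 1, n, k=1) - np.eye(n - 1, n)
        res = minimize(neg_obj, np.zeros(n), method="SLSQP",
                       constraints=[LinearConstraint(A, 0, np.inf)],
                       options={"maxiter": 800, "ftol": 1e-14})
        # raw fitted values (before the evaluation-time logit cap)
        assert -neg_obj(curve.values) >= -res.fun - 1e-6
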