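"""Likelihoods and priors: scalar reference functions and the vectorized
posterior targets, checked against independent term-by-term oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import expit, logit

import facetrait as ft
from facetrait.model_core import (
    ChoiceModelPosterior,
    ZIBPosterior,
    choice_loglik,
    linear_predictor,
    log_prior,
    zib_loglik,
    zib_params,
)


def _coeffs(alpha, beta, **kw):
    return ft.CoefficientSet(alpha=np.asarray(alpha, float), beta=np.asarray(beta, float), **kw)


class TestLinearPredictor:
    def test_zero_case(self):
        c = _coeffs(np.zeros(6), np.zeros((6, 3)))
        assert linear_predictor(c, "happiness", np.zeros(3)) == 0.0

    def test_direct_substitution(self):
        beta = np.zeros((6, 3))
        beta[0] = [1.0, 2.0, 3.0]
        c = _coeffs([1, 0, 0, 0, 0, 0], beta)
        assert linear_predictor(c, "happiness", [0.5, 0.0, 0.0]) == pytest.approx(1.5)

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(3)
        c = _coeffs(
            rng.normal(size=6), rng.normal(size=(6, 5)),
            r_subj={"p1": rng.normal(size=6)}, r_stim={"v1": rng.normal(size=6)},
        )
        x = rng.normal(size=5)
        for k, label in enumerate(ft.EXPRESSIONS):
            expected = c.alpha[k]
            for p in range(5):
                expected += x[p] * c.beta[k, p]
            expected += c.r_subj["p1"][k] + c.r_stim["v1"][k]
            got = linear_predictor(c, label, x, "p1", "v1")
            assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_id_rejected(self):
        c = _coeffs(np.zeros(6), np.zeros((6, 3)), r_subj={"p1": np.zeros(6)})
        with pytest.raises(ValueError):
            linear_predictor(c, "fear", np.zeros(3), subj_id="nobody")


def _trial(chosen="happiness"):
    return ft.TrialRecord("s", "p", "v", "happiness", chosen, 4)


class TestChoiceLoglik:
    def test_all_zero_predictors(self):
        c = _coeffs(np.zeros(6), np.zeros((6, 3)))
        assert choice_loglik(c, _trial(), np.zeros(3)) == pytest.approx(6 * math.log(0.5))

    def test_saturated_limit(self):
        alpha = np.full(6, -40.0)
        alpha[0] = 40.0
        c = _coeffs(alpha, np.zeros((6, 3)))
        assert choice_loglik(c, _trial("happiness"), np.zeros(3)) == pytest.approx(0.0, abs=1e-9)

    def test_scalar_evaluation_oracle(self):
        alpha = np.array([1.0, -1.0, 0, 0, 0, 0])
        c = _coeffs(alpha, np.zeros((6, 3)))
        expected = (
            math.log(expit(1.0)) + math.log(1 - expit(-1.0)) + 4 * math.log(0.5)
        )
        assert choice_loglik(c, _trial("happiness"), np.zeros(3)) == pytest.approx(expected)

    def test_decomposes_into_six_bernoullis(self):
        rng = np.random.default_rng(9)
        c = _coeffs(rng.normal(size=6), rng.normal(size=(6, 3)))
        x = rng.uniform(0, 1, 3)
        trial = _trial("disgust")
        total = choice_loglik(c, trial, x)
        y = trial.one_hot()
        oracle = 0.0
        for k, label in enumerate(ft.EXPRESSIONS):
            mu = linear_predictor(c, label, x)
            p = expit(mu)
            oracle += math.log(p) if y[k] else math.log(1 - p)
        assert total == pytest.approx(oracle, rel=1e-12)


class TestZIBParams:
    def _zc(self, **kw):
        defaults = dict(
            alpha_zero=np.zeros(3), beta_zero=np.zeros((3, 5)),
            alpha_beta=np.zeros(3), beta_beta=np.zeros((3, 5)), phi=10.0,
        )
        defaults.update(kw)
        return ft.ZIBCoefficientSet(**defaults)

    def test_zero_coefficients(self):
        q, a, b = zib_params(self._zc(), "upper", np.zeros(5))
        assert (q, a, b) == (0.5, 5.0, 5.0)

    def test_substitution(self):
        zc = self._zc(alpha_beta=np.full(3, float(logit(0.3))))
        q, a, b = zib_params(zc, "middle", np.zeros(5))
        assert a == pytest.approx(3.0) and b == pytest.approx(7.0)

    @pytest.mark.parametrize("phi", [0.5, 2.0, 10.0, 77.7])
    def test_shape_parameters_sum_to_phi(self, phi):
        rng = np.random.default_rng(int(phi * 10))
        zc = self._zc(
            alpha_beta=rng.normal(size=3), beta_beta=rng.normal(size=(3, 5)), phi=phi
        )
        traits = rng.uniform(1, 7, 5)
        for area in ft.AREAS:
            q, a, b = zib_params(zc, area, traits)
            assert a + b == pytest.approx(phi, rel=1e-12)
            assert a / phi == pytest.approx(a / (a + b))  # Beta mean is mu

    def test_invalid_phi_rejected(self):
        zc = self._zc()
        zc.phi = -2.0
        with pytest.raises(ValueError):
            zib_params(zc, "upper", np.zeros(5))


class TestZIBLoglik:
    def test_zero_branch(self):
        assert zib_loglik(0.5, 2.0, 2.0, 0.0) == pytest.approx(math.log(0.5))

    def test_uniform_beta_limit(self):
        assert zib_loglik(1 - 1e-12, 1.0, 1.0, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_beta_case(self):
        # Beta(2,2) density at 0.25 is 6 * 0.25 * 0.75; with q = 0.8 the
        # density is 0.8 * 1.125 = 0.9
        assert zib_loglik(0.8, 2.0, 2.0, 0.25) == pytest.approx(math.log(0.9), rel=1e-12)

    @pytest.mark.parametrize("g", [-0.1, 1.0, 1.5])
    def test_support_enforced(self, g):
        with pytest.raises(ValueError):
            zib_loglik(0.5, 2.0, 2.0, g)

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.8])
    @pytest.mark.parametrize("ab", [(1.0, 1.0), (2.0, 5.0), (0.5, 0.7), (5.0, 2.0)])
    def test_density_normalizes_to_one(self, q, ab):
        a, b = ab
        cont, _ = integrate.quad(
            lambda g: math.exp(zib_loglik(q, a, b, g)), 0.0, 1.0, limit=200
        )
        total = math.exp(zib_loglik(q, a, b, 0.0)) + cont
        assert total == pytest.approx(1.0, abs=1e-8)


class TestLogPrior:
    def test_empty_set_is_zero(self):
        assert log_prior(None) == 0.0

    def test_matches_scipy_transcription(self):
        rng = np.random.default_rng(5)
        c = _coeffs(
            rng.normal(size=6), rng.normal(size=(6, 3)),
            sd_subj=0.8, sd_stim=1.3,
            r_subj={"p1": rng.normal(size=6), "p2": rng.normal(size=6)},
            r_stim={"v1": rng.normal(size=6)},
        )
        expected = stats.norm.logpdf(c.alpha, 0, 10).sum()
        expected += stats.norm.logpdf(c.beta, 0, 10).sum()
        for sd, effects in ((c.sd_subj, c.r_subj), (c.sd_stim, c.r_stim)):
            expected += stats.gamma.logpdf(sd, a=10, scale=1 / 10)
            for r in effects.values():
                expected += stats.norm.logpdf(r, 0, sd).sum()
        assert log_prior(c) == pytest.approx(expected, rel=1e-12)

    def test_single_fixed_effect_mode_density(self):
        c = _coeffs(np.zeros(6), np.zeros((6, 3)))
        per_coef = -math.log(10 * math.sqrt(2 * math.pi))
        base = log_prior(c)
        # 6 + 18 fixed effects at zero, plus the two gamma scale terms
        gamma_terms = 2 * stats.gamma.logpdf(0.3, a=10, scale=1 / 10)
        assert base == pytest.approx(24 * per_coef + gamma_terms, rel=1e-12)

    def test_gamma_mode_maximizes_scale_contribution(self):
        grid = [0.3, 0.6, 0.9, 1.2, 2.0]
        vals = [
            log_prior(_coeffs(np.zeros(6), np.zeros((6, 3)), sd_subj=s, sd_stim=1.0))
            for s in grid
        ]
        assert grid[int(np.argmax(vals))] == 0.9

    def test_zib_prior_includes_phi(self):
        zc = ft.ZIBCoefficientSet(
            alpha_zero=np.zeros(3), beta_zero=np.zeros((3, 5)),
            alpha_beta=np.zeros(3), beta_beta=np.zeros((3, 5)), phi=4.0,
        )
        expected = 36 * stats.norm.logpdf(0, 0, 10)
        expected += 4 * stats.gamma.logpdf(0.3, a=10, scale=1 / 10)
        expected += stats.gamma.logpdf(4.0, a=2, scale=1 / 0.1)
        assert log_prior(zc) == pytest.approx(expected, rel=1e-12)


class TestVectorizedPosteriors:
    """The sampler targets must agree with finite differences and with the
    scalar reference likelihood."""

    def _choice_target(self, rng, n=25, S=4, J=3):
        X = rng.uniform(0, 0.6, (n, 3))
        si = rng.integers(0, S, n)
        ji = rng.integers(0, J, n)
        Y = np.eye(6)[rng.integers(0, 6, n)]
        return ChoiceModelPosterior(X, si, ji, Y), X, si, ji, Y

    def test_choice_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        target, *_ = self._choice_target(rng)
        theta = target.initial(rng)
        _, grad = target.logp_and_grad(theta)
        eps = 1e-6
        for i in rng.choice(target.dim, size=25, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (target.logp(tp) - target.logp(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_zib_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        n = 25
        X = rng.uniform(1, 7, (n, 5))
        G = rng.uniform(0.05, 0.8, (n, 3)) * (rng.random((n, 3)) < 0.7)
        target = ZIBPosterior(X, rng.integers(0, 4, n), rng.integers(0, 3, n), G)
        theta = target.initial(rng)
        _, grad = target.logp_and_grad(theta)
        eps = 1e-6
        for i in rng.choice(target.dim, size=25, replace=False):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (target.logp(tp) - target.logp(tm)) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_choice_posterior_matches_scalar_reference(self):
        """Vectorized log-posterior == sum of scalar trial log-likelihoods
        plus the log-prior of the equivalent natural-scale coefficients."""
        rng = np.random.default_rng(2)
        target, X, si, ji, Y = self._choice_target(rng, n=12, S=3, J=2)
        theta = target.initial(rng)
        p = target.unpack(theta)
        sd_s, sd_j = math.exp(float(p["log_sd_subj"])), math.exp(float(p["log_sd_stim"]))
        coeffs = ft.CoefficientSet(
            alpha=p["alpha"], beta=p["beta"], sd_subj=sd_s, sd_stim=sd_j,
            r_subj={str(i): sd_s * p["z_subj"][i] for i in range(3)},
            r_stim={str(j): sd_j * p["z_stim"][j] for j in range(2)},
        )
        loglik = 0.0
        for t in range(12):
            chosen = ft.EXPRESSIONS[int(np.argmax(Y[t]))]
            trial = ft.TrialRecord("s", str(si[t]), str(ji[t]), "happiness", chosen, 4)
            loglik += choice_loglik(coeffs, trial, X[t])
        # the non-centered prior differs from the natural-scale one only by
        # the z <-> r change of variables: N(z|0,1) = N(r|0,sd) * sd
        prior = log_prior(coeffs)
        z_prior_correction = 0.0
        for block, sd in (("z_subj", sd_s), ("z_stim", sd_j)):
            z_prior_correction += p[block].size * math.log(sd)
        # sampled scale enters through log-sd with Jacobian sd
        log_sd_jacobian = math.log(sd_s) + math.log(sd_j)
        expected = loglik + prior + z_prior_correction + log_sd_jacobian
        got, _ = target.logp_and_grad(theta)
        assert got == pytest.approx(expected, rel=1e-10)
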