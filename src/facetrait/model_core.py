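"""Likelihoods and priors for the three analyses, as pure functions.

Three models are defined, all fit separately per presented-expression
condition:

* choice ~ observation behavior (variant "A"): for each trial the six
  possible responses carry independent Bernoulli indicators y_k with
  logit(p_k) = alpha_k + sum_g G_g * beta_kg + r_subj + r_stim, where G is
  the (upper, middle, low) attention-weight triple.
* choice ~ personality (variant "B"): same likelihood with the five Big-Five
  scores P_p as predictors.
* behavior ~ personality (the zero-inflated beta model): each band weight G
  is zero with probability 1 - q, else Beta(a, b) with a = phi*mu,
  b = phi*(1 - mu); both logit(q) and logit(mu) are linear in the traits
  with participant and stimulus random effects.

The scalar functions here mirror the written model term by term and are the
reference the vectorized posterior classes (used by the sampler) are tested
against. The choice likelihood is deliberately the independent-Bernoulli
product, not a softmax; a categorical variant is available behind a flag for
sensitivity analysis only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, expit, gammaln

from .types import (
    AREAS,
    EXPRESSIONS,
    TRAITS,
    CoefficientSet,
    PriorConfig,
    TrialRecord,
    ZIBCoefficientSet,
)

_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)


def _normal_logpdf(x: np.ndarray | float, sd: float) -> np.ndarray | float:
    return -0.5 * (np.asarray(x, dtype=float) / sd) ** 2 - math.log(sd) - _HALF_LOG_2PI


def _gamma_logpdf(x: float, shape: float, rate: float) -> float:
    if x <= 0:
        return -math.inf
    return shape * math.log(rate) - gammaln(shape) + (shape - 1.0) * math.log(x) - rate * x


def _lookup(effects: dict, key, width: int) -> np.ndarray:
    """Random-effect lookup: None or an empty effect family -> zeros;
    an unknown id in a populated family -> error."""
    if key is None or not effects:
        return np.zeros(width)
    try:
        return np.asarray(effects[key], dtype=float)
    except KeyError:
        raise ValueError(f"unknown participant/stimulus id {key!r}") from None


def linear_predictor(
    coeffs: CoefficientSet,
    expression_k: str,
    predictors: np.ndarray,
    subj_id: str | None = None,
    stim_id: str | None = None,
) -> float:
    """mu_ijk = alpha_k + sum_p predictors_p * beta_kp + r_subj + r_stim."""
    k = EXPRESSIONS.index(expression_k)
    predictors = np.asarray(predictors, dtype=float)
    if predictors.shape != (coeffs.n_predictors,):
        raise ValueError(
            f"expected {coeffs.n_predictors} predictors, got {predictors.shape}"
        )
    r_s = _lookup(coeffs.r_subj, subj_id, len(EXPRESSIONS))[k]
    r_j = _lookup(coeffs.r_stim, stim_id, len(EXPRESSIONS))[k]
    return float(coeffs.alpha[k] + predictors @ coeffs.beta[k] + r_s + r_j)


def choice_loglik(
    coeffs: CoefficientSet,
    trial: TrialRecord,
    predictors: np.ndarray,
    categorical: bool = False,
) -> float:
    """Log-likelihood of one trial's chosen label.

    Default is the independent-Bernoulli product over the six responses:
    sum_k log Bernoulli(y_k | logit^-1(mu_ijk)), y_k = 1 iff chosen = k.
    With ``categorical=True`` the six Bernoulli probabilities are normalized
    to a categorical law instead (sensitivity analysis only).
    """
    mu = np.array(
        [
            linear_predictor(coeffs, k, predictors, trial.participant_id, trial.stimulus_id)
            for k in EXPRESSIONS
        ]
    )
    if not np.all(np.isfinite(mu)):
        return -math.inf
    y = trial.one_hot()
    if categorical:
        p = expit(mu)
        return float(np.log(p[y == 1.0].item()) - np.log(p.sum()))
    # y*mu - log(1 + exp(mu)) is the stable Bernoulli-logit form
    return float(np.sum(y * mu - np.logaddexp(0.0, mu)))


def zib_params(
    coeffs: ZIBCoefficientSet,
    area_k: str,
    traits: np.ndarray,
    subj_id: str | None = None,
    stim_id: str | None = None,
) -> tuple[float, float, float]:
    """(q, a, b) of the zero-inflated beta law for one band and participant.

    q is the probability of a NONZERO observation; a = phi*mu, b = phi*(1-mu)
    so that a + b = phi and the Beta mean is mu.
    """
    if coeffs.phi <= 0:
        raise ValueError("phi must be positive")
    k = AREAS.index(area_k)
    traits = np.asarray(traits, dtype=float)
    if traits.shape != (len(TRAITS),):
        raise ValueError(f"expected {len(TRAITS)} trait scores, got {traits.shape}")
    eta_q = (
        coeffs.alpha_zero[k]
        + traits @ coeffs.beta_zero[k]
        + _lookup(coeffs.r_subj_zero, subj_id, len(AREAS))[k]
        + _lookup(coeffs.r_stim_zero, stim_id, len(AREAS))[k]
    )
    eta_m = (
        coeffs.alpha_beta[k]
        + traits @ coeffs.beta_beta[k]
        + _lookup(coeffs.r_subj_beta, subj_id, len(AREAS))[k]
        + _lookup(coeffs.r_stim_beta, stim_id, len(AREAS))[k]
    )
    q = float(expit(eta_q))
    mu = float(expit(eta_m))
    return q, coeffs.phi * mu, coeffs.phi * (1.0 - mu)


def zib_loglik(q: float, a: float, b: float, g: float) -> float:
    """Log zero-inflated-beta density at a band weight g in [0, 1).

    g = 0 contributes log(1 - q); g > 0 contributes
    log q + log Beta(g; a, b). Weights of exactly 1 must be clamped upstream.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly in (0, 1)")
    if a <= 0 or b <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if g < 0 or g >= 1:
        raise ValueError("band weight must lie in [0, 1)")
    if g == 0.0:
        return math.log1p(-q)
    log_beta = (
        (a - 1.0) * math.log(g)
        + (b - 1.0) * math.log1p(-g)
        - (gammaln(a) + gammaln(b) - gammaln(a + b))
    )
    return math.log(q) + float(log_beta)


def log_prior(
    coeffs: CoefficientSet | ZIBCoefficientSet | None,
    config: PriorConfig | None = None,
) -> float:
    """Joint log-prior of one coefficient set (empty set -> 0).

    Normal(0, sd 10) on intercepts and fixed effects; gamma(10, 10) on each
    random-effect scale; normal(0, scale) on the random effects themselves;
    gamma(2, 0.1) on the Beta precision phi.
    """
    if coeffs is None:
        return 0.0
    config = config or PriorConfig()
    total = 0.0
    if isinstance(coeffs, CoefficientSet):
        fixed = [coeffs.alpha, coeffs.beta]
        scale_blocks = [
            (coeffs.sd_subj, coeffs.r_subj),
            (coeffs.sd_stim, coeffs.r_stim),
        ]
    else:
        fixed = [coeffs.alpha_zero, coeffs.beta_zero, coeffs.alpha_beta, coeffs.beta_beta]
        scale_blocks = [
            (coeffs.sd_subj_zero, coeffs.r_subj_zero),
            (coeffs.sd_stim_zero, coeffs.r_stim_zero),
            (coeffs.sd_subj_beta, coeffs.r_subj_beta),
            (coeffs.sd_stim_beta, coeffs.r_stim_beta),
        ]
        total += _gamma_logpdf(coeffs.phi, config.phi_shape, config.phi_rate)
    for block in fixed:
        total += float(np.sum(_normal_logpdf(block, config.fixed_effect_sd)))
    for scale, effects in scale_blocks:
        if scale <= 0:
            return -math.inf
        total += _gamma_logpdf(scale, config.random_scale_shape, config.random_scale_rate)
        for r in effects.values():
            total += float(np.sum(_normal_logpdf(np.asarray(r) / scale, 1.0) - math.log(scale)))
    return total


# ---------------------------------------------------------------------------
# Vectorized log-posteriors with analytic gradients (sampler targets)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamBlock:
    name: str
    shape: tuple[int, ...]

    @property
    def size(self) -> int:
        return int(np.prod(self.shape)) if self.shape else 1


class _PackedPosterior:
    """Shared packing/unpacking over a flat parameter vector."""

    blocks: list[ParamBlock]

    @property
    def dim(self) -> int:
        return sum(b.size for b in self.blocks)

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        pos = 0
        for b in self.blocks:
            out[b.name] = theta[pos : pos + b.size].reshape(b.shape)
            pos += b.size
        return out

    def pack(self, params: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.ravel(params[b.name]) for b in self.blocks])

    def logp(self, theta: np.ndarray) -> float:
        return self.logp_and_grad(theta)[0]

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError


def _scatter_sum(values: np.ndarray, index: np.ndarray, n: int) -> np.ndarray:
    """Sum rows of ``values`` (n_obs, k) into groups given by ``index``."""
    out = np.zeros((n, values.shape[1]))
    np.add.at(out, index, values)
    return out


class ChoiceModelPosterior(_PackedPosterior):
    """Log-posterior of one choice-model condition, on unconstrained scale.

    Random effects are non-centered (r = sd * z with z standard normal) and
    the scales are sampled as log(sd) with the Jacobian folded in, which
    keeps the geometry well-conditioned for gradient-based MCMC.

    Parameters
    ----------
    X : (n_trials, n_predictors) predictor matrix (weights or traits).
    subj_idx, stim_idx : integer group indices per trial.
    Y : (n_trials, 6) one-hot chosen-response indicators.
    """

    def __init__(
        self,
        X: np.ndarray,
        subj_idx: np.ndarray,
        stim_idx: np.ndarray,
        Y: np.ndarray,
        prior: PriorConfig | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.subj_idx = np.asarray(subj_idx, dtype=np.intp)
        self.stim_idx = np.asarray(stim_idx, dtype=np.intp)
        self.Y = np.asarray(Y, dtype=float)
        self.prior = prior or PriorConfig()
        n, p = self.X.shape
        if self.Y.shape != (n, len(EXPRESSIONS)):
            raise ValueError("Y must be one-hot over the six expressions")
        self.n_subj = int(self.subj_idx.max()) + 1 if n else 0
        self.n_stim = int(self.stim_idx.max()) + 1 if n else 0
        K = len(EXPRESSIONS)
        self.blocks = [
            ParamBlock("alpha", (K,)),
            ParamBlock("beta", (K, p)),
            ParamBlock("z_subj", (self.n_subj, K)),
            ParamBlock("z_stim", (self.n_stim, K)),
            ParamBlock("log_sd_subj", ()),
            ParamBlock("log_sd_stim", ()),
        ]

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.dim)
        return theta

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e3:
            return -math.inf, np.zeros_like(theta)  # divergent trajectory
        p = self.unpack(theta)
        pr = self.prior
        sd_s = math.exp(float(p["log_sd_subj"]))
        sd_j = math.exp(float(p["log_sd_stim"]))
        mu = (
            p["alpha"][None, :]
            + self.X @ p["beta"].T
            + sd_s * p["z_subj"][self.subj_idx]
            + sd_j * p["z_stim"][self.stim_idx]
        )
        loglik = float(np.sum(self.Y * mu - np.logaddexp(0.0, mu)))
        D = self.Y - expit(mu)  # d loglik / d mu

        g_alpha = D.sum(axis=0)
        g_beta = D.T @ self.X
        acc_s = _scatter_sum(D, self.subj_idx, self.n_subj)
        acc_j = _scatter_sum(D, self.stim_idx, self.n_stim)
        g_z_subj = sd_s * acc_s
        g_z_stim = sd_j * acc_j
        g_usd_s = sd_s * float(np.sum(acc_s * p["z_subj"]))
        g_usd_j = sd_j * float(np.sum(acc_j * p["z_stim"]))

        # priors: normal(0, sd 10) fixed effects, N(0,1) on z, gamma on scales
        v = pr.fixed_effect_sd**2
        logp = loglik
        logp += float(np.sum(_normal_logpdf(p["alpha"], pr.fixed_effect_sd)))
        logp += float(np.sum(_normal_logpdf(p["beta"], pr.fixed_effect_sd)))
        logp += float(np.sum(_normal_logpdf(p["z_subj"], 1.0)))
        logp += float(np.sum(_normal_logpdf(p["z_stim"], 1.0)))
        a, r = pr.random_scale_shape, pr.random_scale_rate
        for u, sd in ((float(p["log_sd_subj"]), sd_s), (float(p["log_sd_stim"]), sd_j)):
            logp += a * math.log(r) - float(gammaln(a)) + a * u - r * sd
        g_alpha -= p["alpha"] / v
        g_beta -= p["beta"] / v
        g_z_subj -= p["z_subj"]
        g_z_stim -= p["z_stim"]
        g_usd_s += a - r * sd_s
        g_usd_j += a - r * sd_j

        grad = self.pack(
            {
                "alpha": g_alpha,
                "beta": g_beta,
                "z_subj": g_z_subj,
                "z_stim": g_z_stim,
                "log_sd_subj": np.asarray(g_usd_s),
                "log_sd_stim": np.asarray(g_usd_j),
            }
        )
        return logp, grad

    def constrain(self, params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Map unconstrained parameters to the natural-scale coefficients."""
        sd_s = np.exp(params["log_sd_subj"])
        sd_j = np.exp(params["log_sd_stim"])
        return {
            "alpha": params["alpha"],
            "beta": params["beta"],
            "sd_subj": sd_s,
            "sd_stim": sd_j,
            "r_subj": sd_s[..., None, None] * params["z_subj"]
            if np.ndim(sd_s)
            else sd_s * params["z_subj"],
            "r_stim": sd_j[..., None, None] * params["z_stim"]
            if np.ndim(sd_j)
            else sd_j * params["z_stim"],
        }


class ZIBPosterior(_PackedPosterior):
    """Log-posterior of the behavior ~ traits zero-inflated-beta condition.

    Data are per (participant, stimulus) session: a (n, 5) trait matrix and
    a (n, 3) matrix of band weights in [0, 1), zeros marking bands never
    visited. Zero and beta blocks each carry their own random effects and
    scales; phi is shared across the three bands and sampled as log(phi).
    """

    def __init__(
        self,
        X: np.ndarray,
        subj_idx: np.ndarray,
        stim_idx: np.ndarray,
        G: np.ndarray,
        prior: PriorConfig | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.subj_idx = np.asarray(subj_idx, dtype=np.intp)
        self.stim_idx = np.asarray(stim_idx, dtype=np.intp)
        G = np.asarray(G, dtype=float)
        if np.any(G < 0) or np.any(G >= 1):
            raise ValueError("band weights must lie in [0, 1); clamp upstream")
        self.G = G
        self.prior = prior or PriorConfig()
        n, p = self.X.shape
        K = len(AREAS)
        if G.shape != (n, K):
            raise ValueError("G must have one column per face band")
        self.nonzero = G > 0
        self.log_g = np.where(self.nonzero, np.log(np.where(self.nonzero, G, 0.5)), 0.0)
        self.log_1mg = np.where(self.nonzero, np.log1p(-np.where(self.nonzero, G, 0.5)), 0.0)
        self.n_subj = int(self.subj_idx.max()) + 1 if n else 0
        self.n_stim = int(self.stim_idx.max()) + 1 if n else 0
        self.blocks = []
        for part in ("zero", "beta"):
            self.blocks += [
                ParamBlock(f"alpha_{part}", (K,)),
                ParamBlock(f"beta_{part}", (K, p)),
                ParamBlock(f"z_subj_{part}", (self.n_subj, K)),
                ParamBlock(f"z_stim_{part}", (self.n_stim, K)),
                ParamBlock(f"log_sd_subj_{part}", ()),
                ParamBlock(f"log_sd_stim_{part}", ()),
            ]
        self.blocks.append(ParamBlock("log_phi", ()))

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.dim)
        theta[-1] = math.log(5.0) + 0.1 * rng.standard_normal()
        return theta

    def _eta(self, p: dict[str, np.ndarray], part: str) -> tuple[np.ndarray, float, float]:
        sd_s = math.exp(float(p[f"log_sd_subj_{part}"]))
        sd_j = math.exp(float(p[f"log_sd_stim_{part}"]))
        eta = (
            p[f"alpha_{part}"][None, :]
            + self.X @ p[f"beta_{part}"].T
            + sd_s * p[f"z_subj_{part}"][self.subj_idx]
            + sd_j * p[f"z_stim_{part}"][self.stim_idx]
        )
        return eta, sd_s, sd_j

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        if not np.all(np.isfinite(theta)) or np.max(np.abs(theta)) > 1e3:
            return -math.inf, np.zeros_like(theta)  # divergent trajectory
        p = self.unpack(theta)
        pr = self.prior
        grads: dict[str, np.ndarray] = {}
        phi = math.exp(float(p["log_phi"]))
        nz = self.nonzero

        # zero part: Bernoulli(nonzero | q) with logit q = eta
        eta_q, sd_sq, sd_jq = self._eta(p, "zero")
        loglik = float(np.sum(nz * eta_q - np.logaddexp(0.0, eta_q)))
        D_q = nz - expit(eta_q)

        # beta part: Beta(g | phi*mu, phi*(1-mu)) on nonzero entries
        eta_m, sd_sm, sd_jm = self._eta(p, "beta")
        m = expit(eta_m)
        a_par = phi * m
        b_par = phi * (1.0 - m)
        log_beta = (
            (a_par - 1.0) * self.log_g
            + (b_par - 1.0) * self.log_1mg
            - gammaln(a_par)
            - gammaln(b_par)
            + gammaln(phi)
        )
        loglik += float(np.sum(np.where(nz, log_beta, 0.0)))
        dl_dm = phi * (self.log_g - self.log_1mg - digamma(a_par) + digamma(b_par))
        D_m = np.where(nz, dl_dm * m * (1.0 - m), 0.0)
        dl_dphi = (
            m * self.log_g
            + (1.0 - m) * self.log_1mg
            - m * digamma(a_par)
            - (1.0 - m) * digamma(b_par)
            + digamma(phi)
        )
        g_log_phi = phi * float(np.sum(np.where(nz, dl_dphi, 0.0)))

        logp = loglik
        v = pr.fixed_effect_sd**2
        a_sc, r_sc = pr.random_scale_shape, pr.random_scale_rate
        for part, D, sd_s, sd_j in (
            ("zero", D_q, sd_sq, sd_jq),
            ("beta", D_m, sd_sm, sd_jm),
        ):
            acc_s = _scatter_sum(D, self.subj_idx, self.n_subj)
            acc_j = _scatter_sum(D, self.stim_idx, self.n_stim)
            grads[f"alpha_{part}"] = D.sum(axis=0) - p[f"alpha_{part}"] / v
            grads[f"beta_{part}"] = D.T @ self.X - p[f"beta_{part}"] / v
            grads[f"z_subj_{part}"] = sd_s * acc_s - p[f"z_subj_{part}"]
            grads[f"z_stim_{part}"] = sd_j * acc_j - p[f"z_stim_{part}"]
            grads[f"log_sd_subj_{part}"] = np.asarray(
                sd_s * float(np.sum(acc_s * p[f"z_subj_{part}"])) + a_sc - r_sc * sd_s
            )
            grads[f"log_sd_stim_{part}"] = np.asarray(
                sd_j * float(np.sum(acc_j * p[f"z_stim_{part}"])) + a_sc - r_sc * sd_j
            )
            logp += float(np.sum(_normal_logpdf(p[f"alpha_{part}"], pr.fixed_effect_sd)))
            logp += float(np.sum(_normal_logpdf(p[f"beta_{part}"], pr.fixed_effect_sd)))
            logp += float(np.sum(_normal_logpdf(p[f"z_subj_{part}"], 1.0)))
            logp += float(np.sum(_normal_logpdf(p[f"z_stim_{part}"], 1.0)))
            for u, sd in (
                (float(p[f"log_sd_subj_{part}"]), sd_s),
                (float(p[f"log_sd_stim_{part}"]), sd_j),
            ):
                logp += a_sc * math.log(r_sc) - float(gammaln(a_sc)) + a_sc * u - r_sc * sd

        # gamma(phi_shape, phi_rate) prior on phi, log scale with Jacobian
        u_phi = float(p["log_phi"])
        logp += (
            pr.phi_shape * math.log(pr.phi_rate)
            - float(gammaln(pr.phi_shape))
            + pr.phi_shape * u_phi
            - pr.phi_rate * phi
        )
        grads["log_phi"] = np.asarray(g_log_phi + pr.phi_shape - pr.phi_rate * phi)
        return logp, self.pack(grads)

    def constrain(self, params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"phi": np.exp(params["log_phi"])}
        for part in ("zero", "beta"):
            sd_s = np.exp(params[f"log_sd_subj_{part}"])
            sd_j = np.exp(params[f"log_sd_stim_{part}"])
            out[f"alpha_{part}"] = params[f"alpha_{part}"]
            out[f"beta_{part}"] = params[f"beta_{part}"]
            out[f"sd_subj_{part}"] = sd_s
            out[f"sd_stim_{part}"] = sd_j
            out[f"r_subj_{part}"] = np.asarray(sd_s)[..., None, None] * params[f"z_subj_{part}"] if np.ndim(sd_s) else sd_s * params[f"z_subj_{part}"]
            out[f"r_stim_{part}"] = np.asarray(sd_j)[..., None, None] * params[f"z_stim_{part}"] if np.ndim(sd_j) else sd_j * params[f"z_stim_{part}"]
        return out
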