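"""Scikit-learn-style estimators wrapping the Bayesian models.

One estimator fit corresponds to one (model variant, presented-expression
condition) pair, matching how the analysis blocks its results. Fitted
attributes follow sklearn conventions (trailing underscore); the posterior
itself lives in ``draws_`` and the HDI significance table in ``summary_``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .inference import MCMCSchedule, PosteriorDraws, run_mcmc, significance_table
from .model_core import ChoiceModelPosterior, ZIBPosterior
from .types import AREAS, EXPRESSIONS, TRAITS, PriorConfig

WEIGHT_COLUMNS = ("w_upper", "w_middle", "w_low")
_CLAMP = 1e-6


def _group_codes(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = pd.Categorical(values)
    return np.asarray(cats.codes), [str(c) for c in cats.categories]


class BayesianChoiceModel(BaseEstimator):
    """Hierarchical Bayesian choice model for one presented expression.

    Six independent Bernoulli response indicators share a linear predictor
    alpha_k + x . beta_k + r_subj + r_stim on the logit scale, with
    participant and stimulus random effects. ``predictors="behavior"``
    (variant A) uses the three band weights; ``predictors="traits"``
    (variant B) uses the five Big-Five scores.

    Parameters
    ----------
    predictors : "behavior" or "traits".
    condition : presented-expression label recorded in the fit metadata.
    chains, warmup, iterations : MCMC schedule (iterations counts warmup +
        retained per chain; the default retains 4 x 1000 = 4000 draws).
    seed : RNG seed for the sampler.
    prior : optional PriorConfig override.

    Attributes
    ----------
    draws_ : PosteriorDraws on the natural scale.
    summary_ : significance table (one row per fixed effect).
    rhat_max_ : max split R-hat over all monitored coefficients.
    """

    def __init__(
        self,
        predictors: str = "behavior",
        condition: str = "happiness",
        chains: int = 4,
        warmup: int = 1000,
        iterations: int = 2000,
        seed: int = 0,
        prior: PriorConfig | None = None,
        target_accept: float = 0.85,
        max_leapfrog: int = 32,
    ):
        self.predictors = predictors
        self.condition = condition
        self.chains = chains
        self.warmup = warmup
        self.iterations = iterations
        self.seed = seed
        self.prior = prior
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog

    @property
    def variant(self) -> str:
        return {"behavior": "A", "traits": "B"}[self.predictors]

    def _predictor_columns(self) -> tuple[str, ...]:
        if self.predictors == "behavior":
            return WEIGHT_COLUMNS
        if self.predictors == "traits":
            return TRAITS
        raise ValueError("predictors must be 'behavior' or 'traits'")

    def fit(self, X: pd.DataFrame, y) -> "BayesianChoiceModel":
        """Fit to per-trial data.

        X must carry ``participant_id``, ``stimulus_id`` and the predictor
        columns; y is the sequence of chosen expression labels.
        """
        cols = self._predictor_columns()
        X = pd.DataFrame(X)
        missing = [c for c in ("participant_id", "stimulus_id", *cols) if c not in X]
        if missing:
            raise ValueError(f"X lacks required columns {missing}")
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        bad = set(y) - set(EXPRESSIONS)
        if bad:
            raise ValueError(f"unknown response labels {sorted(bad)}")
        subj_idx, self.subjects_ = _group_codes(X["participant_id"])
        stim_idx, self.stimuli_ = _group_codes(X["stimulus_id"])
        Y = np.zeros((len(y), len(EXPRESSIONS)))
        for k, label in enumerate(EXPRESSIONS):
            Y[:, k] = y == label
        target = ChoiceModelPosterior(
            X[list(cols)].to_numpy(dtype=float),
            subj_idx,
            stim_idx,
            Y,
            prior=self.prior,
        )
        dims = {
            "alpha": (EXPRESSIONS,),
            "beta": (EXPRESSIONS, cols),
            "r_subj": (tuple(self.subjects_), EXPRESSIONS),
            "r_stim": (tuple(self.stimuli_), EXPRESSIONS),
        }
        self.draws_ = run_mcmc(
            target,
            MCMCSchedule(self.chains, self.warmup, self.iterations),
            seed=self.seed,
            dims=dims,
            meta={"variant": self.variant, "condition": self.condition},
            target_accept=self.target_accept,
            max_leapfrog=self.max_leapfrog,
        )
        self.rhat_max_ = self.draws_.max_rhat()
        self.summary_ = significance_table(self.draws_, "beta", self.condition)
        self.classes_ = np.asarray(EXPRESSIONS, dtype=object)
        self.n_features_in_ = len(cols)
        return self

    def predict_proba(self, X, normalize: bool = True) -> np.ndarray:
        """Population-level posterior-mean response probabilities.

        Random effects are set to zero; per draw the six Bernoulli
        probabilities are (by default) normalized to a categorical law, then
        averaged over the posterior.
        """
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        cols = self._predictor_columns()
        if isinstance(X, pd.DataFrame):
            x = X[list(cols)].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
        alpha = self.draws_.pooled("alpha")  # (N, 6)
        beta = self.draws_.pooled("beta")  # (N, 6, P)
        eta = alpha[:, None, :] + np.einsum("npq,mq->nmp", beta, x)
        p = expit(eta)
        if normalize:
            p = p / p.sum(axis=2, keepdims=True)
        return p.mean(axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class ZeroInflatedBetaModel(BaseEstimator):
    """Zero-inflated beta regression of band weights on Big-Five traits.

    For each face band, the weight is zero with probability 1 - q and
    Beta(phi*mu, phi*(1-mu)) otherwise; logit(q) and logit(mu) are linear
    in the traits with participant and stimulus random effects. One fit per
    presented-expression condition.
    """

    def __init__(
        self,
        condition: str = "happiness",
        chains: int = 4,
        warmup: int = 1000,
        iterations: int = 2000,
        seed: int = 0,
        prior: PriorConfig | None = None,
        target_accept: float = 0.85,
        max_leapfrog: int = 32,
    ):
        self.condition = condition
        self.chains = chains
        self.warmup = warmup
        self.iterations = iterations
        self.seed = seed
        self.prior = prior
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog

    def fit(self, X: pd.DataFrame, y) -> "ZeroInflatedBetaModel":
        """Fit to per-session data.

        X carries ``participant_id``, ``stimulus_id`` and the five trait
        columns; y is an (n, 3) array (or DataFrame with the w_* columns)
        of band weights in [0, 1). Values at or above 1 are clamped just
        below 1 (the Beta support is open).
        """
        X = pd.DataFrame(X)
        missing = [c for c in ("participant_id", "stimulus_id", *TRAITS) if c not in X]
        if missing:
            raise ValueError(f"X lacks required columns {missing}")
        if isinstance(y, pd.DataFrame):
            G = y[list(WEIGHT_COLUMNS)].to_numpy(dtype=float)
        else:
            G = np.asarray(y, dtype=float)
        if G.shape != (len(X), len(AREAS)):
            raise ValueError("y must have one column per face band")
        G = np.where(G >= 1.0, 1.0 - _CLAMP, G)
        subj_idx, self.subjects_ = _group_codes(X["participant_id"])
        stim_idx, self.stimuli_ = _group_codes(X["stimulus_id"])
        target = ZIBPosterior(
            X[list(TRAITS)].to_numpy(dtype=float), subj_idx, stim_idx, G,
            prior=self.prior,
        )
        dims: dict[str, tuple] = {}
        for part in ("zero", "beta"):
            dims[f"alpha_{part}"] = (AREAS,)
            dims[f"beta_{part}"] = (AREAS, TRAITS)
            dims[f"r_subj_{part}"] = (tuple(self.subjects_), AREAS)
            dims[f"r_stim_{part}"] = (tuple(self.stimuli_), AREAS)
        self.draws_ = run_mcmc(
            target,
            MCMCSchedule(self.chains, self.warmup, self.iterations),
            seed=self.seed,
            dims=dims,
            meta={"variant": "C", "condition": self.condition},
            target_accept=self.target_accept,
            max_leapfrog=self.max_leapfrog,
        )
        self.rhat_max_ = self.draws_.max_rhat()
        zero = significance_table(
            self.draws_, "beta_zero", self.condition, response_column="Area",
            extra={"Model": "Bernoulli"},
        )
        beta = significance_table(
            self.draws_, "beta_beta", self.condition, response_column="Area",
            extra={"Model": "Beta"},
        )
        self.summary_ = pd.concat([zero, beta], ignore_index=True)
        self.n_features_in_ = len(TRAITS)
        return self

    def predict(self, X) -> np.ndarray:
        """Posterior-mean expected band weight E[G] = q * mu per band."""
        if not hasattr(self, "draws_"):
            raise ValueError("model is not fitted")
        if isinstance(X, pd.DataFrame):
            x = X[list(TRAITS)].to_numpy(dtype=float)
        else:
            x = np.asarray(X, dtype=float)
        out = []
        for part in ("zero", "beta"):
            alpha = self.draws_.pooled(f"alpha_{part}")
            beta = self.draws_.pooled(f"beta_{part}")
            eta = alpha[:, None, :] + np.einsum("npq,mq->nmp", beta, x)
            out.append(expit(eta))
        return (out[0] * out[1]).mean(axis=0)


def fit_choice_models(
    trials: pd.DataFrame,
    predictors: pd.DataFrame,
    variant: str = "A",
    conditions: tuple[str, ...] = EXPRESSIONS,
    part: int | None = None,
    seed: int = 0,
    **estimator_kwargs,
) -> dict[str, BayesianChoiceModel]:
    """Fit one choice model per presented-expression condition.

    ``predictors`` is the weights table (variant A; joined on session_id)
    or the participants table (variant B; joined on participant_id). Each
    condition gets its own deterministic seed derived from ``seed``.
    """
    kind = {"A": "behavior", "B": "traits"}[variant]
    if part is not None:
        trials = trials[trials["part"] == part]
    if variant == "A":
        data = trials.merge(predictors, on="session_id", suffixes=("", "_w"))
    else:
        data = trials.merge(predictors, on="participant_id")
    fits: dict[str, BayesianChoiceModel] = {}
    for i, cond in enumerate(conditions):
        block = data[data["presented"] == cond]
        if block.empty:
            raise ValueError(f"no trials for condition {cond!r}")
        model = BayesianChoiceModel(
            predictors=kind, condition=cond, seed=seed + 1000 * i, **estimator_kwargs
        )
        fits[cond] = model.fit(block, block["chosen"].to_numpy())
    return fits


def fit_zib_models(
    weights: pd.DataFrame,
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    conditions: tuple[str, ...] = EXPRESSIONS,
    seed: int = 0,
    **estimator_kwargs,
) -> dict[str, ZeroInflatedBetaModel]:
    """Fit one zero-inflated-beta behavior model per condition."""
    data = weights.merge(participants, on="participant_id").merge(
        trials[["session_id", "presented"]], on="session_id"
    )
    fits: dict[str, ZeroInflatedBetaModel] = {}
    for i, cond in enumerate(conditions):
        block = data[data["presented"] == cond]
        if block.empty:
            raise ValueError(f"no sessions for condition {cond!r}")
        model = ZeroInflatedBetaModel(condition=cond, seed=seed + 1000 * i, **estimator_kwargs)
        fits[cond] = model.fit(block, block[list(WEIGHT_COLUMNS)])
    return fits
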