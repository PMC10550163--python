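"""Posterior-predictive summaries: selection-probability tables and
trait sweeps.

Both reports are pure functions of the posterior draws: random effects are
set to zero (population-level prediction), per-draw Bernoulli probabilities
are normalized across the six responses so they compare against the 1/6
chance level, and each summary carries the posterior mean with a 95% HDI.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import PosteriorDraws, hdi
from .types import EXPRESSIONS, TRAITS

CHANCE_LEVEL = 1.0 / len(EXPRESSIONS)


def _per_draw_probabilities(
    draws: PosteriorDraws, profiles: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """(n_draws, 6) response probabilities averaged over predictor profiles."""
    alpha = draws.pooled("alpha")  # (N, 6)
    beta = draws.pooled("beta")  # (N, 6, P)
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != beta.shape[2]:
        raise ValueError(
            f"profiles have {profiles.shape[1]} predictors, model expects {beta.shape[2]}"
        )
    eta = alpha[:, None, :] + np.einsum("npq,mq->nmp", beta, profiles)
    p = expit(eta)
    if normalize:
        p = p / p.sum(axis=2, keepdims=True)
    return p.mean(axis=1)


def selection_probabilities(
    draws: PosteriorDraws,
    condition: str,
    profiles: np.ndarray | pd.DataFrame,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Posterior selection probability of each response for one condition.

    ``profiles`` holds the predictor values to average over (observed
    band-weight triples or trait vectors, one row per profile). The output
    has one row per response with the posterior mean, 95% HDI, the
    unnormalized per-response Bernoulli mean, and the 1/6 chance level.
    """
    if draws.meta.get("condition") != condition:
        raise ValueError(
            f"draws were fit for condition {draws.meta.get('condition')!r}, "
            f"not {condition!r}"
        )
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles.to_numpy(dtype=float)
    p_norm = _per_draw_probabilities(draws, profiles, normalize=True)
    p_raw = _per_draw_probabilities(draws, profiles, normalize=False)
    rows = []
    for k, response in enumerate(EXPRESSIONS):
        interval = hdi(p_norm[:, k], mass)
        rows.append(
            {
                "condition": condition,
                "response": response,
                "mean": float(p_norm[:, k].mean()),
                "hdi_low": interval.lower,
                "hdi_high": interval.upper,
                "bernoulli_mean": float(p_raw[:, k].mean()),
                "chance_level": CHANCE_LEVEL,
            }
        )
    return pd.DataFrame(rows)


def trait_sweep(
    draws: PosteriorDraws,
    condition: str,
    trait: str,
    grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
    mass: float = 0.95,
) -> pd.DataFrame:
    """Selection probabilities as one trait varies over 1..7.

    The swept trait takes each grid value in turn while the other four
    traits are held at zero; requires a trait-predictor (variant B) fit.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if draws.meta.get("variant") != "B":
        raise ValueError("trait_sweep requires a trait-predictor (variant B) fit")
    idx = TRAITS.index(trait)
    rows = []
    for value in grid:
        profile = np.zeros(len(TRAITS))
        profile[idx] = float(value)
        table = selection_probabilities(draws, condition, profile[None, :], mass)
        for rec in table.to_dict("records"):
            rows.append(
                {
                    "condition": condition,
                    "swept_trait": trait,
                    "trait_value": value,
                    "response": rec["response"],
                    "mean": rec["mean"],
                    "hdi_low": rec["hdi_low"],
                    "hdi_high": rec["hdi_high"],
                }
            )
    return pd.DataFrame(rows)
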