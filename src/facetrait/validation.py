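"""Simulation-based validation: convergence studies and parameter recovery.

These drivers exercise the full simulate -> fit loop against known ground
truth: a convergence study fits the behavior-predictor choice model to one
simulated experiment and reports split R-hat over every monitored
coefficient; a recovery study repeats simulate -> fit across replicates and
records, for every fixed effect, whether the 95% HDI covered the generating
value and whether the coefficient was flagged significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimators import WEIGHT_COLUMNS, fit_choice_models
from .inference import MCMCSchedule
from .synthetic import simulate_study
from .types import EXPRESSIONS


def _derived_seed(seed: int, *entropy: int) -> int:
    return int(np.random.SeedSequence([seed, *entropy]).generate_state(1)[0] % (2**31))


def convergence_study(
    n_participants: int = 20,
    n_actors: int = 8,
    seed: int = 0,
    schedule: MCMCSchedule = MCMCSchedule(),
    conditions: tuple[str, ...] = EXPRESSIONS,
    effect_scale: float = 1.0,
) -> pd.DataFrame:
    """Fit the behavior choice model to one simulated experiment.

    Simulates the restricted-viewing part (band weights from the ZIB law,
    choices from the behavior-predictor model with moderate coefficients),
    fits every requested presented-expression condition, and returns one
    row per condition with the max split R-hat over all monitored
    coefficients (fixed effects, random effects, and scales).
    """
    study = simulate_study(
        n_participants=n_participants,
        seed=_derived_seed(seed, 1),
        n_actors=n_actors,
        parts=(2,),
        effect_scale=effect_scale,
    )
    fits = fit_choice_models(
        study.trials,
        study.weights,
        "A",
        conditions,
        seed=_derived_seed(seed, 2),
        chains=schedule.chains,
        warmup=schedule.warmup,
        iterations=schedule.iterations,
    )
    return pd.DataFrame(
        [
            {
                "condition": cond,
                "max_rhat": model.rhat_max_,
                "retained_draws": model.draws_.total_draws,
            }
            for cond, model in fits.items()
        ]
    )


def recovery_study(
    n_replicates: int = 5,
    n_participants: int = 12,
    n_actors: int = 8,
    conditions: tuple[str, ...] = ("happiness",),
    effect_scale: float = 1.0,
    seed: int = 0,
    schedule: MCMCSchedule = MCMCSchedule(chains=2, warmup=400, iterations=800),
) -> pd.DataFrame:
    """Repeated simulate -> fit of the behavior choice model.

    Each replicate draws a fresh ground truth (same fixed-effect pattern
    scaled by ``effect_scale``, fresh random effects), simulates the
    restricted-viewing part, fits, and records per fixed-effect coefficient
    the generating value, posterior mean, 95% HDI, coverage, and
    significance. ``effect_scale=0`` gives the all-zero-truth calibration
    case, where the significant fraction estimates the false-positive rate.
    """
    rows = []
    for rep in range(n_replicates):
        study = simulate_study(
            n_participants=n_participants,
            seed=_derived_seed(seed, 10, rep),
            n_actors=n_actors,
            parts=(2,),
            effect_scale=effect_scale,
        )
        fits = fit_choice_models(
            study.trials,
            study.weights,
            "A",
            conditions,
            seed=_derived_seed(seed, 20, rep),
            chains=schedule.chains,
            warmup=schedule.warmup,
            iterations=schedule.iterations,
        )
        for cond, model in fits.items():
            true_beta = study.truth.choice["A"][cond].beta
            for row in model.summary_.itertuples():
                k = EXPRESSIONS.index(row.Response)
                p = WEIGHT_COLUMNS.index(row.Predictor)
                truth = float(true_beta[k, p])
                rows.append(
                    {
                        "replicate": rep,
                        "condition": cond,
                        "response": row.Response,
                        "predictor": row.Predictor,
                        "true": truth,
                        "mean": row.Mean,
                        "hdi_low": row.HDI_low,
                        "hdi_high": row.HDI_high,
                        "covered": row.HDI_low <= truth <= row.HDI_high,
                        "significant": bool(row.Significant),
                        "max_rhat": model.rhat_max_,
                    }
                )
    return pd.DataFrame(rows)
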