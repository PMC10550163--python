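"""Shared fixtures: a small simulated study and reduced-schedule fits."""

from __future__ import annotations

import numpy as np
import pytest

import facetrait as ft


@pytest.fixture(scope="session")
def small_study() -> ft.SimulatedStudy:
    """4 participants x (2 actors x 6 expressions) x both parts."""
    return ft.simulate_study(n_participants=4, seed=7, n_actors=2, parts=(1, 2))


@pytest.fixture(scope="session")
def choice_fit(small_study) -> ft.BayesianChoiceModel:
    """Behavior-predictor choice model, reduced schedule, one condition."""
    data = small_study.trials.merge(small_study.weights, on="session_id", suffixes=("", "_w"))
    block = data[data["presented"] == "happiness"]
    model = ft.BayesianChoiceModel(
        predictors="behavior", condition="happiness",
        chains=2, warmup=200, iterations=400, seed=5,
    )
    return model.fit(block, block["chosen"].to_numpy())


@pytest.fixture(scope="session")
def zib_fit(small_study) -> ft.ZeroInflatedBetaModel:
    """Zero-inflated beta behavior model, reduced schedule, one condition."""
    data = (
        small_study.weights.merge(small_study.participants_frame, on="participant_id")
        .merge(small_study.trials[["session_id", "presented"]], on="session_id")
    )
    block = data[data["presented"] == "sadness"]
    model = ft.ZeroInflatedBetaModel(
        condition="sadness", chains=2, warmup=200, iterations=400, seed=9
    )
    return model.fit(block, block[["w_upper", "w_middle", "w_low"]])


def make_choice_truth(
    alpha=None, beta=None, n_predictors=3, sd_subj=0.3, sd_stim=0.3
) -> ft.GroundTruth:
    """Ground truth with explicit choice coefficients for every condition."""
    alpha = np.zeros(6) if alpha is None else np.asarray(alpha, dtype=float)
    beta = (
        np.zeros((6, n_predictors)) if beta is None else np.asarray(beta, dtype=float)
    )
    cs = ft.CoefficientSet(alpha=alpha, beta=beta, sd_subj=sd_subj, sd_stim=sd_stim)
    variant = "A" if beta.shape[1] == 3 else "B"
    return ft.GroundTruth(
        choice={variant: {cond: cs for cond in ft.EXPRESSIONS}}, zib={}, seed=0
    )


def make_zib_truth(
    alpha_zero=0.0, beta_zero=None, alpha_beta=0.0, beta_beta=None, phi=10.0
) -> ft.GroundTruth:
    """Ground truth with explicit ZIB coefficients for every condition."""
    zc = ft.ZIBCoefficientSet(
        alpha_zero=np.full(3, float(alpha_zero)),
        beta_zero=np.zeros((3, 5)) if beta_zero is None else np.asarray(beta_zero),
        alpha_beta=np.full(3, float(alpha_beta)),
        beta_beta=np.zeros((3, 5)) if beta_beta is None else np.asarray(beta_beta),
        phi=phi,
    )
    return ft.GroundTruth(
        choice={}, zib={cond: zc for cond in ft.EXPRESSIONS}, seed=0
    )
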