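"""Synthetic study generator: traits, point-light stimuli, cursor traces,
band weights and choices drawn from the generative models with known
coefficients.

The generator emulates the study design end to end: each participant views
every stimulus (n_actors x 6 expressions) once per part; Big-Five scores
are truncated-normal on the 1-7 scale; per-session band weights follow the
zero-inflated beta law with trait-dependent parameters; chosen labels are
drawn from the logistic choice models (trait-driven in the free-viewing
part, behavior-driven in the restricted-viewing part); and cursor traces
are constructed so that preprocessing recovers the generating weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .model_core import linear_predictor, zib_params
from .types import (
    AREAS,
    EXPRESSIONS,
    TRAITS,
    CoefficientSet,
    CursorTrajectory,
    GroundTruth,
    LandmarkVideo,
    ObservationWeights,
    ParticipantProfile,
    TrialRecord,
    ZIBCoefficientSet,
)

_EPS = 1e-6  # open-interval clamp for Beta draws


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------


def gen_participants(
    n: int,
    seed: int,
    mean: float = 4.0,
    sd: float = 1.2,
) -> list[ParticipantProfile]:
    """Draw n Big-Five profiles, each trait truncated-normal on [1, 7].

    ``sd = 0`` degenerates to a point mass at ``mean`` (which must then lie
    in [1, 7]).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sd == 0.0:
        scores = np.full((n, len(TRAITS)), float(mean))
    else:
        a, b = (1.0 - mean) / sd, (7.0 - mean) / sd
        scores = truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=(n, len(TRAITS)), random_state=rng
        )
    width = max(2, len(str(n)))
    return [
        ParticipantProfile(
            participant_id=f"p{i + 1:0{width}d}",
            traits=dict(zip(TRAITS, map(float, scores[i]))),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Stimuli: 68-point face template with expression-specific motion
# ---------------------------------------------------------------------------

_JAW = np.arange(0, 17)
_BROW_L, _BROW_R = np.arange(17, 22), np.arange(22, 27)
_NOSE = np.arange(27, 36)
_EYE_L, _EYE_R = np.arange(36, 42), np.arange(42, 48)
_MOUTH_OUT = np.arange(48, 60)
_MOUTH_IN = np.arange(60, 68)
_LIP_LOWER = np.concatenate([np.arange(55, 60), np.arange(65, 68)])
_LIP_UPPER = np.concatenate([np.arange(49, 54), np.arange(61, 64)])
_MOUTH_CORNERS = np.array([48, 54, 60, 64])


def _face_template() -> np.ndarray:
    """Neutral 68-landmark layout in a unit box (x right, y down)."""
    pts = np.zeros((68, 2))
    ang = np.pi * np.arange(17) / 16.0
    pts[_JAW, 0] = 0.5 - 0.45 * np.cos(ang)
    pts[_JAW, 1] = 0.33 + 0.62 * np.sin(ang)
    t = np.linspace(0.0, 1.0, 5)
    pts[_BROW_L, 0] = 0.16 + 0.26 * t
    pts[_BROW_L, 1] = 0.30 - 0.04 * np.sin(np.pi * t)
    pts[_BROW_R, 0] = 0.58 + 0.26 * t
    pts[_BROW_R, 1] = 0.30 - 0.04 * np.sin(np.pi * t)
    pts[27:31, 0] = 0.5
    pts[27:31, 1] = np.linspace(0.36, 0.56, 4)
    pts[31:36, 0] = np.linspace(0.42, 0.58, 5)
    pts[31:36, 1] = 0.62 - 0.015 * np.sin(np.pi * np.linspace(0, 1, 5))
    for idx, cx in ((_EYE_L, 0.30), (_EYE_R, 0.70)):
        a = 2 * np.pi * np.arange(6) / 6.0
        pts[idx, 0] = cx + 0.07 * np.cos(a)
        pts[idx, 1] = 0.40 - 0.028 * np.sin(a)
    a = 2 * np.pi * np.arange(12) / 12.0
    pts[_MOUTH_OUT, 0] = 0.5 - 0.15 * np.cos(a)
    pts[_MOUTH_OUT, 1] = 0.78 + 0.06 * np.sin(a)
    a = 2 * np.pi * np.arange(8) / 8.0
    pts[_MOUTH_IN, 0] = 0.5 - 0.085 * np.cos(a)
    pts[_MOUTH_IN, 1] = 0.78 + 0.028 * np.sin(a)
    return pts


def _expression_displacement(expression: str) -> np.ndarray:
    """Peak displacement field (unit-box coordinates) for one expression."""
    d = np.zeros((68, 2))
    if expression == "happiness":
        d[_MOUTH_CORNERS, 1] -= 0.035
        d[_MOUTH_CORNERS, 0] += np.array([-0.03, 0.03, -0.02, 0.02])
        d[_LIP_LOWER, 1] += 0.045  # mouth opens
        d[np.concatenate([_EYE_L, _EYE_R]), 1] += 0.008
    elif expression == "surprise":
        d[_LIP_LOWER, 1] += 0.085
        d[np.concatenate([_BROW_L, _BROW_R]), 1] -= 0.045
        d[_JAW[6:11], 1] += 0.04
    elif expression == "fear":
        d[_LIP_LOWER, 1] += 0.06
        d[np.concatenate([_BROW_L, _BROW_R]), 1] -= 0.03
        d[[19, 20, 21, 22, 23, 24], 1] -= 0.015
    elif expression == "sadness":
        d[_MOUTH_CORNERS, 1] += 0.03
        d[[21, 22], 1] -= 0.025  # inner brows rise
        d[_LIP_UPPER, 1] += 0.005
    elif expression == "anger":
        d[np.concatenate([_BROW_L, _BROW_R]), 1] += 0.03
        d[[21, 22], 0] += np.array([0.02, -0.02])
        d[_LIP_LOWER, 1] -= 0.01  # lips pressed
        d[_LIP_UPPER, 1] += 0.01
    elif expression == "disgust":
        d[_LIP_UPPER, 1] -= 0.03
        d[_NOSE[4:], 1] -= 0.02
        d[np.concatenate([_BROW_L, _BROW_R]), 1] += 0.02
    else:
        raise ValueError(f"unknown expression {expression!r}")
    return d


def gen_stimuli(
    n_actors: int,
    expressions: tuple[str, ...] = EXPRESSIONS,
    seed: int = 0,
    canvas: tuple[int, int] = (600, 800),
    frame_interval_ms: float = 100.0,
    duration_ms: float = 2500.0,
    neutral_ms: float = 500.0,
    face_size: tuple[float, float] = (200.0, 250.0),
) -> list[LandmarkVideo]:
    """Generate n_actors x len(expressions) landmark videos.

    Each video holds ``duration_ms / frame_interval_ms`` frames of 68
    points; the face occupies roughly ``face_size`` pixels centred on the
    canvas. Motion is a neutral onset followed by a smooth ramp of the
    expression-specific displacement field; actor identity is a small rigid
    shift/scale perturbation of the shared template.
    """
    if n_actors < 1:
        raise ValueError("n_actors must be >= 1")
    expressions = tuple(expressions)
    if not expressions:
        raise ValueError("expressions must be non-empty")
    for e in expressions:
        if e not in EXPRESSIONS:
            raise ValueError(f"unknown expression {e!r}")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_ms / frame_interval_ms))
    w, h = canvas
    base = _face_template()
    videos = []
    for actor in range(1, n_actors + 1):
        scale = 1.0 + 0.05 * rng.uniform(-1, 1)
        shift = rng.uniform(-12, 12, size=2)
        jitter = rng.normal(0.0, 0.004, size=(68, 2))
        for expression in expressions:
            disp = _expression_displacement(expression)
            frames = np.empty((n_frames, 68, 2))
            for f in range(n_frames):
                t = f * frame_interval_ms
                if t < neutral_ms:
                    env = 0.0
                else:
                    env = math.sin(
                        0.5 * math.pi * min(1.0, (t - neutral_ms) / (duration_ms - neutral_ms))
                    )
                unit = base + jitter + env * disp
                frames[f, :, 0] = w / 2.0 + shift[0] + scale * face_size[0] * (unit[:, 0] - 0.5)
                frames[f, :, 1] = h / 2.0 + shift[1] + scale * face_size[1] * (unit[:, 1] - 0.5)
            videos.append(
                LandmarkVideo(
                    stimulus_id=f"a{actor:02d}_{expression}",
                    actor_id=actor,
                    expression=expression,
                    frames=frames,
                    frame_interval_ms=frame_interval_ms,
                    canvas=canvas,
                )
            )
    return videos


# ---------------------------------------------------------------------------
# Observation weights and choices from the generative models
# ---------------------------------------------------------------------------


def sample_zib_triple(
    profile: ParticipantProfile,
    coeffs: ZIBCoefficientSet,
    rng: np.random.Generator,
    stimulus_id: str | None = None,
) -> np.ndarray:
    """Raw independent zero-inflated-beta draw for the three bands.

    Each band is zero with probability 1 - q, else Beta(a, b); the three
    draws are independent, so their sum may exceed 1. Exact 0/1 Beta draws
    are resampled and nonzero values clamped to [1e-6, 1 - 1e-6].
    """
    out = np.zeros(len(AREAS))
    subj = profile.participant_id if profile.participant_id in coeffs.r_subj_zero else None
    stim = stimulus_id if stimulus_id in coeffs.r_stim_zero else None
    for k, area in enumerate(AREAS):
        q, a, b = zib_params(coeffs, area, profile.trait_vector, subj, stim)
        if rng.random() >= q:
            continue
        g = rng.beta(a, b)
        while g <= 0.0 or g >= 1.0:
            g = rng.beta(a, b)
        out[k] = min(max(g, _EPS), 1.0 - _EPS)
    return out


def sample_observation_weights(
    profile: ParticipantProfile,
    truth: GroundTruth,
    expression: str,
    seed: int | np.random.Generator,
    stimulus_id: str | None = None,
    session_id: str = "",
) -> ObservationWeights:
    """Draw a session's band-weight triple from the ZIB ground truth.

    Because the three bands are independent in the generative law, draws
    summing above 1 are proportionally rescaled to the simplex (the triple
    must be realizable as dwell fractions of one cursor trace).
    """
    coeffs = truth.zib[expression]
    if coeffs.phi <= 0:
        raise ValueError("phi must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = sample_zib_triple(profile, coeffs, rng, stimulus_id)
    total = w.sum()
    if total > 1.0:
        w = w / total * (1.0 - _EPS)
    return ObservationWeights(session_id=session_id, weights=tuple(w))


def sample_choices(
    profile: ParticipantProfile,
    predictors: np.ndarray | ObservationWeights,
    truth: GroundTruth,
    variant: str,
    seed: int | np.random.Generator,
    condition: str = "happiness",
    stimulus_id: str | None = None,
    session_id: str = "",
    part: int | None = None,
) -> TrialRecord:
    """Draw one trial's chosen label from the choice model.

    Variant "A" expects an ObservationWeights triple, variant "B" the
    5-vector of trait scores. The six per-response Bernoulli probabilities
    are normalized to a categorical law for sampling (participants choose
    exactly one label); confidence is uniform 1-7 noise, never modeled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if variant == "A":
        if not isinstance(predictors, ObservationWeights):
            raise ValueError("variant A requires ObservationWeights predictors")
        x = predictors.vector
    elif variant == "B":
        if isinstance(predictors, ObservationWeights):
            raise ValueError("variant B requires trait-score predictors")
        x = np.asarray(predictors, dtype=float)
        if x.shape != (len(TRAITS),):
            raise ValueError("variant B requires a 5-vector of trait scores")
    else:
        raise ValueError("variant must be 'A' or 'B'")
    coeffs = truth.choice[variant][condition]
    subj = profile.participant_id if profile.participant_id in coeffs.r_subj else None
    stim = stimulus_id if stimulus_id in coeffs.r_stim else None
    mu = np.array(
        [linear_predictor(coeffs, k, x, subj, stim) for k in EXPRESSIONS]
    )
    p = expit(mu)
    chosen = EXPRESSIONS[rng.choice(len(EXPRESSIONS), p=p / p.sum())]
    return TrialRecord(
        session_id=session_id,
        participant_id=profile.participant_id,
        stimulus_id=stimulus_id or "",
        presented=condition,
        chosen=chosen,
        confidence=int(rng.integers(1, 8)),
        part=part if part is not None else (1 if variant == "B" else 2),
    )


# ---------------------------------------------------------------------------
# Cursor trajectories realizing a target weight triple
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryPolicy:
    """Dwell/jump parameters for synthesizing cursor traces."""

    duration_ms: float = 2500.0
    sample_interval_ms: float = 20.0
    jitter_px: float = 2.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0 or self.sample_interval_ms <= 0:
            raise ValueError("durations must be positive")
        if self.jitter_px < 0:
            raise ValueError("jitter must be non-negative")


def gen_trajectory(
    weights: ObservationWeights,
    stimulus: LandmarkVideo,
    policy: TrajectoryPolicy = TrajectoryPolicy(),
    seed: int | np.random.Generator = 0,
    screen_origin: tuple[float, float] = (0.0, 0.0),
) -> CursorTrajectory:
    """Synthesize a cursor trace whose preprocessed band weights match
    ``weights``.

    Samples dwell at the vertical centre of each band (proportionally to
    the target weights, with small jitter) so the 10-px Gaussian density
    stays inside the band; leftover mass (1 - sum of weights) dwells at a
    point well outside the face bounding box.
    """
    from .preprocessing import partition_face  # local import avoids a cycle

    if stimulus.n_frames == 0:
        raise ValueError("stimulus has no frames")
    w = weights.vector
    if w.sum() > 1.0 + 1e-9:
        raise ValueError("weights must sum to <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    part = partition_face(stimulus)
    x0, y0, x1, y1 = part.bbox
    cx = 0.5 * (x0 + x1)
    band_edges = [y0, part.cuts[0], part.cuts[1], y1]
    n = int(round(policy.duration_ms / policy.sample_interval_ms))
    counts = np.floor(w * n).astype(int)
    # distribute remainder samples by largest fractional part
    frac = w * n - counts
    for k in np.argsort(-frac):
        if counts.sum() >= round(w.sum() * n):
            break
        counts[k] += 1
    n_out = n - counts.sum()

    canvas_w, canvas_h = stimulus.canvas
    # off-face dwell point: > 4 sigma (40 px at the default filter) from bbox
    margin = 60.0
    if x0 >= margin:
        off = (x0 - margin, 0.5 * (y0 + y1))
    elif canvas_w - x1 >= margin:
        off = (x1 + margin, 0.5 * (y0 + y1))
    elif y0 >= margin:
        off = (cx, y0 - margin)
    else:
        off = (cx, min(canvas_h - 1.0, y1 + margin))

    xs, ys = [], []
    for k in range(3):
        c_lo, c_hi = band_edges[k], band_edges[k + 1]
        yc = 0.5 * (c_lo + c_hi)
        jitter = np.clip(
            rng.normal(0.0, policy.jitter_px, size=(counts[k], 2)), -6.0, 6.0
        )
        xs.append(cx + jitter[:, 0])
        ys.append(yc + jitter[:, 1])
    xs.append(np.full(n_out, off[0]))
    ys.append(np.full(n_out, off[1]))
    x = np.concatenate(xs) + screen_origin[0]
    y = np.concatenate(ys) + screen_origin[1]
    order = rng.permutation(n)
    t = policy.sample_interval_ms * np.arange(n)
    samples = np.column_stack([t, x[order], y[order]])
    return CursorTrajectory(
        session_id=weights.session_id,
        participant_id="",
        stimulus_id=stimulus.stimulus_id,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Ground truth and full-study simulation
# ---------------------------------------------------------------------------


def default_ground_truth(
    participants: list[ParticipantProfile],
    stimuli: list[LandmarkVideo],
    seed: int = 0,
    sd_subj: float = 0.3,
    sd_stim: float = 0.3,
    effect_scale: float = 1.0,
    phi: float = 10.0,
) -> GroundTruth:
    """Moderate, sparse ground-truth coefficients for every model variant.

    Per condition the correct response gets an intercept advantage; one
    trait (variant B) or the condition's diagnostic band (variant A)
    carries a moderate fixed effect on the magnitudes the significance
    tables of such studies report. Intercepts are offset so predictors at
    their typical values (traits near 4, band weights near 1/4) keep choice
    probabilities away from saturation. Random effects are drawn once per
    participant and stimulus from normal(0, sd).
    """
    rng = np.random.default_rng(seed)
    subj_ids = [p.participant_id for p in participants]
    stim_ids = [s.stimulus_id for s in stimuli]
    K = len(EXPRESSIONS)

    def _random_effects(sd: float, ids: list[str], width: int) -> dict[str, np.ndarray]:
        return {i: rng.normal(0.0, sd, size=width) for i in ids}

    choice: dict[str, dict[str, CoefficientSet]] = {"A": {}, "B": {}}
    for ci, cond in enumerate(EXPRESSIONS):
        base = np.where(np.arange(K) == ci, 1.0, -1.0)

        beta_a = np.zeros((K, len(AREAS)))
        beta_a[ci, ci % len(AREAS)] = 1.5 * effect_scale
        beta_a[(ci + 1) % K, (ci + 1) % len(AREAS)] = -1.0 * effect_scale
        choice["A"][cond] = CoefficientSet(
            alpha=base - beta_a @ np.full(len(AREAS), 0.25),
            beta=beta_a,
            sd_subj=sd_subj,
            sd_stim=sd_stim,
            r_subj=_random_effects(sd_subj, subj_ids, K),
            r_stim=_random_effects(sd_stim, stim_ids, K),
        )

        beta_b = np.zeros((K, len(TRAITS)))
        beta_b[ci, ci % len(TRAITS)] = 0.5 * effect_scale
        beta_b[(ci + 2) % K, (ci + 1) % len(TRAITS)] = -0.35 * effect_scale
        choice["B"][cond] = CoefficientSet(
            alpha=base - beta_b @ np.full(len(TRAITS), 4.0),
            beta=beta_b,
            sd_subj=sd_subj,
            sd_stim=sd_stim,
            r_subj=_random_effects(sd_subj, subj_ids, K),
            r_stim=_random_effects(sd_stim, stim_ids, K),
        )

    zib: dict[str, ZIBCoefficientSet] = {}
    for ci, cond in enumerate(EXPRESSIONS):
        beta_zero = np.zeros((len(AREAS), len(TRAITS)))
        beta_zero[ci % len(AREAS), ci % len(TRAITS)] = 0.25 * effect_scale
        beta_beta = np.zeros((len(AREAS), len(TRAITS)))
        beta_beta[(ci + 1) % len(AREAS), ci % len(TRAITS)] = -0.08 * effect_scale
        zib[cond] = ZIBCoefficientSet(
            alpha_zero=float(logit(0.75)) - beta_zero @ np.full(len(TRAITS), 4.0),
            beta_zero=beta_zero,
            alpha_beta=float(logit(0.25)) - beta_beta @ np.full(len(TRAITS), 4.0),
            beta_beta=beta_beta,
            phi=phi,
            sd_subj_zero=sd_subj,
            sd_stim_zero=sd_stim,
            sd_subj_beta=sd_subj,
            sd_stim_beta=sd_stim,
            r_subj_zero=_random_effects(sd_subj, subj_ids, len(AREAS)),
            r_stim_zero=_random_effects(sd_stim, stim_ids, len(AREAS)),
            r_subj_beta=_random_effects(sd_subj, subj_ids, len(AREAS)),
            r_stim_beta=_random_effects(sd_stim, stim_ids, len(AREAS)),
        )
    return GroundTruth(choice=choice, zib=zib, seed=seed)


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated experiment produced."""

    participants: list[ParticipantProfile]
    stimuli: list[LandmarkVideo]
    trials: pd.DataFrame
    weights: pd.DataFrame
    truth: GroundTruth
    trajectories: list[CursorTrajectory] = field(default_factory=list)

    @property
    def participants_frame(self) -> pd.DataFrame:
        rows = [
            {"participant_id": p.participant_id, **{t: p.traits[t] for t in TRAITS}}
            for p in self.participants
        ]
        return pd.DataFrame(rows)


def simulate_study(
    n_participants: int,
    seed: int,
    n_actors: int = 8,
    expressions: tuple[str, ...] = EXPRESSIONS,
    truth: GroundTruth | None = None,
    parts: tuple[int, ...] = (1, 2),
    with_trajectories: bool = False,
    policy: TrajectoryPolicy = TrajectoryPolicy(),
    effect_scale: float = 1.0,
) -> SimulatedStudy:
    """Simulate the full experiment.

    Every participant sees all n_actors x len(expressions) stimuli once per
    part. Part 1 (free viewing) draws choices from the trait model (variant
    B); part 2 (restricted viewing) draws band weights from the ZIB law,
    then choices from the behavior model (variant A). With
    ``with_trajectories`` a cursor trace realizing each part-2 weight
    triple is synthesized as well.
    """
    rng = np.random.default_rng(seed)
    participants = gen_participants(n_participants, seed=int(rng.integers(2**31)))
    stimuli = gen_stimuli(
        n_actors, expressions, seed=int(rng.integers(2**31))
    )
    if truth is None:
        truth = default_ground_truth(
            participants, stimuli, seed=int(rng.integers(2**31)), effect_scale=effect_scale
        )

    trial_rows, weight_rows, trajectories = [], [], []
    for part in parts:
        for profile in participants:
            for video in stimuli:
                session = f"{profile.participant_id}_{video.stimulus_id}_part{part}"
                cond = video.expression
                if part == 1:
                    trial = sample_choices(
                        profile, profile.trait_vector, truth, "B", rng,
                        condition=cond, stimulus_id=video.stimulus_id,
                        session_id=session, part=1,
                    )
                else:
                    ow = sample_observation_weights(
                        profile, truth, cond, rng,
                        stimulus_id=video.stimulus_id, session_id=session,
                    )
                    weight_rows.append(
                        {
                            "session_id": session,
                            "participant_id": profile.participant_id,
                            "stimulus_id": video.stimulus_id,
                            "w_upper": ow.weights[0],
                            "w_middle": ow.weights[1],
                            "w_low": ow.weights[2],
                        }
                    )
                    if with_trajectories:
                        traj = gen_trajectory(ow, video, policy, rng)
                        trajectories.append(
                            CursorTrajectory(
                                session_id=session,
                                participant_id=profile.participant_id,
                                stimulus_id=video.stimulus_id,
                                samples=traj.samples,
                            )
                        )
                    trial = sample_choices(
                        profile, ow, truth, "A", rng,
                        condition=cond, stimulus_id=video.stimulus_id,
                        session_id=session, part=2,
                    )
                trial_rows.append(trial.__dict__.copy())
    return SimulatedStudy(
        participants=participants,
        stimuli=stimuli,
        trials=pd.DataFrame(trial_rows),
        weights=pd.DataFrame(weight_rows),
        truth=truth,
        trajectories=trajectories,
    )
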