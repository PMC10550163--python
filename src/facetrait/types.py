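"""Domain types shared across the pipeline.

The experiment presents short point-light face videos (68 facial landmarks
per frame) and records, per session: which of six basic expressions the
participant chose, their confidence, and — in the restricted-viewing part —
the mouse-cursor trajectory that reveals which face regions they chose to
inspect. Participants additionally carry Big-Five trait scores on a 1-7
scale. These containers are deliberately plain: numpy arrays plus ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: The six basic expression categories, in canonical order.
EXPRESSIONS: tuple[str, ...] = (
    "happiness", "sadness", "anger", "disgust", "surprise", "fear",
)

#: Horizontal face bands, top to bottom. Heights are in proportion 1 : 0.8 : 0.6.
AREAS: tuple[str, ...] = ("upper", "middle", "low")

#: Big-Five trait names, in canonical order.
TRAITS: tuple[str, ...] = (
    "agreeableness", "conscientiousness", "extraversion", "neuroticism", "openness",
)

#: Band-height proportions for the upper/middle/low split.
BAND_RATIOS: tuple[float, float, float] = (1.0, 0.8, 0.6)


@dataclass(frozen=True)
class ParticipantProfile:
    """Big-Five trait scores for one participant (each score in [1, 7])."""

    participant_id: str
    traits: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.traits) != set(TRAITS):
            raise ValueError(f"traits must be exactly {TRAITS}, got {sorted(self.traits)}")
        for name, value in self.traits.items():
            if not 1.0 <= float(value) <= 7.0:
                raise ValueError(f"trait {name!r} = {value} outside [1, 7]")

    @property
    def trait_vector(self) -> np.ndarray:
        """Scores as a 5-vector in canonical trait order."""
        return np.array([self.traits[t] for t in TRAITS], dtype=float)


@dataclass(frozen=True)
class LandmarkVideo:
    """A point-light face animation: ordered frames of 68 (x, y) landmarks.

    ``frames`` has shape (n_frames, 68, 2) in video pixel coordinates
    (origin top-left, y increasing downward).
    """

    stimulus_id: str
    actor_id: int
    expression: str
    frames: np.ndarray
    frame_interval_ms: float = 100.0
    canvas: tuple[int, int] = (600, 800)  # (width, height)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        if frames.ndim != 3 or frames.shape[1:] != (68, 2):
            raise ValueError(f"frames must have shape (n, 68, 2), got {frames.shape}")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")
        w, h = self.canvas
        x, y = frames[..., 0], frames[..., 1]
        if x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h:
            raise ValueError("landmarks fall outside the canvas")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms


@dataclass(frozen=True)
class CursorTrajectory:
    """Time-stamped cursor positions for one session.

    ``samples`` has shape (n, 3): columns (t_ms, x_px, y_px). Coordinates are
    screen coordinates until :func:`facetrait.preprocessing.to_video_coords`
    converts them; ``in_canvas`` (set by that conversion) flags samples that
    landed on the stimulus canvas.
    """

    session_id: str
    participant_id: str
    stimulus_id: str
    samples: np.ndarray
    in_canvas: np.ndarray | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "samples", samples)
        t = samples[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class TrialRecord:
    """One session's outcome: presented vs chosen expression plus confidence."""

    session_id: str
    participant_id: str
    stimulus_id: str
    presented: str
    chosen: str
    confidence: int
    part: int = 2

    def __post_init__(self) -> None:
        for label in (self.presented, self.chosen):
            if label not in EXPRESSIONS:
                raise ValueError(f"unknown expression label {label!r}")
        if not 1 <= int(self.confidence) <= 7:
            raise ValueError("confidence must be in 1..7")
        if self.part not in (1, 2):
            raise ValueError("part must be 1 or 2")

    def one_hot(self) -> np.ndarray:
        """y_k indicator vector over the six expressions (1 iff chosen = k)."""
        y = np.zeros(len(EXPRESSIONS))
        y[EXPRESSIONS.index(self.chosen)] = 1.0
        return y


@dataclass(frozen=True)
class ObservationWeights:
    """Per-session attention weights over the upper/middle/low face bands.

    Each component is the fraction of the session's accumulated cursor
    density falling in that band; mass outside the face bounding box is
    discarded, so the components sum to at most 1.
    """

    session_id: str
    weights: tuple[float, float, float]
    raw_mass_total: float = float("nan")
    out_of_bbox_fraction: float = float("nan")

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        object.__setattr__(self, "weights", w)
        if any(v < 0 or v > 1 for v in w):
            raise ValueError(f"weights must lie in [0, 1], got {w}")
        if sum(w) > 1 + 1e-9:
            raise ValueError(f"weights must sum to <= 1, got {sum(w)}")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass
class CoefficientSet:
    """Coefficients of one choice model (one presented-expression condition).

    ``alpha`` is the per-response intercept (6-vector); ``beta`` the fixed
    effects, shape (6, 3) for observation-behavior predictors or (6, 5) for
    trait predictors. Random effects are per (participant x response) and
    (stimulus x response), scaled by ``sd_subj`` / ``sd_stim``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sd_subj: float = 0.3
    sd_stim: float = 0.3
    r_subj: dict[str, np.ndarray] = field(default_factory=dict)
    r_stim: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.alpha.shape != (len(EXPRESSIONS),):
            raise ValueError("alpha must be a 6-vector")
        if self.beta.ndim != 2 or self.beta.shape[0] != len(EXPRESSIONS):
            raise ValueError("beta must have shape (6, n_predictors)")
        if self.sd_subj <= 0 or self.sd_stim <= 0:
            raise ValueError("random-effect scales must be positive")

    @property
    def n_predictors(self) -> int:
        return self.beta.shape[1]


@dataclass
class ZIBCoefficientSet:
    """Coefficients of the zero-inflated-beta behavior model (one condition).

    The zero block drives q, the probability that a band receives any
    attention at all; the beta block drives the mean mu of the Beta law for
    the nonzero dwell fraction, with shape parameters a = phi*mu and
    b = phi*(1 - mu). Blocks are indexed (3 areas x 5 traits).
    """

    alpha_zero: np.ndarray
    beta_zero: np.ndarray
    alpha_beta: np.ndarray
    beta_beta: np.ndarray
    phi: float = 10.0
    sd_subj_zero: float = 0.3
    sd_stim_zero: float = 0.3
    sd_subj_beta: float = 0.3
    sd_stim_beta: float = 0.3
    r_subj_zero: dict[str, np.ndarray] = field(default_factory=dict)
    r_stim_zero: dict[str, np.ndarray] = field(default_factory=dict)
    r_subj_beta: dict[str, np.ndarray] = field(default_factory=dict)
    r_stim_beta: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha_zero", "alpha_beta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(AREAS),):
                raise ValueError(f"{name} must be a 3-vector")
        for name in ("beta_zero", "beta_beta"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(AREAS), len(TRAITS)):
                raise ValueError(f"{name} must have shape (3, 5)")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


@dataclass
class GroundTruth:
    """Known coefficients used by the synthetic-data generators.

    ``choice`` maps model variant ("A" or "B") and presented expression to a
    CoefficientSet; ``zib`` maps presented expression to a ZIBCoefficientSet.
    """

    choice: dict[str, dict[str, CoefficientSet]]
    zib: dict[str, ZIBCoefficientSet]
    seed: int = 0


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-parameters of the weakly informative priors.

    Fixed effects are normal(0, sd 10) — equivalently variance 100; the
    random-effect scale carries a gamma(shape 10, rate 10) prior; the Beta
    precision phi carries gamma(shape 2, rate 0.1).
    """

    fixed_effect_sd: float = 10.0
    random_scale_shape: float = 10.0
    random_scale_rate: float = 10.0
    phi_shape: float = 2.0
    phi_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("fixed_effect_sd", "random_scale_shape", "random_scale_rate",
                     "phi_shape", "phi_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
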