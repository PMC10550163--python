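"""Cursor-trace preprocessing: screen-to-video conversion, Gaussian density
accumulation, face partitioning, and band-weight aggregation.

Each cursor sample deposits a unit-mass isotropic Gaussian kernel (10-px
standard deviation by default, truncated at 4 sigma) on the video canvas;
the per-session accumulated density is split over three horizontal face
bands whose heights are in proportion upper : middle : low = 1 : 0.8 : 0.6,
and each band weight is that band's share of the total accumulated mass.
Mass outside the face bounding box is discarded (reported as
``out_of_bbox_fraction``), so the three weights sum to at most 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BAND_RATIOS, CursorTrajectory, LandmarkVideo, ObservationWeights

_KERNEL_TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class ScreenConfig:
    """Where the stimulus canvas sits on the experiment screen."""

    screen: tuple[int, int] = (1920, 1080)
    stimulus_origin: tuple[float, float] = (660.0, 140.0)
    canvas: tuple[int, int] = (600, 800)

    def __post_init__(self) -> None:
        ox, oy = self.stimulus_origin
        if (
            ox < 0
            or oy < 0
            or ox + self.canvas[0] > self.screen[0]
            or oy + self.canvas[1] > self.screen[1]
        ):
            raise ValueError("stimulus rectangle must lie fully inside the screen")


@dataclass(frozen=True)
class FacePartition:
    """Face bounding box plus the two cut heights of the 1 : 0.8 : 0.6 split.

    ``bbox`` is (x0, y0, x1, y1) in video coordinates, half-open on the
    right/bottom; ``cuts`` are the two horizontal boundaries, at
    y0 + h * 1/2.4 and y0 + h * 1.8/2.4 for h = y1 - y0.
    """

    bbox: tuple[float, float, float, float]
    cuts: tuple[float, float]

    @classmethod
    def from_bbox(cls, bbox: tuple[float, float, float, float]) -> "FacePartition":
        x0, y0, x1, y1 = bbox
        h = y1 - y0
        if h <= 0 or x1 <= x0:
            raise ValueError("degenerate face bounding box")
        total = sum(BAND_RATIOS)
        c1 = y0 + h * BAND_RATIOS[0] / total
        c2 = y0 + h * (BAND_RATIOS[0] + BAND_RATIOS[1]) / total
        return cls(bbox=(x0, y0, x1, y1), cuts=(c1, c2))

    @property
    def band_heights(self) -> tuple[float, float, float]:
        _, y0, _, y1 = self.bbox
        c1, c2 = self.cuts
        return (c1 - y0, c2 - c1, y1 - c2)


@dataclass(frozen=True)
class DensityMap:
    """Accumulated cursor density on the video canvas; grid[row, col] >= 0."""

    grid: np.ndarray
    canvas: tuple[int, int]

    @property
    def total_mass(self) -> float:
        return float(self.grid.sum())


def to_video_coords(trajectory: CursorTrajectory, config: ScreenConfig) -> CursorTrajectory:
    """Translate screen coordinates into video coordinates.

    Each sample is shifted by -stimulus_origin; samples landing outside the
    video canvas are retained but flagged via ``in_canvas``.
    """
    samples = trajectory.samples
    if len(samples):
        x, y = samples[:, 1], samples[:, 2]
        sw, sh = config.screen
        if x.min() < 0 or y.min() < 0 or x.max() > sw or y.max() > sh:
            raise ValueError("cursor samples fall outside the screen bounds")
    out = samples.copy()
    out[:, 1] -= config.stimulus_origin[0]
    out[:, 2] -= config.stimulus_origin[1]
    w, h = config.canvas
    in_canvas = (
        (out[:, 1] >= 0) & (out[:, 1] < w) & (out[:, 2] >= 0) & (out[:, 2] < h)
    )
    return CursorTrajectory(
        session_id=trajectory.session_id,
        participant_id=trajectory.participant_id,
        stimulus_id=trajectory.stimulus_id,
        samples=out,
        in_canvas=in_canvas,
    )


def _gaussian_stamp(sigma_px: float) -> np.ndarray:
    radius = int(np.ceil(_KERNEL_TRUNCATION_SIGMAS * sigma_px))
    ax = np.arange(-radius, radius + 1)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma_px**2))
    return k / k.sum()  # unit mass per sample


def accumulate_density(
    trajectory: CursorTrajectory,
    sigma_px: float = 10.0,
    canvas: tuple[int, int] = (600, 800),
) -> DensityMap:
    """Sum one unit-mass truncated Gaussian kernel per in-canvas sample.

    The total mass equals the number of in-canvas samples up to truncation
    (and canvas-edge clipping) error; out-of-canvas samples contribute
    nothing.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    w, h = canvas
    grid = np.zeros((h, w))
    stamp = _gaussian_stamp(sigma_px)
    radius = stamp.shape[0] // 2
    samples = trajectory.samples
    mask = trajectory.in_canvas
    for idx in range(len(samples)):
        x, y = samples[idx, 1], samples[idx, 2]
        if mask is not None and not mask[idx]:
            continue
        if not (0 <= x < w and 0 <= y < h):
            continue
        cx, cy = int(round(x)), int(round(y))
        r0, r1 = max(0, cy - radius), min(h, cy + radius + 1)
        c0, c1 = max(0, cx - radius), min(w, cx + radius + 1)
        grid[r0:r1, c0:c1] += stamp[
            r0 - cy + radius : r1 - cy + radius, c0 - cx + radius : c1 - cx + radius
        ]
    return DensityMap(grid=grid, canvas=canvas)


def partition_face(video: LandmarkVideo) -> FacePartition:
    """Partition from the union bounding box of all frames' landmarks.

    The union over frames (rather than a per-frame box) keeps the partition
    fixed within a session. Pixel rows/columns containing any landmark are
    included, so the box is [floor(min), floor(max) + 1) in each axis.
    """
    if video.n_frames < 1:
        raise ValueError("video must have at least one frame")
    pts = video.frames.reshape(-1, 2)
    x0 = float(np.floor(pts[:, 0].min()))
    x1 = float(np.floor(pts[:, 0].max())) + 1.0
    y0 = float(np.floor(pts[:, 1].min()))
    y1 = float(np.floor(pts[:, 1].max())) + 1.0
    return FacePartition.from_bbox((x0, y0, x1, y1))


def aggregate_weights(
    density: DensityMap,
    partition: FacePartition,
    session_id: str = "",
) -> ObservationWeights:
    """Band weights: each band's share of the total accumulated mass.

    A grid cell (row r, column c) belongs to the band containing its centre
    row r + 0.5. A zero-mass map yields all-zero weights with a warning
    (the participant never moved onto the stimulus).
    """
    total = density.total_mass
    if total <= 0.0:
        warnings.warn(
            f"session {session_id!r}: zero accumulated mass, returning zero weights",
            stacklevel=2,
        )
        return ObservationWeights(
            session_id=session_id, weights=(0.0, 0.0, 0.0),
            raw_mass_total=0.0, out_of_bbox_fraction=1.0,
        )
    h, w = density.grid.shape
    x0, y0, x1, y1 = partition.bbox
    c1, c2 = partition.cuts
    col0, col1 = max(0, int(np.ceil(x0 - 0.5))), min(w, int(np.ceil(x1 - 0.5)))
    row_edges = [y0, c1, c2, y1]
    masses = []
    for k in range(3):
        r0 = max(0, int(np.ceil(row_edges[k] - 0.5)))
        r1 = min(h, int(np.ceil(row_edges[k + 1] - 0.5)))
        masses.append(float(density.grid[r0:r1, col0:col1].sum()) if r1 > r0 else 0.0)
    weights = tuple(m / total for m in masses)
    return ObservationWeights(
        session_id=session_id,
        weights=weights,
        raw_mass_total=total,
        out_of_bbox_fraction=1.0 - sum(weights),
    )


def process_session(
    trajectory: CursorTrajectory,
    video: LandmarkVideo,
    config: ScreenConfig | None = None,
    sigma_px: float = 10.0,
) -> ObservationWeights:
    """Full preprocessing of one session: convert, accumulate, aggregate."""
    if config is not None:
        trajectory = to_video_coords(trajectory, config)
        canvas = config.canvas
    else:
        canvas = video.canvas
    density = accumulate_density(trajectory, sigma_px=sigma_px, canvas=canvas)
    partition = partition_face(video)
    return aggregate_weights(density, partition, session_id=trajectory.session_id)


class CursorWeightExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping (trajectory, video) pairs to band-weight rows.

    Parameters
    ----------
    sigma_px : Gaussian filter standard deviation in pixels.
    config : optional ScreenConfig; when given, trajectories are assumed to
        be in screen coordinates and are converted first.
    """

    def __init__(self, sigma_px: float = 10.0, config: ScreenConfig | None = None):
        self.sigma_px = sigma_px
        self.config = config

    def fit(self, X=None, y=None):
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of (CursorTrajectory, LandmarkVideo) pairs."""
        rows = []
        for trajectory, video in X:
            ow = process_session(trajectory, video, self.config, self.sigma_px)
            rows.append(
                {
                    "session_id": trajectory.session_id,
                    "participant_id": trajectory.participant_id,
                    "stimulus_id": trajectory.stimulus_id,
                    "w_upper": ow.weights[0],
                    "w_middle": ow.weights[1],
                    "w_low": ow.weights[2],
                    "raw_mass_total": ow.raw_mass_total,
                    "out_of_bbox_fraction": ow.out_of_bbox_fraction,
                }
            )
        return pd.DataFrame(rows)
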