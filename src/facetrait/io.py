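"""Plain-text interchange formats: CSV tables, per-stimulus JSON, and
long-format posterior-draw files.

All artifacts are text so a pipeline run is fully inspectable: participants
and trials as CSV, stimuli as one JSON per video (frames as nested
[[x, y], ...] lists), ground truth as JSON, and posterior draws as a long
(chain, draw, variable, value) CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .types import (
    CoefficientSet,
    CursorTrajectory,
    GroundTruth,
    LandmarkVideo,
    ZIBCoefficientSet,
)

TRAJECTORY_COLUMNS = ["session_id", "participant_id", "stimulus_id", "t_ms", "x_px", "y_px"]


def write_stimuli(videos: list[LandmarkVideo], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for v in videos:
        payload = {
            "stimulus_id": v.stimulus_id,
            "actor_id": v.actor_id,
            "expression": v.expression,
            "canvas": list(v.canvas),
            "frame_interval_ms": v.frame_interval_ms,
            "frames": np.round(v.frames, 3).tolist(),
        }
        (directory / f"{v.stimulus_id}.json").write_text(json.dumps(payload))


def read_stimuli(directory: str | Path) -> list[LandmarkVideo]:
    videos = []
    for path in sorted(Path(directory).glob("*.json")):
        d = json.loads(path.read_text())
        videos.append(
            LandmarkVideo(
                stimulus_id=d["stimulus_id"],
                actor_id=int(d["actor_id"]),
                expression=d["expression"],
                frames=np.asarray(d["frames"], dtype=float),
                frame_interval_ms=float(d["frame_interval_ms"]),
                canvas=tuple(d["canvas"]),
            )
        )
    return videos


def write_trajectories(trajectories: list[CursorTrajectory], path: str | Path) -> None:
    frames = []
    for tr in trajectories:
        df = pd.DataFrame(tr.samples, columns=["t_ms", "x_px", "y_px"])
        df.insert(0, "stimulus_id", tr.stimulus_id)
        df.insert(0, "participant_id", tr.participant_id)
        df.insert(0, "session_id", tr.session_id)
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    )
    out.to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[CursorTrajectory]:
    df = pd.read_csv(path)
    out = []
    for session, block in df.groupby("session_id", sort=False):
        out.append(
            CursorTrajectory(
                session_id=str(session),
                participant_id=str(block["participant_id"].iloc[0]),
                stimulus_id=str(block["stimulus_id"].iloc[0]),
                samples=block[["t_ms", "x_px", "y_px"]].to_numpy(dtype=float),
            )
        )
    return out


def _coeffs_to_json(c: CoefficientSet) -> dict:
    return {
        "alpha": c.alpha.tolist(),
        "beta": c.beta.tolist(),
        "sd_subj": c.sd_subj,
        "sd_stim": c.sd_stim,
        "r_subj": {k: np.asarray(v).tolist() for k, v in c.r_subj.items()},
        "r_stim": {k: np.asarray(v).tolist() for k, v in c.r_stim.items()},
    }


def _coeffs_from_json(d: dict) -> CoefficientSet:
    return CoefficientSet(
        alpha=np.asarray(d["alpha"]),
        beta=np.asarray(d["beta"]),
        sd_subj=d["sd_subj"],
        sd_stim=d["sd_stim"],
        r_subj={k: np.asarray(v) for k, v in d["r_subj"].items()},
        r_stim={k: np.asarray(v) for k, v in d["r_stim"].items()},
    )


_ZIB_ARRAYS = ("alpha_zero", "beta_zero", "alpha_beta", "beta_beta")
_ZIB_SCALARS = ("phi", "sd_subj_zero", "sd_stim_zero", "sd_subj_beta", "sd_stim_beta")
_ZIB_EFFECTS = ("r_subj_zero", "r_stim_zero", "r_subj_beta", "r_stim_beta")


def _zib_to_json(c: ZIBCoefficientSet) -> dict:
    out: dict = {name: np.asarray(getattr(c, name)).tolist() for name in _ZIB_ARRAYS}
    out.update({name: getattr(c, name) for name in _ZIB_SCALARS})
    for name in _ZIB_EFFECTS:
        out[name] = {k: np.asarray(v).tolist() for k, v in getattr(c, name).items()}
    return out


def _zib_from_json(d: dict) -> ZIBCoefficientSet:
    kwargs: dict = {name: np.asarray(d[name]) for name in _ZIB_ARRAYS}
    kwargs.update({name: d[name] for name in _ZIB_SCALARS})
    for name in _ZIB_EFFECTS:
        kwargs[name] = {k: np.asarray(v) for k, v in d[name].items()}
    return ZIBCoefficientSet(**kwargs)


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "choice": {
            variant: {cond: _coeffs_to_json(c) for cond, c in by_cond.items()}
            for variant, by_cond in truth.choice.items()
        },
        "zib": {cond: _zib_to_json(c) for cond, c in truth.zib.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        choice={
            variant: {cond: _coeffs_from_json(c) for cond, c in by_cond.items()}
            for variant, by_cond in d["choice"].items()
        },
        zib={cond: _zib_from_json(c) for cond, c in d["zib"].items()},
        seed=int(d["seed"]),
    )


# ---------------------------------------------------------------------------
# Posterior draws (chain, draw, variable, value)
# ---------------------------------------------------------------------------


def write_draws(
    draws: PosteriorDraws,
    path: str | Path,
    blocks: tuple[str, ...] | None = None,
) -> None:
    """Write named blocks in long format plus a JSON metadata sidecar.

    By default only the population-level blocks (everything that is not a
    per-participant or per-stimulus random effect) are written.
    """
    if blocks is None:
        blocks = tuple(n for n in draws.draws if not n.startswith("r_"))
    records = []
    for name in blocks:
        for label, arr in draws.scalar_views([name]):
            c, d = arr.shape
            records.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "variable": label,
                        "value": arr.ravel(),
                    }
                )
            )
    pd.concat(records, ignore_index=True).to_csv(path, index=False)
    meta = {
        "condition": draws.meta.get("condition"),
        "variant": draws.meta.get("variant"),
        "seed": draws.meta.get("seed"),
        "blocks": {
            name: [list(map(str, axis)) for axis in draws.dims.get(name, ())]
            for name in blocks
        },
        "max_rhat": draws.max_rhat(),
    }
    Path(path).with_suffix(".meta.json").write_text(json.dumps(meta))


_LABEL_RE = re.compile(r"^(?P<block>[A-Za-z0-9_]+)(\[(?P<idx>.*)\])?$")


def read_draws(path: str | Path) -> PosteriorDraws:
    """Rebuild a PosteriorDraws from a long CSV written by write_draws."""
    df = pd.read_csv(path)
    meta = json.loads(Path(path).with_suffix(".meta.json").read_text())
    n_chains = int(df["chain"].max()) + 1
    n_draws = int(df["draw"].max()) + 1
    blocks: dict[str, np.ndarray] = {}
    dims: dict[str, tuple] = {}
    for name, axes in meta["blocks"].items():
        axes = [tuple(a) for a in axes]
        shape = tuple(len(a) for a in axes)
        arr = np.empty((n_chains, n_draws, *shape))
        block_df = df[df["variable"].str.match(rf"^{re.escape(name)}(\[|$)")]
        for label, sub in block_df.groupby("variable", sort=False):
            m = _LABEL_RE.match(str(label))
            idx_str = m.group("idx")
            if idx_str is None:
                idx: tuple = ()
            else:
                parts = idx_str.split(",")
                idx = tuple(axes[ax].index(p) for ax, p in enumerate(parts))
            arr[(slice(None), slice(None), *idx)] = (
                sub.sort_values(["chain", "draw"])["value"].to_numpy().reshape(n_chains, n_draws)
            )
        blocks[name] = arr
        if axes:
            dims[name] = tuple(axes)
    return PosteriorDraws(
        draws=blocks,
        dims=dims,
        meta={"condition": meta.get("condition"), "variant": meta.get("variant"),
              "seed": meta.get("seed")},
    )
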