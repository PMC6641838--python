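"""Reading and writing the pipeline's on-disk formats.

Movies travel as multi-page grayscale TIFF plus a YAML sidecar carrying
frame period, Z-plane count and stimulus windows; trajectories and score
tables as CSV; schedules as YAML; ground truth and statistics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior import BehaviorScore, Epoch, EpochSchedule, Shock, Trajectory
from .imaging import ActivityMap, MovieStack

__all__ = [
    "save_movie",
    "load_movie",
    "save_trajectories",
    "load_trajectories",
    "save_schedule",
    "load_schedule",
    "scores_to_frame",
    "save_activity_map",
    "load_roi_masks",
    "dump_json",
]


def save_movie(movie: MovieStack, tiff_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write a movie as float32 TIFF plus a YAML metadata sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, movie.data.astype(np.float32), photometric="minisblack")
    side = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".yaml")
    meta = {
        "frame_period": float(movie.frame_period),
        "z_planes": int(movie.data.shape[1]) if movie.is_volumetric else 1,
        "stim_windows": {k: [float(a), float(b)] for k, (a, b) in movie.stim_windows.items()},
        "meta": _jsonable(movie.meta),
    }
    side.write_text(yaml.safe_dump(meta, sort_keys=True))


def load_movie(tiff_path: str | Path, sidecar_path: str | Path | None = None) -> MovieStack:
    tiff_path = Path(tiff_path)
    side = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".yaml")
    meta = yaml.safe_load(side.read_text())
    data = tifffile.imread(tiff_path).astype(float)
    z = int(meta.get("z_planes", 1))
    if z > 1 and data.ndim == 3:
        data = data.reshape(data.shape[0] // z, z, *data.shape[1:])
    return MovieStack(
        data=data,
        frame_period=float(meta["frame_period"]),
        stim_windows={k: (float(a), float(b)) for k, (a, b) in meta.get("stim_windows", {}).items()},
        meta=meta.get("meta", {}),
    )


def save_trajectories(trajectories: list[Trajectory], path: str | Path) -> None:
    """CSV with columns fly_id, t_s, x_mm."""
    frames = [
        pd.DataFrame({"fly_id": tr.fly_id, "t_s": tr.t, "x_mm": tr.x}) for tr in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_trajectories(path: str | Path, chamber_length: float = 50.0) -> list[Trajectory]:
    df = pd.read_csv(path)
    return [
        Trajectory(str(fid), sub["t_s"].to_numpy(), sub["x_mm"].to_numpy(), chamber_length)
        for fid, sub in df.groupby("fly_id", sort=False)
    ]


def save_schedule(schedule: EpochSchedule, path: str | Path) -> None:
    doc = {
        "epochs": [
            {"t_start": e.t_start, "t_end": e.t_end, "left": e.left, "right": e.right, "role": e.role}
            for e in schedule.epochs
        ],
        "shocks": [{"t": s.t, "duration": s.duration, "voltage": s.voltage} for s in schedule.shocks],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_schedule(path: str | Path) -> EpochSchedule:
    doc = yaml.safe_load(Path(path).read_text())
    return EpochSchedule(
        epochs=tuple(Epoch(**e) for e in doc.get("epochs", [])),
        shocks=tuple(Shock(**s) for s in doc.get("shocks", [])),
    )


def scores_to_frame(scores: list[BehaviorScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                fly_id=s.fly_id,
                group=s.group,
                preference_pre=s.preference_pre,
                preference_post=s.preference_post,
                learning_index=s.learning_index,
                avoidance_index=s.avoidance_index,
                n_choice_entries=s.n_choice_entries,
                excluded=s.excluded,
            )
            for s in scores
        ]
    )


def save_activity_map(amap: ActivityMap, out_dir: str | Path, stem: str) -> None:
    """Float TIFF pair (dff, mask) plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}_dff.tif", np.nan_to_num(amap.dff).astype(np.float32))
    tifffile.imwrite(out / f"{stem}_mask.tif", amap.responsive.astype(np.uint8))
    summary = dict(
        n_responsive=int(amap.responsive.sum()),
        n_valid=int(amap.valid.sum()),
        mean_dff_responsive=float(np.nanmean(amap.dff[amap.responsive])) if amap.responsive.any() else 0.0,
        meta=_jsonable(amap.meta),
    )
    (out / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2))


def load_roi_masks(path: str | Path) -> dict[str, np.ndarray]:
    """Labelled-TIFF ROI masks: one boolean mask per nonzero label."""
    labels = tifffile.imread(path)
    return {f"roi{v}": labels == v for v in np.unique(labels) if v != 0}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, default=str))
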