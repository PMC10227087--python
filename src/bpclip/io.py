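"""File formats: frame stacks (TIFF/PNG), CSV tables, JSON sidecars.

Every CSV written here starts with ``#``-prefixed provenance comment lines
(package version, seed, config hash) so outputs can be traced; readers skip
them transparently. Sessions serialize as a directory holding a multi-page
TIFF (or PNG sequence), the calibration frames, a JSON sidecar with the
annotations and ground truth, and the per-sample level table.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .protocol import LevelRecord, SessionRecording
from .synth import VirtualSubject


def _provenance(seed=None, config_hash=None) -> list[str]:
    lines = [f"# bpclip {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    return lines


def write_csv(df: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    """Write a table with provenance comment lines (comma, dot-decimal, UTF-8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in _provenance(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_frame_stack(frames: np.ndarray, path) -> None:
    """Write a uint8 frame stack as multi-page TIFF or a PNG sequence.

    A path ending in .tif/.tiff gets one multi-page file; a directory path
    gets numbered PNGs (frame_000000.png, ...).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", np.asarray(frame, np.uint8))


def read_frame_stack(path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of numbered PNGs."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files under {path}")
        return np.stack([iio.imread(f) for f in files])
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return frames


def save_session(session: SessionRecording, directory) -> Path:
    """Serialize a session to a directory (frames.tif + session.json + CSV)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": session.seed,
        "complete": session.complete,
        "duration_s": session.duration_s,
        "frame_rate": session.frame_rate,
        "config": session.config,
        "levels": [
            {
                "level_index": r.level_index,
                "target_scale": r.target_scale,
                "attempts": r.attempts,
            }
            for r in session.levels
        ],
    }
    if session.subject is not None:
        meta["subject_truth"] = dataclasses.asdict(session.subject)
    (directory / "session.json").write_text(json.dumps(meta, indent=2))
    samples = pd.concat(
        [
            pd.DataFrame(
                {
                    "level_index": r.level_index,
                    "timestamp": r.timestamps,
                    "force_scale": r.force_scale,
                    "ppg_value": r.ppg,
                }
            )
            for r in session.levels
        ],
        ignore_index=True,
    ) if session.levels else pd.DataFrame(
        columns=["level_index", "timestamp", "force_scale", "ppg_value"]
    )
    write_csv(samples, directory / "levels.csv", seed=session.seed)
    if session.frames is not None:
        write_frame_stack(session.frames, directory / "frames.tif")
        np.savetxt(directory / "frame_levels.txt", session.frame_levels, fmt="%d")
        np.savetxt(directory / "frame_timestamps.txt", session.frame_timestamps)
    if session.calibration_frames is not None:
        write_frame_stack(session.calibration_frames, directory / "calibration.tif")
    return directory


def load_session(directory) -> SessionRecording:
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    samples = read_csv(directory / "levels.csv")
    levels = []
    meta_levels = {d["level_index"]: d for d in meta["levels"]}
    for lvl, grp in samples.groupby("level_index", sort=True):
        info = meta_levels.get(int(lvl), {})
        levels.append(
            LevelRecord(
                level_index=int(lvl),
                target_scale=float(info.get("target_scale", float("nan"))),
                timestamps=grp["timestamp"].to_numpy(),
                force_scale=grp["force_scale"].to_numpy(),
                ppg=grp["ppg_value"].to_numpy(),
                attempts=int(info.get("attempts", 1)),
            )
        )
    session = SessionRecording(
        levels=levels,
        complete=bool(meta["complete"]),
        duration_s=float(meta["duration_s"]),
        frame_rate=float(meta["frame_rate"]),
        config=meta.get("config", {}),
        seed=meta.get("seed"),
    )
    if (directory / "frames.tif").exists():
        session.frames = read_frame_stack(directory / "frames.tif")
        session.frame_levels = np.loadtxt(
            directory / "frame_levels.txt", dtype=int
        )
        session.frame_timestamps = np.loadtxt(directory / "frame_timestamps.txt")
    if (directory / "calibration.tif").exists():
        session.calibration_frames = read_frame_stack(directory / "calibration.tif")
    if "subject_truth" in meta:
        session.subject = VirtualSubject(**meta["subject_truth"])
    return session
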