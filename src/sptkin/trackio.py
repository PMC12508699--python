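"""Reading, writing and validation of localization and track tables.

All positions are in micrometres, continuous (not pixel units); frame indices
are 0-based integers.  Track tables are comma-separated text with a mandatory
``track_id,frame,x,y`` header; localization tables use ``frame,x,y``.  Floats
are written with 10 significant digits so a write/read round trip is stable at
analysis precision.

A :class:`Track` may skip frames (gap-bridged detections are not interpolated);
its ``n_steps`` is the *frame span*, last frame minus first frame, which at
100 fps equates steps with elapsed time (100 steps == 1 s).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "TrackFormatError",
    "Localization",
    "Track",
    "RunConfig",
    "load_config",
    "read_tracks",
    "write_tracks",
    "read_localizations",
    "write_localizations",
]

#: significant digits used when serializing coordinates
_FLOAT_FMT = "%.10g"


class TrackFormatError(ValueError):
    """Raised when a table violates the track/localization CSV contract."""


@dataclass(frozen=True)
class Localization:
    """One detected particle position in one frame."""

    frame: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame must be >= 0, got {self.frame}")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("localization coordinates must be finite")


@dataclass
class Track:
    """An ordered sequence of localizations sharing a particle identity.

    ``frames`` must be strictly increasing; skipped frames are allowed and
    represent detection gaps bridged by the tracker.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) == 0:
            raise ValueError("track must contain at least one point")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frames must be strictly increasing")
        if self.frames[0] < 0:
            raise ValueError("frame indices must be >= 0")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.track_id!r}: coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        """Frame span (number of frame-to-frame displacements, gaps included)."""
        return int(self.frames[-1] - self.frames[0])

    def duration(self, frame_interval: float) -> float:
        """Track duration in seconds: frame span times the frame interval."""
        return self.n_steps * frame_interval

    def points(self) -> list[Localization]:
        return [Localization(int(f), float(px), float(py)) for f, px, py in zip(self.frames, self.x, self.y)]


class RunConfig(BaseModel):
    """Analysis-run configuration.

    Defaults mirror a 100 fps acquisition with the tracker filters used for
    membrane-binding analysis: a minimum of 30 steps per track, 0.8 um maximum
    frame-to-frame link distance, 1.2 um ambiguity exclusion radius, a maximum
    bridged gap of 3 frames, the bound/free split at D <= 1 um^2/s, and the
    specific-binding threshold of >100 steps (1 s at 10 ms/frame).
    """

    model_config = ConfigDict(extra="ignore")

    frame_interval: float = 0.010  # s
    d_threshold: float = 1.0  # um^2/s; bound iff D <= threshold
    specific_min_steps: int = 100  # strict: specific iff n_steps > this
    min_track_steps: int = 30
    max_frame_gap: int = 3
    max_link_distance: float = 0.800  # um per unit frame gap
    exclusion_radius: float = 1.200  # um
    msd_fit_lags: int = 4
    dwell_bin_width: float = 0.10  # s
    rng_seed: int = 0

    @field_validator("frame_interval", "d_threshold", "max_link_distance", "exclusion_radius", "dwell_bin_width")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("max_frame_gap")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("max_frame_gap must be >= 0")
        return v

    @field_validator("msd_fit_lags")
    @classmethod
    def _min_lags(cls, v: int) -> int:
        if v < 2:
            raise ValueError("msd_fit_lags must be >= 2")
        return v

    @model_validator(mode="after")
    def _ordering(self) -> "RunConfig":
        if self.specific_min_steps <= self.min_track_steps:
            raise ValueError("specific_min_steps must exceed min_track_steps")
        return self


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML file; keyword overrides win."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise TrackFormatError(f"config file {path} must contain a mapping")
    data.update(overrides)
    return RunConfig(**data)


def _read_table(path: str | os.PathLike, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    for col in required:
        if col not in df.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")
    for col in required:
        if col == "track_id":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            # +2: 1-based line numbers, header on line 1
            raise TrackFormatError(f"{path}: non-numeric value in column '{col}' at line {bad[0] + 2}")
        df[col] = vals
    frames = df["frame"]
    if len(frames) and (np.any(frames % 1 != 0) or np.any(frames < 0)):
        bad = df.index[(frames % 1 != 0) | (frames < 0)][0]
        raise TrackFormatError(f"{path}: frame must be a non-negative integer at line {bad + 2}")
    df["frame"] = df["frame"].astype(np.int64) if len(df) else df["frame"]
    return df


def read_tracks(path: str | os.PathLike, config: RunConfig | None = None) -> list[Track]:
    """Read a track CSV (``track_id,frame,x,y``) into a list of tracks.

    Rows are grouped by ``track_id`` and sorted by frame; duplicate
    (track_id, frame) pairs are rejected.  ``config`` is accepted for interface
    symmetry (durations are derived on demand from its frame interval).
    """
    df = _read_table(path, ("track_id", "frame", "x", "y"))
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame", kind="stable")
        frames = grp["frame"].to_numpy()
        if len(np.unique(frames)) != len(frames):
            dup = frames[np.where(np.diff(frames) == 0)[0][0]]
            raise TrackFormatError(f"{path}: duplicate frame {dup} in track '{tid}'")
        tracks.append(Track(str(tid), frames, grp["x"].to_numpy(float), grp["y"].to_numpy(float)))
    return tracks


def write_tracks(tracks: list[Track], path: str | os.PathLike) -> None:
    """Write tracks as CSV sorted by (track_id, frame); 10 significant digits."""
    rows = []
    for t in tracks:
        for f, px, py in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), px, py))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    df = df.sort_values(["track_id", "frame"], kind="stable")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_localizations(path: str | os.PathLike) -> dict[int, np.ndarray]:
    """Read a localization CSV (``frame,x,y``) grouped by frame.

    Returns a dict mapping frame index to an (n, 2) array of (x, y); frames
    with no localizations are simply absent.  Keys are in increasing order.
    """
    df = _read_table(path, ("frame", "x", "y"))
    out: dict[int, np.ndarray] = {}
    for frame, grp in df.groupby("frame", sort=True):
        out[int(frame)] = grp[["x", "y"]].to_numpy(float)
    return out


def write_localizations(locs: dict[int, np.ndarray], path: str | os.PathLike) -> None:
    """Write per-frame localizations as CSV, rows sorted by frame then x."""
    rows = []
    for frame in sorted(locs):
        pts = np.asarray(locs[frame], dtype=float).reshape(-1, 2)
        pts = pts[np.argsort(pts[:, 0], kind="stable")]
        for px, py in pts:
            rows.append((frame, px, py))
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
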