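"""Frame-to-frame track linking with gap closing and ambiguity exclusion.

Localizations are assigned to active track ends frame by frame as a global
minimum-cost bipartite matching with squared-distance cost (solved exactly via
the Hungarian algorithm).  A pair is admissible only if its distance is at
most ``max_link_distance * (gap + 1)`` where ``gap`` is the number of skipped
frames — a linear distance budget, conservative for diffusive motion whose
displacement grows with sqrt(time).  A track end left unmatched for more than
``max_frame_gap`` frames is closed; unmatched localizations seed new tracks.

Two localizations closer than ``exclusion_radius`` within a frame are mutually
ambiguous: both are dropped from that frame entirely (they neither extend nor
seed tracks), so no track passes through an ambiguous detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from sptkin.trackio import RunConfig, Track

__all__ = ["LinkParams", "FilterCounts", "link", "filter_tracks", "linking_fidelity"]

_BIG = 1e30  # cost sentinel for inadmissible pairs


class LinkParams(BaseModel):
    """Tracker settings: link distance, gap closing, exclusion, length filter."""

    model_config = ConfigDict(extra="ignore")

    max_link_distance: float = 0.800  # um per unit frame gap
    max_frame_gap: int = 3
    exclusion_radius: float = 1.200  # um
    min_track_steps: int = 30

    @field_validator("max_link_distance", "exclusion_radius")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("max_frame_gap")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("max_frame_gap must be >= 0")
        return v

    @model_validator(mode="after")
    def _ordering(self) -> "LinkParams":
        if self.exclusion_radius < self.max_link_distance:
            raise ValueError("exclusion_radius must be >= max_link_distance")
        return self

    @classmethod
    def from_run_config(cls, config: RunConfig) -> "LinkParams":
        return cls(
            max_link_distance=config.max_link_distance,
            max_frame_gap=config.max_frame_gap,
            exclusion_radius=config.exclusion_radius,
            min_track_steps=config.min_track_steps,
        )


@dataclass
class FilterCounts:
    """Bookkeeping for a filter stage; loaded = kept + removed always."""

    loaded: int
    kept: int
    removed: int

    def __post_init__(self) -> None:
        assert self.loaded == self.kept + self.removed, "filter stage must conserve track counts"


class _OpenTrack:
    __slots__ = ("frames", "xs", "ys")

    def __init__(self, frame: int, x: float, y: float) -> None:
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]

    def append(self, frame: int, x: float, y: float) -> None:
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)


def link(localizations: dict[int, np.ndarray], params: LinkParams) -> list[Track]:
    """Reconstruct tracks from per-frame localizations.

    ``localizations`` maps frame index to an (n, 2) array of positions; frames
    must be provided in increasing key order (as :func:`sptkin.trackio.read_localizations`
    returns them).  Output tracks are ordered by (first frame, x of first
    point) and assigned sequential ids.
    """
    frames = list(localizations)
    if frames != sorted(frames):
        raise ValueError("localizations must be sorted by frame")

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []

    for frame in frames:
        pts = np.asarray(localizations[frame], dtype=float).reshape(-1, 2)

        # retire track ends whose gap exceeds the budget
        still_open: list[_OpenTrack] = []
        for tr in open_tracks:
            if frame - tr.frames[-1] - 1 > params.max_frame_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        # symmetric exclusion of ambiguous (too-close) localizations
        if len(pts) > 1:
            d = cdist(pts, pts)
            np.fill_diagonal(d, np.inf)
            pts = pts[np.min(d, axis=1) > params.exclusion_radius]

        if len(pts) == 0:
            continue

        matched_pts = np.zeros(len(pts), dtype=bool)
        if open_tracks:
            ends = np.array([[tr.xs[-1], tr.ys[-1]] for tr in open_tracks])
            gaps = np.array([frame - tr.frames[-1] - 1 for tr in open_tracks])
            dist = cdist(ends, pts)
            budget = params.max_link_distance * (gaps + 1)
            cost = np.where(dist <= budget[:, None], dist**2, _BIG)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < _BIG:
                    open_tracks[r].append(frame, pts[c, 0], pts[c, 1])
                    matched_pts[c] = True

        for c in np.nonzero(~matched_pts)[0]:
            open_tracks.append(_OpenTrack(frame, pts[c, 0], pts[c, 1]))

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr.frames[0], tr.xs[0], tr.ys[0]))
    width = max(4, len(str(max(len(closed) - 1, 0))))
    return [Track(f"t{i:0{width}d}", np.array(tr.frames), np.array(tr.xs), np.array(tr.ys)) for i, tr in enumerate(closed)]


def filter_tracks(tracks: list[Track], params: LinkParams) -> tuple[list[Track], FilterCounts]:
    """Keep tracks with at least ``min_track_steps`` frame-to-frame steps."""
    kept = [t for t in tracks if t.n_steps >= params.min_track_steps]
    counts = FilterCounts(loaded=len(tracks), kept=len(kept), removed=len(tracks) - len(kept))
    return kept, counts


def linking_fidelity(tracks: list[Track], true_tracks: list[Track], decimals: int = 9) -> float | None:
    """Fraction of frame-to-frame links whose endpoints share a true particle.

    ``true_tracks`` are the identity-carrying tracks the localizations came
    from (coordinates must match exactly, as produced by
    :func:`sptkin.simulate.degrade_to_localizations`).  Returns None when the
    reconstruction contains no links at all (undefined rather than 1.0).
    """
    owner: dict[tuple[int, float, float], str] = {}
    for t in true_tracks:
        for f, px, py in zip(t.frames, t.x, t.y):
            owner[(int(f), round(float(px), decimals), round(float(py), decimals))] = t.track_id

    n_links = 0
    n_correct = 0
    for t in tracks:
        keys = [(int(f), round(float(px), decimals), round(float(py), decimals)) for f, px, py in zip(t.frames, t.x, t.y)]
        for a, b in zip(keys, keys[1:]):
            if a not in owner or b not in owner:
                raise ValueError(f"track {t.track_id!r}: localization {a if a not in owner else b} not found in ground truth")
            n_links += 1
            if owner[a] == owner[b]:
                n_correct += 1
    if n_links == 0:
        return None
    return n_correct / n_links
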