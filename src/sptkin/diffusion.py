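"""Mean-squared-displacement analysis and diffusion-coefficient estimation.

The time-averaged MSD of a 2D track at lag tau is the mean of
|r(t + tau) - r(t)|^2 over every frame pair present in the track (bridged gap
frames contribute no pairs).  For Brownian motion with static localization
noise sigma, E[MSD](tau) = 4 D tau + 4 sigma^2, so D is taken as slope/4 of a
weighted least-squares line through the first few lags with a free intercept —
the standard bias/variance compromise for short noisy tracks.  The anomalous
exponent alpha (log-log slope over the same lags) classifies motion as
confined (alpha < 0.8), Brownian (0.8 <= alpha <= 1.3) or directed
(alpha > 1.3); the class names follow common SPT usage, the cutoffs are
pipeline choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from sptkin.trackio import RunConfig, Track

__all__ = ["MotionClass", "MSDCurve", "DiffusionEstimate", "compute_msd", "estimate_D", "ensemble_msd", "analyze_tracks"]


class MotionClass(str, Enum):
    BROWNIAN = "BROWNIAN"
    DIRECTED = "DIRECTED"
    CONFINED = "CONFINED"


#: alpha range classified as Brownian; below = confined, above = directed
ALPHA_BROWNIAN_LOW = 0.8
ALPHA_BROWNIAN_HIGH = 1.3


@dataclass
class MSDCurve:
    """Time-averaged MSD versus lag time for one track or an ensemble."""

    lag_times: np.ndarray  # s, strictly increasing
    msd_values: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs averaged per lag
    n_tracks: int = 1

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd_values = np.asarray(self.msd_values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag_times must be strictly increasing")
        if np.any(self.msd_values < 0) or np.any(self.n_pairs < 1):
            raise ValueError("msd_values must be >= 0 and n_pairs >= 1")


@dataclass
class DiffusionEstimate:
    """Per-track diffusion estimate feeding the bound/free classifier."""

    D: float  # um^2/s, clipped at 0
    intercept: float  # um^2; ~4*sigma^2 for static localization noise
    n_lags_used: int
    alpha: float  # anomalous exponent; NaN when undefined (all-zero MSD)
    motion_class: MotionClass


def compute_msd(track: Track, max_lag: int, frame_interval: float) -> MSDCurve:
    """Time-averaged MSD with overlapping pairs, honouring detection gaps.

    Lags with no available frame pair are omitted from the curve.
    """
    if track.n_points < 2:
        raise ValueError("track must have at least 2 points")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag > track.n_steps:
        raise ValueError(f"max_lag {max_lag} exceeds track frame span {track.n_steps}")

    index = {int(f): i for i, f in enumerate(track.frames)}
    lags, msds, pairs = [], [], []
    for lag in range(1, max_lag + 1):
        i0, i1 = [], []
        for f, i in index.items():
            j = index.get(f + lag)
            if j is not None:
                i0.append(i)
                i1.append(j)
        if not i0:
            continue
        dx = track.x[i1] - track.x[i0]
        dy = track.y[i1] - track.y[i0]
        lags.append(lag * frame_interval)
        msds.append(float(np.mean(dx**2 + dy**2)))
        pairs.append(len(i0))
    return MSDCurve(np.array(lags), np.array(msds), np.array(pairs))


def estimate_D(msd: MSDCurve, n_lags: int) -> DiffusionEstimate:
    """Fit MSD(tau) = 4 D tau + intercept over the first ``n_lags`` lags.

    The line is weighted by the number of displacement pairs per lag; D is
    slope/4 clipped at zero.  alpha is the unweighted log-log slope over the
    same lags restricted to strictly positive MSD values; with fewer than two
    such lags alpha is undefined (NaN) and the track is classed as confined.
    """
    if len(msd.lag_times) < n_lags:
        raise ValueError(f"MSD curve has {len(msd.lag_times)} lags, need {n_lags}")
    tau = msd.lag_times[:n_lags]
    y = msd.msd_values[:n_lags]
    w = np.sqrt(msd.n_pairs[:n_lags].astype(float))
    slope, intercept = np.polyfit(tau, y, 1, w=w)
    D = max(float(slope) / 4.0, 0.0)

    pos = y > 0
    if np.count_nonzero(pos) >= 2:
        alpha = float(np.polyfit(np.log(tau[pos]), np.log(y[pos]), 1)[0])
    else:
        alpha = float("nan")

    if np.isnan(alpha) or alpha < ALPHA_BROWNIAN_LOW:
        cls = MotionClass.CONFINED
    elif alpha > ALPHA_BROWNIAN_HIGH:
        cls = MotionClass.DIRECTED
    else:
        cls = MotionClass.BROWNIAN
    return DiffusionEstimate(D=D, intercept=float(intercept), n_lags_used=int(n_lags), alpha=alpha, motion_class=cls)


def ensemble_msd(tracks: list[Track], max_lag: int, frame_interval: float, population_filter=None) -> MSDCurve:
    """Lag-wise pair-weighted average of per-track MSDs over a population.

    ``population_filter`` is an optional predicate on tracks; the returned
    curve records the population size in ``n_tracks``.
    """
    selected = [t for t in tracks if population_filter is None or population_filter(t)]
    if not selected:
        raise ValueError("ensemble MSD of an empty population")
    sums: dict[float, float] = {}
    counts: dict[float, int] = {}
    for t in selected:
        curve = compute_msd(t, min(max_lag, max(t.n_steps, 1)), frame_interval)
        for tau, m, npairs in zip(curve.lag_times, curve.msd_values, curve.n_pairs):
            sums[tau] = sums.get(tau, 0.0) + m * npairs
            counts[tau] = counts.get(tau, 0) + int(npairs)
    taus = np.array(sorted(sums))
    return MSDCurve(
        taus,
        np.array([sums[t] / counts[t] for t in taus]),
        np.array([counts[t] for t in taus]),
        n_tracks=len(selected),
    )


def analyze_tracks(tracks: list[Track], config: RunConfig) -> pd.DataFrame:
    """Per-track diffusion table: id, steps, duration, D, intercept, alpha, class."""
    rows = []
    for t in tracks:
        max_lag = min(config.msd_fit_lags, t.n_steps)
        curve = compute_msd(t, max_lag, config.frame_interval)
        if len(curve.lag_times) < 2:
            continue  # too gappy to fit a line through
        est = estimate_D(curve, min(config.msd_fit_lags, len(curve.lag_times)))
        rows.append(
            {
                "track_id": t.track_id,
                "n_steps": t.n_steps,
                "duration_s": t.duration(config.frame_interval),
                "D": est.D,
                "intercept": est.intercept,
                "alpha": est.alpha,
                "motion_class": est.motion_class.value,
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "n_steps", "duration_s", "D", "intercept", "alpha", "motion_class"])
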