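"""Bound/free and specific/non-specific classification of tracks.

A track is membrane-bound iff its diffusion coefficient is at or below the
threshold (default 1 um^2/s, inclusive), otherwise free.  Among bound tracks,
specific receptor engagement is identified by dwell time: strictly more than
``specific_min_steps`` frame-to-frame steps (default 100, i.e. longer than 1 s
at 100 fps); shorter bound tracks are treated as non-specific sticking.  The
dwell time of a bound track is its full duration — track termination by
bleaching or focal-plane exit therefore right-censors dwells, which the
kinetics module accounts for.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from sptkin.diffusion import DiffusionEstimate
from sptkin.trackio import RunConfig, Track

__all__ = [
    "Population",
    "Specificity",
    "BindingLabel",
    "classify_population",
    "classify_specificity",
    "label_tracks",
    "binding_percentage",
    "summarize_conditions",
]


class Population(str, Enum):
    BOUND = "BOUND"
    FREE = "FREE"


class Specificity(str, Enum):
    SPECIFIC = "SPECIFIC"
    NONSPECIFIC = "NONSPECIFIC"
    NA = "NA"


@dataclass
class BindingLabel:
    population: Population
    specificity: Specificity
    dwell_time: float | None  # s; track duration for bound tracks, None for free

    def __post_init__(self) -> None:
        if (self.specificity is Specificity.NA) != (self.population is Population.FREE):
            raise ValueError("specificity is NA iff the track is FREE")
        if self.population is Population.BOUND and not (self.dwell_time and self.dwell_time > 0):
            raise ValueError("bound tracks must carry a positive dwell time")


def classify_population(estimate: DiffusionEstimate | float, d_threshold: float) -> Population:
    """BOUND iff D <= d_threshold (inclusive boundary), else FREE."""
    D = estimate.D if isinstance(estimate, DiffusionEstimate) else float(estimate)
    return Population.BOUND if D <= d_threshold else Population.FREE


def classify_specificity(track: Track, population: Population, min_steps: int) -> Specificity:
    """SPECIFIC iff a bound track lasts strictly more than ``min_steps`` steps."""
    if population is not Population.BOUND:
        raise ValueError("specificity is only defined for BOUND tracks")
    return Specificity.SPECIFIC if track.n_steps > min_steps else Specificity.NONSPECIFIC


def label_tracks(tracks: list[Track], estimates: list[DiffusionEstimate | float], config: RunConfig) -> list[BindingLabel]:
    """Label each track bound/free and, if bound, specific/non-specific."""
    if len(tracks) != len(estimates):
        raise ValueError("tracks and estimates must align")
    labels = []
    for track, est in zip(tracks, estimates):
        pop = classify_population(est, config.d_threshold)
        if pop is Population.BOUND:
            spec = classify_specificity(track, pop, config.specific_min_steps)
            labels.append(BindingLabel(pop, spec, track.duration(config.frame_interval)))
        else:
            labels.append(BindingLabel(pop, Specificity.NA, None))
    return labels


def binding_percentage(labels: list[BindingLabel]) -> float:
    """100 x bound tracks / total tracks."""
    if not labels:
        raise ValueError("binding percentage of an empty track set")
    n_bound = sum(1 for lb in labels if lb.population is Population.BOUND)
    return 100.0 * n_bound / len(labels)


def summarize_conditions(per_track: pd.DataFrame) -> pd.DataFrame:
    """Per-condition binding summaries with mean +/- SEM over replicates.

    ``per_track`` has one row per track with columns ``condition``,
    ``replicate`` (biological replicate id; technical replicates are assumed
    already pooled into it), ``population`` and ``specificity``.  Percentages
    are computed per (condition, replicate) and then averaged across
    replicates; SEM = sd/sqrt(n_replicates), reported as NaN (undefined, not
    zero) for a single replicate.
    """
    required = {"condition", "replicate", "population", "specificity"}
    missing = required - set(per_track.columns)
    if missing:
        raise ValueError(f"per_track is missing columns {sorted(missing)}")
    if per_track.empty:
        raise ValueError("no tracks to summarize")

    rep = (
        per_track.assign(
            bound=per_track["population"].astype(str) == Population.BOUND.value,
            specific=per_track["specificity"].astype(str) == Specificity.SPECIFIC.value,
        )
        .groupby(["condition", "replicate"], sort=True)
        .agg(n_tracks=("bound", "size"), n_bound=("bound", "sum"), n_specific=("specific", "sum"))
        .reset_index()
    )
    rep["binding_pct"] = 100.0 * rep["n_bound"] / rep["n_tracks"]
    rep["specific_pct"] = 100.0 * rep["n_specific"] / rep["n_tracks"]

    def _sem(v: pd.Series) -> float:
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    out = (
        rep.groupby("condition", sort=True)
        .agg(
            n_replicates=("replicate", "nunique"),
            n_tracks=("n_tracks", "sum"),
            n_bound=("n_bound", "sum"),
            n_specific=("n_specific", "sum"),
            binding_pct_mean=("binding_pct", "mean"),
            binding_pct_sem=("binding_pct", _sem),
            specific_pct_mean=("specific_pct", "mean"),
            specific_pct_sem=("specific_pct", _sem),
        )
        .reset_index()
    )
    return out
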