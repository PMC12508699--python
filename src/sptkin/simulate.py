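"""Forward simulator for two-population membrane-binding SPT data.

Generates 2D trajectories of particles that diffuse freely (D_free, around
2.5 um^2/s for a ~150 nm nanostructure in buffer), bind receptors inside a
circular "cell" region at rate lambda_on, unbind at rate 1/tau_B_true, stick
non-specifically for short exponential dwells, photobleach (a generic track
termination hazard that also stands in for focal-plane exit), and carry
Gaussian localization noise.  Detection dropout is applied separately by
:func:`degrade_to_localizations`, which strips particle identities and creates
the linking problem the tracker has to solve.

The state machine runs at the frame interval with exponential transition
probabilities 1 - exp(-rate * dt) and at most one transition per frame; with
dt = 10 ms and dwell times of order seconds the discretization bias on a mean
dwell is about dt/2 (5 ms), negligible against the statistics analyzed.
Boundaries reflect, preserving particle number without drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from sptkin.trackio import Track

__all__ = [
    "FREE",
    "BOUND_SPECIFIC",
    "BOUND_NONSPECIFIC",
    "BLEACHED",
    "STATE_NAMES",
    "SimConfig",
    "BindingEvent",
    "GroundTruth",
    "simulate_ground_truth",
    "degrade_to_localizations",
]

FREE = 0
BOUND_SPECIFIC = 1
BOUND_NONSPECIFIC = 2
BLEACHED = 3
STATE_NAMES = {FREE: "FREE", BOUND_SPECIFIC: "BOUND_SPECIFIC", BOUND_NONSPECIFIC: "BOUND_NONSPECIFIC", BLEACHED: "BLEACHED"}

_BOUND_STATES = (BOUND_SPECIFIC, BOUND_NONSPECIFIC)


class SimConfig(BaseModel):
    """Simulation parameters.

    Defaults emulate the acquisition the analysis is designed for: 2000 frames
    at 10 ms/frame in a 50x50 um field with a 10-um-radius cell region, a fast
    free population at 2.5 um^2/s, a slow bound population well below the
    1 um^2/s classification threshold, mean specific dwell of a couple of
    seconds, sub-second non-specific sticking, 30 nm localization noise and a
    gentle bleaching hazard so many tracks survive the 30-step filter.
    """

    model_config = ConfigDict(extra="ignore")

    n_particles: int = 100
    n_frames: int = 2000
    frame_interval: float = 0.010  # s
    field_size: tuple[float, float] = (50.0, 50.0)  # um
    cell_center: tuple[float, float] | None = None  # default: field centre
    cell_radius: float = 10.0  # um
    D_free: float = 2.5  # um^2/s
    D_bound: float = 0.05  # um^2/s
    lambda_on: float = 0.5  # s^-1, binding rate while inside the cell region
    tau_B_true: float = 2.0  # s, mean specific bound dwell (= 1/k_off)
    lambda_nonspecific: float = 0.1  # s^-1
    tau_nonspecific: float = 0.3  # s, mean non-specific dwell
    loc_sigma: float = 0.030  # um, localization noise std per axis
    bleach_rate: float = 0.05  # s^-1, track termination hazard
    p_detect: float = 0.95
    init_bound_fraction: float = 0.0  # fraction of particles starting bound
    seed: int = 0

    @field_validator("n_particles")
    @classmethod
    def _np_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("n_particles must be >= 0")
        return v

    @field_validator("n_frames")
    @classmethod
    def _nf_pos(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("n_frames must be > 0")
        return v

    @field_validator("frame_interval", "cell_radius", "tau_B_true", "tau_nonspecific")
    @classmethod
    def _pos(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("lambda_on", "lambda_nonspecific", "bleach_rate", "loc_sigma", "D_bound")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("p_detect")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not (0 < v <= 1):
            raise ValueError("p_detect must be in (0, 1]")
        return v

    @field_validator("init_bound_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not (0 <= v <= 1):
            raise ValueError("init_bound_fraction must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _ordering(self) -> "SimConfig":
        if not self.D_free > self.D_bound:
            raise ValueError("D_free must exceed D_bound")
        return self

    @property
    def centre(self) -> np.ndarray:
        if self.cell_center is not None:
            return np.asarray(self.cell_center, dtype=float)
        return np.asarray(self.field_size, dtype=float) / 2.0


@dataclass(frozen=True)
class BindingEvent:
    """One contiguous bound interval of one particle.

    Frames ``start``..``end`` inclusive are spent bound; ``completed`` is True
    iff the interval ended by unbinding (False when cut short by bleaching or
    the end of the movie, i.e. right-censored).
    """

    particle: int
    start: int
    end: int
    kind: int  # BOUND_SPECIFIC or BOUND_NONSPECIFIC
    completed: bool

    def dwell(self, frame_interval: float) -> float:
        return (self.end - self.start + 1) * frame_interval


@dataclass
class GroundTruth:
    """Per-particle per-frame state labels plus the list of bound intervals."""

    states: np.ndarray  # (n_particles, n_frames) int8
    events: list[BindingEvent]
    frame_interval: float

    def dwell_times(self, kind: int = BOUND_SPECIFIC, completed_only: bool = True) -> np.ndarray:
        """Dwell times (s) of bound intervals of the given kind."""
        return np.array(
            [e.dwell(self.frame_interval) for e in self.events if e.kind == kind and (e.completed or not completed_only)],
            dtype=float,
        )


def _transition_prob(rate: float, dt: float) -> float:
    if rate <= 0 or not math.isfinite(rate):
        return 0.0 if rate <= 0 else 1.0
    return -math.expm1(-rate * dt)


def _reflect(pos: np.ndarray, size: np.ndarray) -> np.ndarray:
    # fold positions back into [0, L] (period 2L sawtooth)
    period = 2.0 * size
    p = np.mod(pos, period)
    return np.where(p > size, period - p, p)


def simulate_ground_truth(sim: SimConfig) -> tuple[list[Track], GroundTruth]:
    """Simulate trajectories and ground-truth state labels.

    Returns observed tracks (true positions plus localization noise, one point
    per frame until bleaching) carrying true particle identities, and a
    :class:`GroundTruth` with the full state matrix and bound-interval list.
    Fully reproducible from ``sim.seed``.
    """
    n, T = sim.n_particles, sim.n_frames
    dt = sim.frame_interval
    size = np.asarray(sim.field_size, dtype=float)
    centre = sim.centre
    rng = np.random.default_rng(sim.seed)

    states = np.full((n, T), BLEACHED, dtype=np.int8)
    obs = np.full((n, T, 2), np.nan)
    if n == 0:
        return [], GroundTruth(states, [], dt)

    pos = rng.uniform(low=[0.0, 0.0], high=size, size=(n, 2))
    state = np.zeros(n, dtype=np.int8)
    n_bound = int(round(sim.init_bound_fraction * n))
    if n_bound:
        idx = rng.choice(n, size=n_bound, replace=False)
        # bound particles start uniformly inside the cell region
        r = sim.cell_radius * np.sqrt(rng.random(n_bound))
        theta = rng.uniform(0, 2 * np.pi, n_bound)
        pos[idx] = centre + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pos[idx] = _reflect(pos[idx], size)
        state[idx] = BOUND_SPECIFIC

    p_bleach = _transition_prob(sim.bleach_rate, dt)
    p_bind_s = _transition_prob(sim.lambda_on, dt)
    p_bind_n = _transition_prob(sim.lambda_nonspecific, dt)
    p_unb_s = _transition_prob(1.0 / sim.tau_B_true, dt)
    p_unb_n = _transition_prob(1.0 / sim.tau_nonspecific, dt)
    step_sigma = np.array([math.sqrt(2 * sim.D_free * dt), math.sqrt(2 * sim.D_bound * dt), math.sqrt(2 * sim.D_bound * dt), 0.0])

    for t in range(T):
        states[:, t] = state
        alive = state != BLEACHED
        noise = rng.normal(0.0, sim.loc_sigma, size=(n, 2)) if sim.loc_sigma > 0 else np.zeros((n, 2))
        obs[alive, t] = pos[alive] + noise[alive]
        if t == T - 1:
            break

        u = rng.random(n)
        inside = np.sum((pos - centre) ** 2, axis=1) <= sim.cell_radius**2
        free = state == FREE
        bound_s = state == BOUND_SPECIFIC
        bound_n = state == BOUND_NONSPECIFIC

        # cumulative branch probabilities; at most one transition per frame
        c_bleach = np.where(alive, p_bleach, 0.0)
        c_bind_s = c_bleach + np.where(free & inside, p_bind_s, 0.0)
        c_bind_n = c_bind_s + np.where(free, p_bind_n, 0.0)
        c_unbind = c_bind_n + np.where(bound_s, p_unb_s, 0.0) + np.where(bound_n, p_unb_n, 0.0)

        new_state = state.copy()
        new_state[alive & (u < c_bleach)] = BLEACHED
        took = u < c_bleach
        new_state[~took & (u < c_bind_s)] = BOUND_SPECIFIC
        took |= u < c_bind_s
        new_state[~took & (u < c_bind_n)] = BOUND_NONSPECIFIC
        took |= u < c_bind_n
        new_state[~took & (u < c_unbind)] = FREE

        steps = rng.normal(0.0, 1.0, size=(n, 2)) * step_sigma[new_state][:, None]
        pos = _reflect(pos + steps, size)
        state = new_state

    tracks: list[Track] = []
    width = max(4, len(str(max(n - 1, 0))))
    for i in range(n):
        frames = np.nonzero(states[i] != BLEACHED)[0]
        if len(frames) == 0:
            continue
        tracks.append(Track(f"p{i:0{width}d}", frames, obs[i, frames, 0], obs[i, frames, 1]))

    events = _extract_events(states)
    return tracks, GroundTruth(states, events, dt)


def _extract_events(states: np.ndarray) -> list[BindingEvent]:
    events: list[BindingEvent] = []
    n, T = states.shape
    for i in range(n):
        s = states[i]
        boundary = np.nonzero(np.diff(s) != 0)[0]
        starts = np.concatenate([[0], boundary + 1])
        ends = np.concatenate([boundary, [T - 1]])
        for a, b in zip(starts, ends):
            kind = int(s[a])
            if kind not in _BOUND_STATES:
                continue
            nxt = int(s[b + 1]) if b + 1 < T else None
            completed = nxt == FREE
            events.append(BindingEvent(i, int(a), int(b), kind, completed))
    return events


def degrade_to_localizations(tracks: list[Track], sim: SimConfig) -> dict[int, np.ndarray]:
    """Strip particle identities and apply detection dropout.

    Each track point is kept independently with probability ``sim.p_detect``;
    the surviving points are pooled per frame and sorted by x, producing the
    anonymous localization tables a tracker starts from.  Uses a random stream
    independent of the simulation's so the same trajectories can be degraded
    reproducibly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 0xD7]))
    per_frame: dict[int, list[tuple[float, float]]] = {}
    for t in tracks:
        keep = rng.random(t.n_points) < sim.p_detect if sim.p_detect < 1 else np.ones(t.n_points, bool)
        for f, px, py in zip(t.frames[keep], t.x[keep], t.y[keep]):
            per_frame.setdefault(int(f), []).append((px, py))
    out: dict[int, np.ndarray] = {}
    for f in sorted(per_frame):
        pts = np.asarray(per_frame[f], dtype=float)
        out[f] = pts[np.argsort(pts[:, 0], kind="stable")]
    return out
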