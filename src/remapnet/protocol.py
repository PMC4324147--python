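"""Trial geometry, eye/stimulus kinematics, training sets and task batteries.

Spatial conventions: head-centered stimulus location ``h`` and retinal
locations live on [-45, 45] deg; retinotopic saccade targets ``s`` on
[-30, 30] deg. Every trial starts fixating straight ahead (eye position
``e0 = 0``), so the initial retinal stimulus location equals ``h``. With a
saccade ``s`` the post-saccadic retinal location is ``h - s``.

Absent stimulus / absent saccade are represented by ``None`` in
:class:`TrialSpec` and by ``NaN`` in sampled kinematic arrays, never by a
large float, so Gaussian drives evaluate to exactly zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Inclusive retinal / head-centered range represented by visual neurons (deg).
RETINAL_RANGE = (-45, 45)
#: Inclusive saccade-target range represented by saccade neurons (deg).
SACCADE_RANGE = (-30, 30)
#: Minimum saccade magnitude in training (deg).
MIN_SACCADE = 10

DEFAULT_SACCADE_SPEED = 300.0  # deg/s


def saccade_duration_ms(s: float, speed: float = DEFAULT_SACCADE_SPEED) -> float:
    """Duration of a constant-velocity saccade of amplitude ``s`` (ms)."""
    return abs(s) / speed * 1000.0


@dataclass(frozen=True)
class TrialSpec:
    """One trial's event times and geometry.

    ``h``: head-centered stimulus location (deg) or ``None`` if no stimulus.
    ``s``: retinotopic saccade target (deg) or ``None`` if no saccade.
    Stimulus is visible on ``[t_stim_on, t_stim_off)`` (ms); the saccade
    starts at ``t_sacc`` (ms). ``e0`` is always 0 (initial fixation).

    ``strict=False`` relaxes the requirement that the post-saccadic retinal
    location ``h - s`` stays on the retinal grid; control and delayed-flash
    trials may legitimately sweep the stimulus off the represented space.
    """

    h: Optional[float]
    s: Optional[float]
    t_stim_on: float
    t_stim_off: float
    t_sacc: Optional[float]
    duration: float
    e0: float = 0.0
    strict: bool = True
    tag: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("trial duration must be positive")
        if self.h is not None:
            if not RETINAL_RANGE[0] <= self.h <= RETINAL_RANGE[1]:
                raise ValueError(f"stimulus location {self.h} outside "
                                 f"{RETINAL_RANGE}")
            if not self.t_stim_on < self.t_stim_off <= self.duration:
                raise ValueError(
                    f"invalid stimulus window [{self.t_stim_on}, "
                    f"{self.t_stim_off}) for duration {self.duration}")
        if self.s is not None:
            if not SACCADE_RANGE[0] <= self.s <= SACCADE_RANGE[1]:
                raise ValueError(f"saccade target {self.s} outside "
                                 f"{SACCADE_RANGE}")
            if self.t_sacc is None or self.t_sacc < 0:
                raise ValueError("saccade present requires t_sacc >= 0")
            if self.strict and self.h is not None:
                post = self.h - self.s
                if not RETINAL_RANGE[0] <= post <= RETINAL_RANGE[1]:
                    raise ValueError(
                        f"post-saccadic retinal location {post} outside "
                        f"{RETINAL_RANGE} (h={self.h}, s={self.s})")

    @property
    def has_stimulus(self) -> bool:
        return self.h is not None

    @property
    def has_saccade(self) -> bool:
        return self.s is not None

    def saccade_end(self, speed: float = DEFAULT_SACCADE_SPEED) -> Optional[float]:
        if self.s is None:
            return None
        return self.t_sacc + saccade_duration_ms(self.s, speed)

    def to_dict(self) -> dict:
        return {
            "h": self.h, "s": self.s,
            "t_stim_on": self.t_stim_on, "t_stim_off": self.t_stim_off,
            "t_sacc": self.t_sacc, "duration": self.duration,
            "e0": self.e0, "strict": self.strict, "tag": self.tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialSpec":
        return cls(**d)


@dataclass(frozen=True)
class KinematicTrace:
    """Time-sampled eye position and retinal stimulus location of one trial.

    ``retinal_stim`` is ``NaN`` wherever the stimulus is not visible.
    """

    times: np.ndarray
    eye: np.ndarray
    retinal_stim: np.ndarray


def time_grid(duration: float, dt: float) -> np.ndarray:
    """Sample times 0, dt, ..., duration (duration snapped up to the grid)."""
    n = math.ceil(duration / dt - 1e-9)
    return np.arange(n + 1) * dt


def eye_position_trace(trial: TrialSpec, dt: float,
                       speed: float = DEFAULT_SACCADE_SPEED) -> np.ndarray:
    """Piecewise-linear eye position e(t): fixation, constant-velocity ramp
    to the saccade target, fixation at the target. Identically 0 with no
    saccade."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = time_grid(trial.duration, dt)
    if trial.s is None:
        return np.zeros_like(t)
    dur = saccade_duration_ms(trial.s, speed)
    if dur == 0.0:
        return np.zeros_like(t)
    frac = np.clip((t - trial.t_sacc) / dur, 0.0, 1.0)
    return trial.s * frac


def retinal_stimulus_trace(trial: TrialSpec, eye: np.ndarray,
                           dt: float) -> np.ndarray:
    """Retinal stimulus location h - e(t) on [t_stim_on, t_stim_off); NaN
    elsewhere."""
    t = time_grid(trial.duration, dt)
    if len(eye) != len(t):
        raise ValueError("eye trace not on the trial's time grid")
    psi = np.full_like(t, np.nan)
    if trial.h is not None:
        vis = (t >= trial.t_stim_on) & (t < trial.t_stim_off)
        psi[vis] = trial.h - eye[vis]
    return psi


def kinematics(trial: TrialSpec, dt: float,
               speed: float = DEFAULT_SACCADE_SPEED) -> KinematicTrace:
    eye = eye_position_trace(trial, dt, speed)
    psi = retinal_stimulus_trace(trial, eye, dt)
    return KinematicTrace(time_grid(trial.duration, dt), eye, psi)


# ---------------------------------------------------------------------------
# training sets

@dataclass(frozen=True)
class TrainingSet:
    """A seeded set of M training remappings (h_i, s_i).

    Each pair obeys the training constraints: integer h in [-45, 45],
    integer s in [-30, 30] with |s| >= 10, post-saccadic retinal location
    h - s in [-45, 45].
    """

    pairs: tuple
    seed: int

    def __post_init__(self) -> None:
        for h, s in self.pairs:
            if not pair_is_feasible(h, s):
                raise ValueError(f"infeasible training pair (h={h}, s={s})")

    @property
    def M(self) -> int:
        return len(self.pairs)

    def post_saccadic_locations(self) -> list:
        """Retinal location h_i - s_i each pair remaps the stimulus onto."""
        return [h - s for h, s in self.pairs]


def pair_is_feasible(h: int, s: int) -> bool:
    """Training-pair constraint: on-grid, saccade >= 10 deg, post-saccadic
    retinal location on the retinal grid."""
    return (RETINAL_RANGE[0] <= h <= RETINAL_RANGE[1]
            and SACCADE_RANGE[0] <= s <= SACCADE_RANGE[1]
            and abs(s) >= MIN_SACCADE
            and RETINAL_RANGE[0] <= h - s <= RETINAL_RANGE[1])


def enumerate_feasible_pairs() -> list:
    """All feasible integer (h, s) training pairs (oracle for samplers)."""
    return [(h, s)
            for h in range(RETINAL_RANGE[0], RETINAL_RANGE[1] + 1)
            for s in range(SACCADE_RANGE[0], SACCADE_RANGE[1] + 1)
            if pair_is_feasible(h, s)]


def sample_training_set(M: int, seed: int,
                        distinct_posts: bool = False) -> TrainingSet:
    """Sample M training pairs uniformly over the feasible integer set by
    rejection sampling; deterministic for a fixed seed.

    ``distinct_posts=True`` additionally rejects pairs whose post-saccadic
    location h - s duplicates an earlier pair's, so that the M remappings
    target M distinct remapping neurons (one analysis neuron per trial).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if distinct_posts and M > RETINAL_RANGE[1] - RETINAL_RANGE[0] + 1:
        raise ValueError("more pairs than distinct post-saccadic locations")
    rng = np.random.default_rng(seed)
    pairs = []
    posts = set()
    while len(pairs) < M:
        h = int(rng.integers(RETINAL_RANGE[0], RETINAL_RANGE[1] + 1))
        s = int(rng.integers(SACCADE_RANGE[0], SACCADE_RANGE[1] + 1))
        if not pair_is_feasible(h, s):
            continue
        if distinct_posts and h - s in posts:
            continue
        pairs.append((h, s))
        posts.add(h - s)
    return TrainingSet(tuple(pairs), seed)


def sample_multidirection_pairs(post_locations, per_target: int,
                                seed: int) -> TrainingSet:
    """For each post-saccadic target location r, sample ``per_target``
    distinct feasible (h, s) pairs with h - s = r.

    Used to train individual remapping neurons to remap from several
    different pre-saccadic stimulus locations.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    for r in post_locations:
        feasible = [(r + s, s)
                    for s in range(SACCADE_RANGE[0], SACCADE_RANGE[1] + 1)
                    if pair_is_feasible(r + s, s)]
        if len(feasible) < per_target:
            raise ValueError(
                f"only {len(feasible)} feasible pairs for target {r}")
        idx = rng.choice(len(feasible), size=per_target, replace=False)
        pairs.extend(feasible[i] for i in idx)
    return TrainingSet(tuple(pairs), seed)


# ---------------------------------------------------------------------------
# trial construction

def make_training_trial(h: int, s: int, dt: float = 2.0,
                        speed: float = DEFAULT_SACCADE_SPEED) -> TrialSpec:
    """One training trial: stimulus present for the whole trial, saccade at
    200 ms, 450 ms of post-saccadic fixation (duration snapped up to the
    integration grid; ~700 ms for a 15 deg saccade)."""
    if not pair_is_feasible(h, s):
        raise ValueError(
            f"(h={h}, s={s}) violates the training constraints: need "
            f"|s| >= {MIN_SACCADE} and h - s in {RETINAL_RANGE}")
    raw = 200.0 + saccade_duration_ms(s, speed) + 450.0
    duration = math.ceil(raw / dt - 1e-9) * dt
    return TrialSpec(h=h, s=s, t_stim_on=0.0, t_stim_off=duration,
                     t_sacc=200.0, duration=duration,
                     tag={"kind": "training", "h": h, "s": s})


def build_task_battery(kind: str, training_set: Optional[TrainingSet] = None,
                       flash_duration_ms: float = 50.0,
                       probe_duration_ms: float = 700.0) -> list:
    """Build one of the five test-task batteries.

    stimulus_control -- 91 trials, one 100-200 ms flash per integer retinal
      location, no saccade, 900 ms.
    saccade_control -- 61 trials, one saccade per integer target at 100 ms,
      no stimulus, 900 ms.
    probe -- 61 x 91 = 5551 trials, stimulus on for the whole trial, saccade
      at 200 ms.
    single_step -- one trial per training pair: 100 ms flash at h_i from
      100 ms, saccade s_i at 600 ms, 900 ms.
    delayed_flash -- per training pair, two families (current-RF at
      head-centered h_i - s_i, future-RF at h_i) x 13 onsets 100-700 ms in
      50 ms steps, ``flash_duration_ms`` flashes, saccade s_i at 600 ms.
    """
    lo_r, hi_r = RETINAL_RANGE
    lo_s, hi_s = SACCADE_RANGE
    if kind == "stimulus_control":
        return [TrialSpec(h=float(r), s=None, t_stim_on=100.0,
                          t_stim_off=200.0, t_sacc=None, duration=900.0,
                          tag={"kind": kind, "r": r})
                for r in range(lo_r, hi_r + 1)]
    if kind == "saccade_control":
        return [TrialSpec(h=None, s=float(s), t_stim_on=0.0, t_stim_off=0.0,
                          t_sacc=100.0, duration=900.0,
                          tag={"kind": kind, "s": s})
                for s in range(lo_s, hi_s + 1)]
    if kind == "probe":
        return [TrialSpec(h=float(r), s=float(s), t_stim_on=0.0,
                          t_stim_off=probe_duration_ms, t_sacc=200.0,
                          duration=probe_duration_ms, strict=False,
                          tag={"kind": kind, "r": r, "s": s})
                for s in range(lo_s, hi_s + 1)
                for r in range(lo_r, hi_r + 1)]
    if kind in ("single_step", "delayed_flash"):
        if training_set is None:
            raise ValueError(f"{kind} battery requires a training set")
        if kind == "single_step":
            return [TrialSpec(h=float(h), s=float(s), t_stim_on=100.0,
                              t_stim_off=200.0, t_sacc=600.0, duration=900.0,
                              tag={"kind": kind, "pair": i, "h": h, "s": s})
                    for i, (h, s) in enumerate(training_set.pairs)]
        onsets = [100.0 + 50.0 * k for k in range(13)]
        # long enough that the 300 ms stimulus-aligned analysis window of
        # the latest flash (onset 700 + 50 + 300 = 1050 ms) fits the trial
        dur = 1100.0
        trials = []
        for i, (h, s) in enumerate(training_set.pairs):
            # head-centered flash locations: the analysis neuron's RF sits at
            # h - s before the saccade (current RF) and at h after (future RF)
            for family, loc in (("current_RF", h - s), ("future_RF", h)):
                for onset in onsets:
                    trials.append(TrialSpec(
                        h=float(loc), s=float(s), t_stim_on=onset,
                        t_stim_off=onset + flash_duration_ms, t_sacc=600.0,
                        duration=dur, strict=False,
                        tag={"kind": kind, "pair": i, "family": family,
                             "onset": onset, "h": h, "s": s}))
        return trials
    raise ValueError(f"unknown battery kind {kind!r}")


def battery_to_json(trials, path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in trials], fh, indent=1)


def battery_from_json(path) -> list:
    with open(path) as fh:
        return [TrialSpec.from_dict(d) for d in json.load(fh)]
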