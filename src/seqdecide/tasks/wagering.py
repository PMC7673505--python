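"""Task 3: motion discrimination with post-decision wagering.

A random-dot movie of signed coherence ``coh`` (positive = leftward) plays
for T steps, T drawn uniformly from {1, 2, 3, 4, 6, 8}.  Ten motion units
(five per preferred direction) carry internal activations
``s = coh/10 + N(0, sigma^2)`` with ``sigma = 2.5`` (sign flipped for the
non-preferred direction) squashed through a logistic into the input range.
The momentary evidence e_t is the summed left-minus-right internal activation
and E its total over the movie.  On half of the trials a sure target appears
after the movie; the teacher takes the direction choice only when |E| exceeds
the linearly growing wagering threshold ``theta(T) = 5 + 2.5 T``, otherwise
the sure target, which pays a smaller but certain reward.

Input codec (22 units): 10 motion units, fixation point, left/right/sure
targets, blank, 5 actions (fixate/left/right/sure/elsewhere), 2 reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequences import ChannelMap, EventSequence, TrialRecord

__all__ = [
    "Task3Config",
    "motion_evidence",
    "wager_teacher_choice",
    "sample_task3_trial",
    "Task3Environment",
    "prechoice_index",
]

N_IN = 22
MOT_L = slice(0, 5)
MOT_R = slice(5, 10)
FIX_PT, TARG_L, TARG_R, TARG_S, BLANK = 10, 11, 12, 13, 14
ACT_FIX, ACT_LEFT, ACT_RIGHT, ACT_SURE, ACT_OTHER = 15, 16, 17, 18, 19
REW, NOREW = 20, 21
CHANNELS = ChannelMap(sensory=slice(0, 15), action=slice(15, 20), reward=slice(20, 22))
LEFT, RIGHT, SURE = 0, 1, 2

FIX_STEPS = 2
TARGET_STEPS = 1


@dataclass(frozen=True)
class Task3Config:
    coherences: tuple = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)
    durations: tuple = (1, 2, 3, 4, 6, 8)
    sigma: float = 2.5
    theta0: float = 5.0
    theta_slope: float = 2.5
    sure_prob: float = 0.5

    def theta(self, t: int) -> float:
        return self.theta0 + self.theta_slope * t


def motion_evidence(
    coherence: float, duration: int, cfg: Task3Config, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample the movie: (internal activations S, responses R, accumulated E).

    ``S`` is (duration, 10): columns 0-4 prefer leftward motion and see
    ``+coh/10`` drift, columns 5-9 see ``-coh/10``, each plus independent
    N(0, sigma^2) noise per step.  ``R = sigmoid(S)`` feeds the network;
    ``E = sum_t (sum_left S - sum_right S)`` drives the teacher.
    """
    drift = np.where(np.arange(10) < 5, coherence, -coherence) / 10.0
    S = drift[None, :] + rng.normal(0.0, cfg.sigma, size=(duration, 10))
    R = 1.0 / (1.0 + np.exp(-S))
    e_t = S[:, MOT_L].sum(axis=1) - S[:, MOT_R].sum(axis=1)
    return S, R, float(e_t.sum())


def wager_teacher_choice(E: float, duration: int, sure_available: bool, cfg: Task3Config) -> int:
    """Deterministic teacher: direction by the sign of E, wagering by |E| vs theta."""
    if sure_available and abs(E) <= cfg.theta(duration):
        return SURE
    return LEFT if E > 0 else RIGHT


def prechoice_index(duration: int) -> int:
    """Step index of the delay frame right before the choice (the sampling slot)."""
    return FIX_STEPS + TARGET_STEPS + duration


def _frames_passive(R: np.ndarray, sure_available: bool) -> np.ndarray:
    """Fixation, targets, movie frames, then one delay frame (the commit slot)."""
    T = R.shape[0]
    frames = np.zeros((FIX_STEPS + TARGET_STEPS + T + 1, N_IN))
    frames[:, ACT_FIX] = 1.0
    frames[:, FIX_PT] = 1.0
    frames[FIX_STEPS:, [TARG_L, TARG_R]] = 1.0
    frames[FIX_STEPS + TARGET_STEPS : FIX_STEPS + TARGET_STEPS + T, :10] = R
    if sure_available:
        frames[-1, TARG_S] = 1.0
    return frames


_TARGET_OF = {LEFT: TARG_L, RIGHT: TARG_R, SURE: TARG_S}
_ACTION_OF = {LEFT: ACT_LEFT, RIGHT: ACT_RIGHT, SURE: ACT_SURE}


def _frames_tail(choice: int, rewarded: bool) -> np.ndarray:
    tail = np.zeros((2, N_IN))
    tail[:, _TARGET_OF[choice]] = 1.0
    tail[:, _ACTION_OF[choice]] = 1.0
    tail[1, REW if rewarded else NOREW] = 1.0
    return tail


def sample_task3_trial(
    cfg: Task3Config,
    rng: np.random.Generator,
    coherence: float | None = None,
    duration: int | None = None,
    sure_available: bool | None = None,
) -> TrialRecord:
    """One teacher trial; the signed coherence's sign sets the correct side."""
    if coherence is None:
        coherence = float(rng.choice(cfg.coherences)) * (1.0 if rng.integers(2) == 0 else -1.0)
    if duration is None:
        duration = int(rng.choice(cfg.durations))
    if sure_available is None:
        sure_available = bool(rng.random() < cfg.sure_prob)
    S, R, E = motion_evidence(coherence, duration, cfg, rng)
    choice = wager_teacher_choice(E, duration, sure_available, cfg)
    if coherence > 0:
        correct = LEFT
    elif coherence < 0:
        correct = RIGHT
    else:
        correct = int(rng.integers(2))
    rewarded = (choice == correct) or (choice == SURE)
    frames = np.vstack([_frames_passive(R, sure_available), _frames_tail(choice, rewarded)])
    return TrialRecord(
        events=EventSequence(frames, CHANNELS),
        correct_target=correct,
        stimuli=coherence,
        choice=choice,
        rt_epochs=duration,
        rewarded=rewarded,
        info={
            "coherence": coherence,
            "duration": duration,
            "sure_available": sure_available,
            "evidence": E,
        },
    )


class Task3Environment:
    """Closed-loop single-trial environment; the choice is sampled at the delay frame."""

    def __init__(self, cfg: Task3Config, rng: np.random.Generator, **trial_kw):
        self.cfg = cfg
        self._rng = rng
        self._trial_kw = trial_kw
        self.n_in = N_IN
        self.channel_map = CHANNELS

    def reset(self, rng) -> np.ndarray:
        kw = dict(self._trial_kw)
        coh = kw.get("coherence")
        if coh is None:
            coh = float(self._rng.choice(self.cfg.coherences)) * (
                1.0 if self._rng.integers(2) == 0 else -1.0
            )
        self.duration = kw.get("duration") or int(self._rng.choice(self.cfg.durations))
        self.sure_available = kw.get("sure_available")
        if self.sure_available is None:
            self.sure_available = bool(self._rng.random() < self.cfg.sure_prob)
        self.coherence = coh
        _, R, self.E = motion_evidence(coh, self.duration, self.cfg, self._rng)
        self._passive = _frames_passive(R, self.sure_available)
        self._commit_slot = prechoice_index(self.duration)
        self._pos = 0
        self._tail = None
        self._tail_pos = 0
        self.choice = None
        self.rewarded = False
        self.aborted = False
        if coh > 0:
            self.correct_target = LEFT
        elif coh < 0:
            self.correct_target = RIGHT
        else:
            self.correct_target = int(rng.integers(2))
        return self._passive[0]

    def samples_action(self) -> bool:
        return self._tail is None

    def scripted_action(self) -> int:
        return _ACTION_OF[self.choice]

    def step(self, action: int, rng) -> tuple[np.ndarray | None, bool]:
        if self._tail is not None:
            self._tail_pos += 1
            if self._tail_pos < len(self._tail):
                return self._tail[self._tail_pos], False
            return None, True
        if action == ACT_FIX:
            self._pos += 1
            if self._pos >= len(self._passive):
                self.aborted = True
                return None, True
            return self._passive[self._pos], False
        valid_here = self._pos == self._commit_slot and action in (ACT_LEFT, ACT_RIGHT, ACT_SURE)
        if not valid_here or (action == ACT_SURE and not self.sure_available):
            self.aborted = True
            return None, True
        self.choice = {ACT_LEFT: LEFT, ACT_RIGHT: RIGHT, ACT_SURE: SURE}[action]
        self.rewarded = (self.choice == self.correct_target) or (self.choice == SURE)
        self._tail = _frames_tail(self.choice, self.rewarded)
        self._tail_pos = 0
        return self._tail[0], False

    def trial_record(self, frames: np.ndarray) -> TrialRecord:
        return TrialRecord(
            events=EventSequence(frames, CHANNELS),
            correct_target=self.correct_target,
            stimuli=self.coherence,
            choice=self.choice,
            rt_epochs=self.duration if self.choice is not None else None,
            rewarded=self.rewarded,
            aborted=self.aborted,
            info={
                "coherence": self.coherence,
                "duration": self.duration,
                "sure_available": self.sure_available,
                "evidence": self.E,
            },
        )
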