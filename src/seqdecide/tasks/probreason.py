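"""Task 1: reaction-time probabilistic reasoning ("weather prediction" with shapes).

A trial presents a stream of shapes drawn i.i.d. from one of two mirrored
10-symbol distributions, one per choice target.  Each shape carries a base-10
log likelihood ratio (logLR) in [-0.9, 0.9]; positive values support the left
target.  The teacher policy is a drift-diffusion model on the accumulated
logLR with collapsing bounds: commit to left (right) when the total crosses
the upper (lower) bound ``+-(bound0 - collapse * n)`` after the n-th shape.

Input codec (20 units):
  0-9   the ten shapes, ordered by descending logLR
  10    fixation point   11  left target   12  right target
  13    blank (no visual stimulus)
  14-17 actions: fixate, saccade left, saccade right, saccade elsewhere
  18-19 reward, no-reward
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequences import ChannelMap, EventSequence, TrialRecord

__all__ = [
    "ShapeCodebook",
    "DDMPolicyConfig",
    "Task1Timing",
    "build_codebook",
    "sample_task1_trial",
    "teacher_trials",
    "Task1Environment",
    "random_test_stream",
]

N_IN = 20
SHAPES = slice(0, 10)
FIX_PT, TARG_L, TARG_R, BLANK = 10, 11, 12, 13
ACT_FIX, ACT_LEFT, ACT_RIGHT, ACT_OTHER = 14, 15, 16, 17
REW, NOREW = 18, 19
CHANNELS = ChannelMap(sensory=slice(0, 14), action=slice(14, 18), reward=slice(18, 20))
LEFT, RIGHT = 0, 1

DEFAULT_WEIGHTS = (0.9, 0.7, 0.5, 0.3, 0.1, -0.1, -0.3, -0.5, -0.7, -0.9)


@dataclass(frozen=True)
class ShapeCodebook:
    """Ten shape logLRs and the two sampling distributions they induce."""

    weights: np.ndarray
    p_left: np.ndarray
    p_right: np.ndarray

    def mirror(self, i: int) -> int:
        """Index of the shape whose logLR is the negation of shape i's."""
        return int(np.argmin(np.abs(self.weights + self.weights[i])))


@dataclass(frozen=True)
class DDMPolicyConfig:
    """Collapsing-bound schedule of the teacher: +-(bound0 - collapse*n)."""

    bound0: float = 1.5
    collapse: float = 0.1
    max_shapes: int = 25

    def bound(self, n_shapes: int) -> float:
        return self.bound0 - self.collapse * n_shapes


@dataclass(frozen=True)
class Task1Timing:
    """Frame counts of each trial phase at the 100 ms step size.

    Pre-trial fixation, targets-on lead-in, then shape epochs of
    ``shape_on`` stimulus steps plus ``shape_off`` inter-shape steps.  The
    commit slot is the last shape-on step of each epoch: a saccade sampled
    there is a valid response, anywhere else it aborts the trial.
    """

    fix_steps: int = 3
    target_steps: int = 2
    shape_on: int = 2
    shape_off: int = 2

    @property
    def epoch_len(self) -> int:
        return self.shape_on + self.shape_off

    def shape_onset(self, epoch: int) -> int:
        """Time-step index of the first stimulus frame of 1-based ``epoch``."""
        return self.fix_steps + self.target_steps + self.epoch_len * (epoch - 1)

    def commit_slot(self, epoch: int) -> int:
        return self.shape_onset(epoch) + self.shape_on - 1

    def epoch_steps(self, epoch: int) -> np.ndarray:
        """All step indices of one epoch (stimulus plus inter-shape interval)."""
        start = self.shape_onset(epoch)
        return np.arange(start, start + self.epoch_len)


def build_codebook(weights=DEFAULT_WEIGHTS) -> ShapeCodebook:
    """Construct the unique mirror-symmetric sampling distributions.

    ``p_left(i) ~ 10^{w_i/2}`` and ``p_right(i) ~ 10^{-w_i/2}``; because the
    weight set is mirrored the two normalizers coincide and the per-shape
    log10 probability ratio equals the assigned logLR exactly.
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 1 or not np.allclose(np.sort(w), np.sort(-w)):
        raise ValueError("shape weights must come in +- mirrored pairs")
    p_left = 10.0 ** (w / 2.0)
    p_right = 10.0 ** (-w / 2.0)
    p_left /= p_left.sum()
    p_right /= p_right.sum()
    return ShapeCodebook(weights=w, p_left=p_left, p_right=p_right)


def _base_frame() -> np.ndarray:
    f = np.zeros(N_IN)
    f[ACT_FIX] = 1.0
    return f


def _passive_frames(timing: Task1Timing, shapes: np.ndarray) -> np.ndarray:
    """Stimulus schedule of a trial in which fixation is held throughout."""
    n = len(shapes)
    T = timing.fix_steps + timing.target_steps + timing.epoch_len * n
    frames = np.tile(_base_frame(), (T, 1))
    frames[: timing.fix_steps, FIX_PT] = 1.0
    frames[timing.fix_steps :, [FIX_PT, TARG_L, TARG_R]] = 1.0
    for e, shape in enumerate(shapes, start=1):
        on = timing.shape_onset(e)
        frames[on : on + timing.shape_on, shape] = 1.0
    return frames


def _tail_frames(choice: int, rewarded: bool) -> np.ndarray:
    """Saccade frame then outcome frame, after a commitment."""
    target = TARG_L if choice == LEFT else TARG_R
    act = ACT_LEFT if choice == LEFT else ACT_RIGHT
    tail = np.zeros((2, N_IN))
    tail[:, target] = 1.0
    tail[:, act] = 1.0
    tail[1, REW if rewarded else NOREW] = 1.0
    return tail


def _make_events(timing: Task1Timing, shapes, choice, rewarded) -> EventSequence:
    frames = _passive_frames(timing, np.asarray(shapes))
    if choice is not None:
        k = len(shapes)
        frames = frames[: timing.commit_slot(k) + 1]
        frames = np.vstack([frames, _tail_frames(choice, rewarded)])
    return EventSequence(frames, CHANNELS)


def ddm_choice(cum: float, bound: float, rng: np.random.Generator) -> int | None:
    """Absorption test after one shape: left/right index, or None if surviving."""
    up = cum >= bound - 1e-12
    down = cum <= -bound + 1e-12
    if up and down:  # collapsed bound straddled exactly: split by a fair coin
        return int(rng.integers(2))
    if up:
        return LEFT
    if down:
        return RIGHT
    return None


def sample_task1_trial(
    codebook: ShapeCodebook,
    ddm: DDMPolicyConfig = DDMPolicyConfig(),
    rng: np.random.Generator | None = None,
    timing: Task1Timing = Task1Timing(),
    shapes: np.ndarray | None = None,
    correct_target: int | None = None,
) -> TrialRecord:
    """One teacher trial: sample shapes, run the collapsing-bound DDM, encode.

    A forced shape stream (and correct target) may be supplied for
    deterministic traces.  Trials in which the accumulator never reaches a
    bound within ``max_shapes`` are marked non-committed (``choice=None``)
    and are excluded from training.
    """
    rng = np.random.default_rng() if rng is None else rng
    if correct_target is None:
        correct_target = int(rng.integers(2))
    p = codebook.p_left if correct_target == LEFT else codebook.p_right
    drawn: list[int] = []
    cum = 0.0
    choice = None
    for n in range(1, ddm.max_shapes + 1):
        if shapes is not None:
            if n > len(shapes):
                break
            s = int(shapes[n - 1])
        else:
            s = int(rng.choice(10, p=p))
        drawn.append(s)
        cum += codebook.weights[s]
        choice = ddm_choice(cum, ddm.bound(n), rng)
        if choice is not None:
            break
    rewarded = choice == correct_target if choice is not None else False
    events = _make_events(timing, drawn, choice, rewarded)
    return TrialRecord(
        events=events,
        correct_target=correct_target,
        stimuli=np.asarray(drawn),
        choice=choice,
        rt_epochs=len(drawn) if choice is not None else None,
        rewarded=rewarded,
        info={
            "total_logLR": float(np.sum(codebook.weights[drawn])),
            "final_logLR": float(codebook.weights[drawn[-1]]) if drawn else 0.0,
            "committed": choice is not None,
        },
    )


def teacher_trials(
    codebook: ShapeCodebook,
    ddm: DDMPolicyConfig = DDMPolicyConfig(),
    seed: int = 0,
    timing: Task1Timing = Task1Timing(),
    unique_sequences: int | None = None,
):
    """Infinite stream of teacher trials for the trainer.

    ``unique_sequences`` caps the diversity of the training set: that many
    trials are pre-generated and then resampled with replacement (the
    limited-diversity training variant).
    """
    rng = np.random.default_rng(seed)
    if unique_sequences is None:
        while True:
            yield sample_task1_trial(codebook, ddm, rng, timing)
    else:
        pool = [sample_task1_trial(codebook, ddm, rng, timing) for _ in range(unique_sequences)]
        while True:
            yield pool[int(rng.integers(len(pool)))]


def random_test_stream(codebook: ShapeCodebook, n: int, seed: int, n_shapes: int = 25):
    """Random (correct_target, 25-shape stream) pairs for closed-loop testing."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        tgt = int(rng.integers(2))
        p = codebook.p_left if tgt == LEFT else codebook.p_right
        out.append((tgt, rng.choice(10, p=p, size=n_shapes)))
    return out


class Task1Environment:
    """Closed-loop environment over a fixed 25-shape stream.

    The network holds fixation frame by frame; a left/right saccade sampled at
    a commit slot ends the stimulus stream and plays out the saccade and
    outcome frames.  A saccade anywhere else, a saccade to another location,
    or running out of shapes without responding aborts the trial.
    """

    def __init__(
        self,
        shapes: np.ndarray,
        correct_target: int,
        codebook: ShapeCodebook,
        timing: Task1Timing = Task1Timing(),
    ):
        self.shapes = np.asarray(shapes, dtype=np.intp)
        self.correct_target = int(correct_target)
        self.codebook = codebook
        self.timing = timing
        self.n_in = N_IN
        self.channel_map = CHANNELS

    def reset(self, rng) -> np.ndarray:
        self._passive = _passive_frames(self.timing, self.shapes)
        self._commit_slots = {
            self.timing.commit_slot(e): e for e in range(1, len(self.shapes) + 1)
        }
        self._pos = 0
        self._tail: np.ndarray | None = None
        self._tail_pos = 0
        self.choice: int | None = None
        self.rt_epochs: int | None = None
        self.rewarded = False
        self.aborted = False
        self.abort_reason: str | None = None
        return self._passive[0]

    def samples_action(self) -> bool:
        return self._tail is None

    def scripted_action(self) -> int:
        return ACT_LEFT if self.choice == LEFT else ACT_RIGHT

    def step(self, action: int, rng) -> tuple[np.ndarray | None, bool]:
        if self._tail is not None:
            self._tail_pos += 1
            if self._tail_pos < len(self._tail):
                return self._tail[self._tail_pos], False
            return None, True
        if action not in (ACT_FIX, ACT_LEFT, ACT_RIGHT, ACT_OTHER):
            raise ValueError(f"action {action} is outside the task codec")
        if action == ACT_FIX:
            self._pos += 1
            if self._pos >= len(self._passive):
                self.aborted = True
                self.abort_reason = "no_response"
                return None, True
            return self._passive[self._pos], False
        if action == ACT_OTHER or self._pos not in self._commit_slots:
            self.aborted = True
            self.abort_reason = "fixation_break" if self._pos < self.timing.shape_onset(1) else "bad_timing"
            return None, True
        self.choice = LEFT if action == ACT_LEFT else RIGHT
        self.rt_epochs = self._commit_slots[self._pos]
        self.rewarded = self.choice == self.correct_target
        self._tail = _tail_frames(self.choice, self.rewarded)
        self._tail_pos = 0
        return self._tail[0], False

    def trial_record(self, frames: np.ndarray) -> TrialRecord:
        shown = self.shapes[: self.rt_epochs] if self.rt_epochs else self.shapes
        w = self.codebook.weights
        return TrialRecord(
            events=EventSequence(frames, CHANNELS),
            correct_target=self.correct_target,
            stimuli=np.asarray(shown),
            choice=self.choice,
            rt_epochs=self.rt_epochs,
            rewarded=self.rewarded,
            aborted=self.aborted,
            info={
                "total_logLR": float(np.sum(w[shown])) if len(shown) else 0.0,
                "final_logLR": float(w[shown[-1]]) if len(shown) else 0.0,
                "abort_reason": self.abort_reason,
            },
        )
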