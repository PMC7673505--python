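"""Task 4: the two-step task with block-wise reward reversals.

A first-stage choice between options A1 and A2 leads to intermediate outcome
B1 or B2; A1 commonly (probability ``p_common``) transitions to B1 and A2 to
B2.  The B states pay a Bernoulli reward with probabilities 0.8 / 0.2 that
swap every ``block_len`` trials.  The training set consists of trials with
uniformly random choices; rewarded trials alone drive learning.  Trials are
short (4 frames) and the hidden state is carried across them, so contingency
across trials is the only route to above-chance reward.

Input codec (10 units): 2 option cues, 2 intermediate-state cues, blank,
3 actions (hold / choose A1 / choose A2), 2 reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..sequences import ChannelMap, EventSequence, TrialRecord

__all__ = [
    "TwoStepConfig",
    "TwoStepWorld",
    "twostep_env_step",
    "sample_task4_dataset",
    "TwoStepEnvironment",
    "encode_task4_trial",
    "DECISION_STEP",
]

N_IN = 10
OPT_1, OPT_2, B_1, B_2, BLANK = 0, 1, 2, 3, 4
ACT_HOLD, ACT_A1, ACT_A2 = 5, 6, 7
REW, NOREW = 8, 9
CHANNELS = ChannelMap(sensory=slice(0, 5), action=slice(5, 8), reward=slice(8, 10))

DECISION_STEP = 1  # the options frame; the first-stage choice is sampled here


@dataclass(frozen=True)
class TwoStepConfig:
    """Transition and reward structure.  ``p_common`` is the A_i -> B_i probability."""

    p_common: float = 0.8
    reward_probs: tuple = (0.8, 0.2)
    block_len: int = 50

    def __post_init__(self) -> None:
        if not 0.5 < self.p_common < 1.0:
            raise ValueError("p_common must be in (0.5, 1)")
        if abs(sum(self.reward_probs) - 1.0) > 1e-12:
            raise ValueError("reward probabilities must sum to 1 across the B states")


class TwoStepWorld:
    """Persistent task state: trial counter and the current block's contingency."""

    def __init__(self, cfg: TwoStepConfig, block_len: int | None = None):
        self.cfg = cfg
        self.block_len = block_len or cfg.block_len
        self.trial_index = 0

    @property
    def good_b(self) -> int:
        """Which B state currently pays at the high rate (0 or 1)."""
        return (self.trial_index // self.block_len) % 2

    def reward_prob(self, b: int) -> float:
        hi, lo = self.cfg.reward_probs
        return hi if b == self.good_b else lo

    def transition(self, action: int, rng: np.random.Generator) -> tuple[int, bool]:
        """Resolve one trial: (intermediate state index, rewarded)."""
        common = rng.random() < self.cfg.p_common
        b = action if common else 1 - action
        rewarded = bool(rng.random() < self.reward_prob(b))
        self.trial_index += 1
        return b, rewarded


def twostep_env_step(world: TwoStepWorld, action: int, rng: np.random.Generator):
    """Functional form of one environment transition (state advances in place)."""
    if action not in (0, 1):
        raise ValueError("action must be 0 (A1) or 1 (A2)")
    b, rewarded = world.transition(action, rng)
    return b, rewarded, world


def encode_task4_trial(choice: int, b: int, rewarded: bool) -> EventSequence:
    """Four frames: inter-trial blank, options on, B cue + efference, outcome."""
    frames = np.zeros((4, N_IN))
    frames[:, ACT_HOLD] = 1.0
    frames[0, BLANK] = 1.0
    frames[1, [OPT_1, OPT_2]] = 1.0
    frames[2, B_1 if b == 0 else B_2] = 1.0
    frames[2, ACT_HOLD] = 0.0
    frames[2, ACT_A1 if choice == 0 else ACT_A2] = 1.0
    frames[3, BLANK] = 1.0
    frames[3, REW if rewarded else NOREW] = 1.0
    return EventSequence(frames, CHANNELS)


def _record(choice, b, rewarded, world_index, common, good_b) -> TrialRecord:
    return TrialRecord(
        events=encode_task4_trial(choice, b, rewarded),
        correct_target=good_b,  # the option whose common outcome currently pays 0.8
        stimuli=None,
        choice=choice,
        rt_epochs=1,
        rewarded=rewarded,
        info={"b_state": b, "common": common, "trial_index": world_index, "good_b": good_b},
    )


def sample_task4_dataset(cfg: TwoStepConfig, n_blocks: int, rng: np.random.Generator):
    """Training stream: uniformly random choices through the block structure."""
    world = TwoStepWorld(cfg)
    for _ in range(n_blocks * cfg.block_len):
        choice = int(rng.integers(2))
        idx = world.trial_index
        good_b = world.good_b
        b, rewarded = world.transition(choice, rng)
        yield _record(choice, b, rewarded, idx, common=(b == choice), good_b=good_b)


class TwoStepEnvironment:
    """Closed-loop single-trial wrapper around a shared :class:`TwoStepWorld`.

    Only the options frame samples an action (restrict the policy's action
    set to the A1/A2 output units); the other frames are scripted holds.
    """

    def __init__(self, world: TwoStepWorld):
        self.world = world
        self.n_in = N_IN
        self.channel_map = CHANNELS

    def reset(self, rng) -> np.ndarray:
        self._frames = np.zeros((4, N_IN))
        self._frames[0, BLANK] = 1.0
        self._frames[0, ACT_HOLD] = 1.0
        self._frames[1, [OPT_1, OPT_2]] = 1.0
        self._frames[1, ACT_HOLD] = 1.0
        self._pos = 0
        self.choice = None
        self.b_state = None
        self.rewarded = False
        return self._frames[0]

    def samples_action(self) -> bool:
        return self._pos == DECISION_STEP

    def scripted_action(self) -> int:
        return ACT_HOLD

    def step(self, action: int, rng) -> tuple[np.ndarray | None, bool]:
        pos = self._pos
        self._pos += 1
        if pos == 0:
            return self._frames[1], False
        if pos == DECISION_STEP:
            if action not in (ACT_A1, ACT_A2):
                raise ValueError("the decision step requires an A1/A2 action")
            self.choice = 0 if action == ACT_A1 else 1
            self._trial_index = self.world.trial_index
            self._good_b = self.world.good_b
            self.b_state, self.rewarded = self.world.transition(self.choice, rng)
            frame = np.zeros(N_IN)
            frame[B_1 if self.b_state == 0 else B_2] = 1.0
            frame[ACT_A1 if self.choice == 0 else ACT_A2] = 1.0
            self._frames[2] = frame
            return frame, False
        if pos == 2:
            frame = np.zeros(N_IN)
            frame[BLANK] = 1.0
            frame[ACT_HOLD] = 1.0
            frame[REW if self.rewarded else NOREW] = 1.0
            self._frames[3] = frame
            return frame, False
        return None, True

    def trial_record(self, frames: np.ndarray) -> TrialRecord:
        return _record(
            self.choice,
            self.b_state,
            self.rewarded,
            self._trial_index,
            common=(self.b_state == self.choice),
            good_b=self._good_b,
        )
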