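"""Task 2: heading discrimination with visual and vestibular cues.

Two 8-unit populations encode heading direction D (degrees, positive =
leftward by package convention) with Gaussian tuning curves; each unit's
spike count is Poisson with mean ``g * f(D)`` and its input activation is the
squashed count ``r = 1 / (1 + exp(1 - s))``.  The teacher is a Bayesian ideal
observer: it forms the discretized posterior over headings from the spike
counts (the bimodal posterior is the normalized product of the unimodal ones)
and picks the side with more posterior mass.  Training uses only the unimodal
conditions; the bimodal condition probes generalization.

Input codec (26 units): 8 visual + 8 vestibular tuned units, fixation point,
left/right targets, blank, 4 actions (fixate/left/right/elsewhere), 2 reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ..sequences import ChannelMap, EventSequence, TrialRecord

__all__ = [
    "Task2Config",
    "tuning_response",
    "bayes_ideal_choice",
    "sample_task2_trial",
    "Task2Environment",
    "ideal_observer_choices",
]

N_IN = 26
VIS = slice(0, 8)
VEST = slice(8, 16)
FIX_PT, TARG_L, TARG_R, BLANK = 16, 17, 18, 19
ACT_FIX, ACT_LEFT, ACT_RIGHT, ACT_OTHER = 20, 21, 22, 23
REW, NOREW = 24, 25
CHANNELS = ChannelMap(sensory=slice(0, 20), action=slice(20, 24), reward=slice(24, 26))
LEFT, RIGHT = 0, 1

_PREFERRED = (-90.0, -64.3, -38.6, -12.9, 12.9, 38.6, 64.3, 90.0)


@dataclass(frozen=True)
class Task2Config:
    preferred_dirs: tuple = _PREFERRED
    sigma_tuning: float = 45.0
    gain: float = 300.0
    stimulus_headings: tuple = (-16.0, -8.0, -4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
    posterior_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-90.0, 90.0, 181), compare=False
    )
    neutral_response: float = 0.5


def tuning_curve(heading: float, cfg: Task2Config) -> np.ndarray:
    """Gaussian tuning f(D): normal density of D - D_pref with SD sigma."""
    d = heading - np.asarray(cfg.preferred_dirs)
    s = cfg.sigma_tuning
    return np.exp(-0.5 * (d / s) ** 2) / (s * np.sqrt(2.0 * np.pi))


def tuning_response(
    heading: float, cfg: Task2Config, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one population response: (spike counts s, activations r).

    ``s ~ Poisson(g * f(D))`` per unit and ``r = 1/(1 + exp(1 - s))``, so a
    single spike maps to exactly 0.5 and responses stay inside (0, 1).
    """
    if abs(heading) > 90.0:
        raise ValueError("|heading| must be <= 90 degrees")
    mean = cfg.gain * tuning_curve(heading, cfg)
    s = rng.poisson(mean).astype(np.float64)
    r = 1.0 / (1.0 + np.exp(1.0 - s))
    return s, r


def posterior_over_headings(spikes: np.ndarray, cfg: Task2Config) -> np.ndarray:
    """Discretized posterior p(D | s) on the posterior grid, in probability units.

    Computed in log space: log p(D|s) = sum_i [ -g f_i(D) + s_i log(g f_i(D)) ]
    up to the normalizer (flat prior over the grid).
    """
    grid = cfg.posterior_grid
    f = cfg.gain * np.stack([tuning_curve(d, cfg) for d in grid])  # (n_grid, 8)
    logp = np.sum(-f + spikes[None, :] * np.log(f), axis=1)
    return np.exp(logp - logsumexp(logp))


def bayes_ideal_choice(
    spikes, cfg: Task2Config, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Ideal-observer posterior and left/right choice from spike counts.

    ``spikes`` is one modality's count vector or a list of vectors (bimodal:
    the posteriors multiply, i.e. log-likelihoods add).  Grid points at
    exactly 0 degrees are excluded from the mass comparison; an exact tie is
    broken by a fair coin when an rng is supplied, otherwise toward right.
    """
    arrs = [np.asarray(spikes)] if np.asarray(spikes[0]).ndim == 0 else [np.asarray(a) for a in spikes]
    grid = cfg.posterior_grid
    f = cfg.gain * np.stack([tuning_curve(d, cfg) for d in grid])
    logp = np.zeros(len(grid))
    for s in arrs:
        if np.any(s < 0) or not np.allclose(s, np.round(s)):
            raise ValueError("spike counts must be nonnegative integers")
        logp += np.sum(-f + s[None, :] * np.log(f), axis=1)
    post = np.exp(logp - logsumexp(logp))
    if not np.isfinite(post).all() or post.sum() <= 0:
        raise FloatingPointError("posterior vanished; log-space accumulation failed")
    mass_left = post[grid > 0].sum()
    mass_right = post[grid < 0].sum()
    if mass_left > mass_right:
        choice = LEFT
    elif mass_right > mass_left:
        choice = RIGHT
    else:
        choice = int(rng.integers(2)) if rng is not None else RIGHT
    return post, choice


def _frames_passive(cfg: Task2Config, r_vis: np.ndarray, r_vest: np.ndarray) -> np.ndarray:
    """Fixation (2), targets on (1), stimulus (1); commit slot is the stimulus frame."""
    T = 4
    frames = np.zeros((T, N_IN))
    frames[:, ACT_FIX] = 1.0
    frames[:, FIX_PT] = 1.0
    frames[2:, [TARG_L, TARG_R]] = 1.0
    frames[:, VIS] = cfg.neutral_response
    frames[:, VEST] = cfg.neutral_response
    frames[3, VIS] = r_vis
    frames[3, VEST] = r_vest
    return frames


def _frames_tail(choice: int, rewarded: bool) -> np.ndarray:
    tail = np.zeros((2, N_IN))
    tail[:, VIS] = 0.5  # tuned units sit at the neutral response off-stimulus
    tail[:, VEST] = 0.5
    tail[:, TARG_L if choice == LEFT else TARG_R] = 1.0
    tail[:, ACT_LEFT if choice == LEFT else ACT_RIGHT] = 1.0
    tail[1, REW if rewarded else NOREW] = 1.0
    return tail


STIM_STEP = 3  # index of the stimulus frame; the pre-choice snapshot step


def _draw_stimulus(cfg, condition, heading, rng):
    neutral = cfg.neutral_response
    s_by_mod = {}
    r_vis = np.full(8, neutral)
    r_vest = np.full(8, neutral)
    if condition in ("visual", "bimodal"):
        s, r_vis = tuning_response(heading, cfg, rng)
        s_by_mod["visual"] = s
    if condition in ("vestibular", "bimodal"):
        s, r_vest = tuning_response(heading, cfg, rng)
        s_by_mod["vestibular"] = s
    return s_by_mod, r_vis, r_vest


def sample_task2_trial(
    cfg: Task2Config,
    rng: np.random.Generator,
    condition: str = "visual",
    heading: float | None = None,
) -> TrialRecord:
    """One teacher trial under the given condition.

    The absent modality's units sit at the neutral response (0.5) with no
    noise.  The teacher choice is the ideal observer's; reward requires the
    choice to match the heading sign (a coin flip at heading 0).
    """
    if heading is None:
        heading = float(rng.choice(cfg.stimulus_headings))
    s_by_mod, r_vis, r_vest = _draw_stimulus(cfg, condition, heading, rng)
    _, choice = bayes_ideal_choice(list(s_by_mod.values()), cfg, rng)
    if heading > 0:
        correct = LEFT
    elif heading < 0:
        correct = RIGHT
    else:
        correct = int(rng.integers(2))
    rewarded = choice == correct
    frames = np.vstack([_frames_passive(cfg, r_vis, r_vest), _frames_tail(choice, rewarded)])
    return TrialRecord(
        events=EventSequence(frames, CHANNELS),
        correct_target=correct,
        stimuli=heading,
        choice=choice,
        rt_epochs=1,
        rewarded=rewarded,
        info={"condition": condition, "heading": heading},
    )


def ideal_observer_choices(
    cfg: Task2Config, condition: str, headings: np.ndarray, n_per_heading: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated ideal-observer choice fractions: (headings repeated, left=1)."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for d in headings:
        for _ in range(n_per_heading):
            s_by_mod, _, _ = _draw_stimulus(cfg, condition, float(d), rng)
            _, choice = bayes_ideal_choice(list(s_by_mod.values()), cfg, rng)
            xs.append(d)
            ys.append(1 if choice == LEFT else 0)
    return np.asarray(xs, dtype=float), np.asarray(ys)


class Task2Environment:
    """Closed-loop single-trial environment (saccade sampled at the stimulus frame)."""

    def __init__(self, cfg: Task2Config, condition: str, heading: float, rng: np.random.Generator):
        self.cfg = cfg
        self.condition = condition
        self.heading = float(heading)
        self.n_in = N_IN
        self.channel_map = CHANNELS
        self._stim_rng = rng

    def reset(self, rng) -> np.ndarray:
        _, r_vis, r_vest = _draw_stimulus(self.cfg, self.condition, self.heading, self._stim_rng)
        self._passive = _frames_passive(self.cfg, r_vis, r_vest)
        self._pos = 0
        self._tail = None
        self._tail_pos = 0
        self.choice = None
        self.rewarded = False
        self.aborted = False
        if self.heading > 0:
            self.correct_target = LEFT
        elif self.heading < 0:
            self.correct_target = RIGHT
        else:
            self.correct_target = int(rng.integers(2))
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
        if action == ACT_FIX:
            self._pos += 1
            if self._pos >= len(self._passive):
                self.aborted = True
                return None, True
            return self._passive[self._pos], False
        if action == ACT_OTHER or self._pos != STIM_STEP:
            self.aborted = True
            return None, True
        self.choice = LEFT if action == ACT_LEFT else RIGHT
        self.rewarded = self.choice == self.correct_target
        self._tail = _frames_tail(self.choice, self.rewarded)
        self._tail_pos = 0
        return self._tail[0], False

    def trial_record(self, frames: np.ndarray) -> TrialRecord:
        return TrialRecord(
            events=EventSequence(frames, CHANNELS),
            correct_target=self.correct_target,
            stimuli=self.heading,
            choice=self.choice,
            rt_epochs=1 if self.choice is not None else None,
            rewarded=self.rewarded,
            aborted=self.aborted,
            info={"condition": self.condition, "heading": self.heading},
        )
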