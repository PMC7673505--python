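"""Event sequences and trial records.

An :class:`EventSequence` is the lingua franca of the package: a ``T x N_IL``
matrix of input-unit activations on a 100 ms time grid, with named channel
ranges for the sensory, action, and reward units.  Each task defines a codec
(a fixed assignment of units to stimuli, efference copies, and reward
outcomes) and emits trials as :class:`TrialRecord` objects wrapping one
sequence plus its behavioral metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ChannelMap", "EventSequence", "TrialRecord"]


@dataclass(frozen=True)
class ChannelMap:
    """Partition of the input units into sensory, action, and reward ranges."""

    sensory: slice
    action: slice
    reward: slice

    @property
    def n_units(self) -> int:
        return max(s.stop for s in (self.sensory, self.action, self.reward))

    def validate(self) -> None:
        slices = [self.sensory, self.action, self.reward]
        covered: list[int] = []
        for s in slices:
            if s.step not in (None, 1) or s.start < 0 or s.stop <= s.start:
                raise ValueError(f"channel slice {s} must be a forward unit-step range")
            covered.extend(range(s.start, s.stop))
        if sorted(covered) != list(range(self.n_units)):
            raise ValueError("channel ranges must partition [0, n_units) without overlap")

    def action_indices(self) -> np.ndarray:
        return np.arange(self.action.start, self.action.stop)


@dataclass
class EventSequence:
    """Time x input-unit activation matrix with named channel ranges.

    Entries lie in [0, 1]: binary presence for discrete events, continuous
    strength for graded sensory responses.  In generated sequences exactly one
    action-channel unit is active per time step (the efference copy of the
    single executable action).
    """

    activations: np.ndarray
    channel_map: ChannelMap
    dt_ms: float = 100.0

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=np.float64)

    @property
    def n_steps(self) -> int:
        return self.activations.shape[0]

    @property
    def n_units(self) -> int:
        return self.activations.shape[1]

    def validate(self) -> None:
        a = self.activations
        if a.ndim != 2 or a.shape[0] < 2:
            raise ValueError("activations must be a T x N matrix with T >= 2")
        if not np.all(np.isfinite(a)):
            raise ValueError("activations must be finite")
        if a.min() < 0.0 or a.max() > 1.0:
            raise ValueError("activations must lie in [0, 1]")
        self.channel_map.validate()
        if self.channel_map.n_units != self.n_units:
            raise ValueError("channel map does not cover the activation columns")
        acts = a[:, self.channel_map.action]
        if not np.allclose((acts == 1.0).sum(axis=1), 1.0):
            raise ValueError("exactly one action unit must be 1 at each time step")

    def to_frame(self):
        """Trace as a pandas DataFrame (one row per time step) for CSV export."""
        import pandas as pd

        return pd.DataFrame(self.activations, columns=[f"u{i}" for i in range(self.n_units)])


@dataclass
class TrialRecord:
    """One trial: its event sequence plus behavioral metadata.

    ``choice`` is None for aborted or non-committed trials.  ``rt_epochs``
    counts stimulus epochs up to the commitment (the standard reaction-time
    unit for epoch-based tasks).  ``hidden`` optionally carries the
    recorded hidden-state trace of a closed-loop run.
    """

    events: EventSequence
    correct_target: int | None
    stimuli: Any
    choice: int | None
    rt_epochs: int | None
    rewarded: bool
    aborted: bool = False
    hidden: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        """Loggable summary (no event matrix) for JSONL trial logs."""
        stim = self.stimuli
        if isinstance(stim, np.ndarray):
            stim = stim.tolist()
        return {
            "correct_target": self.correct_target,
            "stimuli": stim,
            "choice": self.choice,
            "rt_epochs": self.rt_epochs,
            "rewarded": bool(self.rewarded),
            "aborted": bool(self.aborted),
            **{k: v for k, v in self.info.items() if np.isscalar(v)},
        }
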