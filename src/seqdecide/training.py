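"""Supervised next-event prediction training.

The loss for one trial is the summed per-step mean squared error between the
output trace and the next input frame::

    L = sum_{t=1}^{T-1} |y_t - x_{t+1}|^2 / N_OL

Parameters are updated at the end of every (rewarded) trial with the Adam
recurrences as printed in the source model description -- i.e. WITHOUT the
bias-correction terms of standard Adam -- after clipping the global gradient
norm at ``clip_norm``.  For the two-step task, the hidden state is carried
across trials and gradients are propagated one trial further back than the
loss (a two-trial unroll window with the loss masked to the current trial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import gru_backward, gru_forward
from .core import GRUParams
from .sequences import EventSequence, TrialRecord

__all__ = [
    "AdamState",
    "TrainConfig",
    "TrainLog",
    "sequence_loss",
    "backprop",
    "clip_gradient",
    "adam_step",
    "train",
]


@dataclass
class AdamState:
    """First/second gradient moments over the flat parameter vector."""

    m: np.ndarray
    v: np.ndarray
    t: int = 0
    eta: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8

    @classmethod
    def zeros(cls, params: GRUParams, eta: float = 1e-3, **kw) -> "AdamState":
        n = params.flat.size
        return cls(m=np.zeros(n), v=np.zeros(n), eta=eta, **kw)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults follow the study conditions: learning rate 1e-3 for the
    epoch-based tasks (1e-4 for the two-step task, set per task by the
    harness), gradient clipping at 0.25, updates on rewarded trials only, and
    a training set of 7.5e5 trials at full scale.
    """

    eta: float = 1e-3
    clip_norm: float = 0.25
    n_trials: int = 750_000
    rewarded_only: bool = True
    carry_state: bool = False
    bptt_trials: int = 1
    seed: int = 0
    bias_correction: bool = False
    clip_mode: str = "global"  # or "per_tensor"
    checkpoint_every: int = 5000

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.clip_norm <= 0:
            raise ValueError("eta and clip_norm must be positive")
        if self.bptt_trials not in (1, 2):
            raise ValueError("bptt_trials must be 1 or 2")


@dataclass
class TrainLog:
    """Per-checkpoint training diagnostics, serializable as JSONL."""

    records: list[dict] = field(default_factory=list)
    early_stop: bool = False

    def append(self, **kw) -> None:
        if self.records and kw.get("trial", 0) < self.records[-1]["trial"]:
            raise ValueError("trial indices must be monotone")
        self.records.append(kw)

    def to_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def _as_matrix(seq: EventSequence | np.ndarray) -> np.ndarray:
    if isinstance(seq, EventSequence):
        return np.ascontiguousarray(seq.activations, dtype=np.float64)
    return np.ascontiguousarray(seq, dtype=np.float64)


def sequence_loss(outputs: np.ndarray, seq: EventSequence | np.ndarray) -> float:
    """Next-event MSE loss of an output trace against its source sequence.

    ``outputs`` may have T or T-1 rows; with T rows the final row (which has
    no target frame) is ignored.
    """
    X = _as_matrix(seq)
    Y = np.asarray(outputs, dtype=np.float64)
    T = X.shape[0]
    if Y.shape[0] == T:
        Y = Y[:-1]
    if Y.shape != (T - 1, X.shape[1]):
        raise ValueError(f"output trace shape {outputs.shape} does not align with a {X.shape} sequence")
    diff = Y - X[1:]
    return float(np.sum(diff * diff) / X.shape[1])


def backprop(
    params: GRUParams,
    seq: EventSequence | np.ndarray,
    horizon: int = 1,
    prev_seq: EventSequence | np.ndarray | None = None,
    h0: np.ndarray | None = None,
    loss_mask: np.ndarray | None = None,
) -> tuple[GRUParams, float]:
    """Gradients of the sequence loss with respect to every parameter tensor.

    With ``horizon=2`` and a previous trial supplied, the unroll window is the
    concatenation of both trials, the loss is restricted to predictions of the
    current trial's frames, and truncation happens at the start of the
    previous trial.  Returns ``(grads, loss)`` with the gradients packed in a
    GRUParams-shaped container.
    """
    X = _as_matrix(seq)
    if horizon == 2 and prev_seq is not None:
        Xp = _as_matrix(prev_seq)
        X = np.vstack([Xp, X])
        loss_mask = np.zeros(X.shape[0] - 1)
        loss_mask[Xp.shape[0] - 1 :] = 1.0
    if h0 is None:
        h0 = np.zeros(params.n_hidden)
    if loss_mask is None:
        loss_mask = np.ones(X.shape[0] - 1)
    H, S, Z, R, C, Y = gru_forward(*params.tensors(), X, h0)
    grads = params.zeros_like()
    loss = gru_backward(*params.tensors(), X, h0, H, S, Z, R, C, Y, loss_mask, *grads.tensors())
    if not np.all(np.isfinite(grads.flat)):
        bad = [n for n in GRUParams.shapes(1, 1, 1) if not np.all(np.isfinite(getattr(grads, n)))]
        raise FloatingPointError(f"non-finite gradient in tensors: {bad}")
    return grads, float(loss)


def clip_gradient(g: GRUParams, clip_norm: float, mode: str = "global") -> GRUParams:
    """Rescale gradients so their norm does not exceed ``clip_norm``.

    The default reads the clipping rule as a single global norm over all
    tensors; ``mode='per_tensor'`` clips each tensor's norm independently.
    """
    if mode == "global":
        norm = float(np.linalg.norm(g.flat))
        if norm > clip_norm:
            g.flat *= clip_norm / norm
    elif mode == "per_tensor":
        for t in g.tensors():
            norm = float(np.linalg.norm(t))
            if norm > clip_norm:
                t *= clip_norm / norm
    else:
        raise ValueError(f"unknown clip mode {mode!r}")
    return g


def adam_step(
    params: GRUParams, adam: AdamState, g: GRUParams, bias_correction: bool = False
) -> tuple[GRUParams, AdamState]:
    """One Adam update, in place, as printed (no bias correction by default).

    ``theta <- theta - eta * m / (sqrt(v) + eps)`` with the usual moment
    recurrences.  Standard bias-corrected Adam is available behind the flag
    for robustness experiments.
    """
    adam.t += 1
    gf = g.flat
    adam.m *= adam.beta1
    adam.m += (1.0 - adam.beta1) * gf
    adam.v *= adam.beta2
    adam.v += (1.0 - adam.beta2) * gf * gf
    m, v = adam.m, adam.v
    if bias_correction:
        m = m / (1.0 - adam.beta1**adam.t)
        v = v / (1.0 - adam.beta2**adam.t)
    params.flat -= adam.eta * m / (np.sqrt(v) + adam.epsilon)
    return params, adam


def _usable(trial: TrialRecord, rewarded_only: bool) -> bool:
    # aborted and non-committed teacher trials carry no usable action sequence
    if trial.aborted or trial.choice is None:
        return False
    return trial.rewarded or not rewarded_only


def train(params: GRUParams, generator, cfg: TrainConfig, probe=None) -> tuple[GRUParams, TrainLog]:
    """Per-trial training loop: filter, forward, backprop, clip, Adam.

    ``generator`` is an iterable of TrialRecords.  With ``cfg.carry_state``
    the hidden state is threaded through every trial (trained or not), and
    updates unroll over the current plus the previous trial.  ``probe``, if
    given, is called as ``probe(params)`` at each checkpoint and its dict
    result merged into the log record.
    """
    adam = AdamState.zeros(params, eta=cfg.eta)
    log = TrainLog()
    it = iter(generator)
    h_run = np.zeros(params.n_hidden)
    prev_X: np.ndarray | None = None
    prev_h0: np.ndarray | None = None
    window_losses: list[float] = []
    n_updates = 0
    for i in range(cfg.n_trials):
        try:
            trial = next(it)
        except StopIteration:
            warnings.warn(f"trial generator exhausted after {i} of {cfg.n_trials} trials")
            log.early_stop = True
            log.append(trial=i, event="early_stop")
            break
        X = _as_matrix(trial.events)
        use = _usable(trial, cfg.rewarded_only)
        if cfg.carry_state:
            h0 = h_run.copy()
            H, *_ = gru_forward(*params.tensors(), X, h0)
            if use:
                if cfg.bptt_trials == 2 and prev_X is not None:
                    grads, loss = backprop(params, X, horizon=2, prev_seq=prev_X, h0=prev_h0)
                else:
                    grads, loss = backprop(params, X, h0=h0)
                clip_gradient(grads, cfg.clip_norm, cfg.clip_mode)
                adam_step(params, adam, grads, cfg.bias_correction)
                window_losses.append(loss)
                n_updates += 1
            h_run = H[-1].copy()
            prev_X, prev_h0 = X, h0
        elif use:
            grads, loss = backprop(params, X)
            clip_gradient(grads, cfg.clip_norm, cfg.clip_mode)
            adam_step(params, adam, grads, cfg.bias_correction)
            window_losses.append(loss)
            n_updates += 1
        if (i + 1) % cfg.checkpoint_every == 0:
            rec = {
                "trial": i + 1,
                "loss": float(np.mean(window_losses)) if window_losses else None,
                "n_updates": n_updates,
            }
            if probe is not None:
                rec.update(probe(params))
            log.append(**rec)
            window_losses = []
    return params, log
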