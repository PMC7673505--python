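"""The three-layer gated recurrent network.

The hidden layer is a GRU with one departure from the textbook cell: the new
state is passed through a rectified-linear function so unit activities stay
non-negative, like firing rates.  With update gate ``z``, reset gate ``r``,
input ``x_t`` and previous state ``h_{t-1}``::

    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    s_t = (1 - z_t) * h_{t-1} + z_t * tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
    h_t = max(s_t, 0)
    y_t = sigmoid(W_o h_t)

The output layer mirrors the input layer: ``y_t`` is the network's prediction
of the next input frame ``x_{t+1}``.  Sensory and reward predictions are
thresholded at 0.5; the executed action is drawn from a softmax over the
action output units with inverse temperature beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequences import EventSequence, TrialRecord

__all__ = [
    "GRUParams",
    "NetworkState",
    "StepOutput",
    "ActionPolicy",
    "init_params",
    "gru_step",
    "predict_events",
    "sample_action",
    "run_open_loop",
    "run_closed_loop",
]

_FIELDS = ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "b_z", "b_r", "b_h", "W_o")


class GRUParams:
    """All connection weights and biases of the network.

    The ten tensors are views into a single flat float64 buffer, so the
    optimizer and gradient clipping can treat the whole parameter set as one
    contiguous vector while the network code addresses named matrices.
    """

    __slots__ = ("n_in", "n_hidden", "n_out", "flat") + _FIELDS

    def __init__(self, n_in: int, n_hidden: int, n_out: int, flat: np.ndarray | None = None):
        if min(n_in, n_hidden, n_out) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.n_in, self.n_hidden, self.n_out = int(n_in), int(n_hidden), int(n_out)
        shapes = self.shapes(n_in, n_hidden, n_out)
        size = sum(int(np.prod(s)) for s in shapes.values())
        if flat is None:
            flat = np.zeros(size, dtype=np.float64)
        flat = np.ascontiguousarray(flat, dtype=np.float64)
        if flat.shape != (size,):
            raise ValueError(f"flat buffer must have shape ({size},)")
        self.flat = flat
        offset = 0
        for name, shape in shapes.items():
            n = int(np.prod(shape))
            object.__setattr__(self, name, flat[offset : offset + n].reshape(shape))
            offset += n

    @staticmethod
    def shapes(n_in: int, n_hidden: int, n_out: int) -> dict[str, tuple[int, ...]]:
        return {
            "W_z": (n_hidden, n_in),
            "W_r": (n_hidden, n_in),
            "W_h": (n_hidden, n_in),
            "U_z": (n_hidden, n_hidden),
            "U_r": (n_hidden, n_hidden),
            "U_h": (n_hidden, n_hidden),
            "b_z": (n_hidden,),
            "b_r": (n_hidden,),
            "b_h": (n_hidden,),
            "W_o": (n_out, n_hidden),
        }

    def tensors(self) -> tuple[np.ndarray, ...]:
        return tuple(getattr(self, name) for name in _FIELDS)

    def copy(self) -> "GRUParams":
        return GRUParams(self.n_in, self.n_hidden, self.n_out, self.flat.copy())

    def zeros_like(self) -> "GRUParams":
        return GRUParams(self.n_in, self.n_hidden, self.n_out)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.flat)):
            raise ValueError("parameters contain non-finite entries")

    def __eq__(self, other) -> bool:  # value equality, used by checkpoint tests
        return (
            isinstance(other, GRUParams)
            and (self.n_in, self.n_hidden, self.n_out) == (other.n_in, other.n_hidden, other.n_out)
            and np.array_equal(self.flat, other.flat)
        )


@dataclass
class NetworkState:
    """Non-negative hidden state vector plus a step counter."""

    h: np.ndarray
    step_index: int = 0

    @classmethod
    def zeros(cls, n_hidden: int) -> "NetworkState":
        return cls(h=np.zeros(n_hidden), step_index=0)


@dataclass
class StepOutput:
    """Output-layer activities and the gate vectors of one step."""

    y: np.ndarray
    z_gate: np.ndarray
    r_gate: np.ndarray


@dataclass
class ActionPolicy:
    """Softmax action selection over the action output units.

    ``beta`` is the inverse temperature of the softmax.  The default was set
    with ``scripts/calibrate_beta.py`` so a trained probabilistic-reasoning
    model aborts a few percent of test trials, matching the behavioral regime
    the analyses assume.  ``tie_rule`` is the value emitted by
    :func:`predict_events` when an output sits exactly at the 0.5 threshold.
    """

    beta: float = 7.2
    action_indices: np.ndarray = field(default_factory=lambda: np.arange(0))
    tie_rule: int = 0

    def __post_init__(self) -> None:
        self.action_indices = np.asarray(self.action_indices, dtype=np.intp)
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


def init_params(n_in: int, n_hidden: int, n_out: int, seed: int) -> GRUParams:
    """Initialize weights uniformly in (-k, k) with k = 1/sqrt(fan-in).

    Biases start at zero.  The scheme keeps pre-activations of order one, so
    the sigmoids start unsaturated; it is deterministic given the seed.
    """
    params = GRUParams(n_in, n_hidden, n_out)
    rng = np.random.default_rng(seed)
    for name in ("W_z", "W_r", "W_h", "U_z", "U_r", "U_h", "W_o"):
        w = getattr(params, name)
        k = 1.0 / np.sqrt(w.shape[1])
        w[...] = rng.uniform(-k, k, size=w.shape)
    return params


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


def gru_step(params: GRUParams, state: NetworkState, x: np.ndarray) -> tuple[NetworkState, StepOutput]:
    """Advance the hidden state by one input frame and read out the prediction."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (params.n_in,):
        raise ValueError(f"input must have shape ({params.n_in},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite entries")
    h_prev = state.h
    if h_prev.shape != (params.n_hidden,):
        raise ValueError("hidden state has the wrong length")
    z = _sigmoid(params.W_z @ x + params.U_z @ h_prev + params.b_z)
    r = _sigmoid(params.W_r @ x + params.U_r @ h_prev + params.b_r)
    cand = np.tanh(params.W_h @ x + params.U_h @ (r * h_prev) + params.b_h)
    s = (1.0 - z) * h_prev + z * cand
    h = np.maximum(s, 0.0)
    y = _sigmoid(params.W_o @ h)
    return NetworkState(h=h, step_index=state.step_index + 1), StepOutput(y=y, z_gate=z, r_gate=r)


def predict_events(y: np.ndarray | StepOutput, policy: ActionPolicy | None = None) -> np.ndarray:
    """Binary event prediction: 1 where y > 0.5, 0 where y < 0.5.

    An output sitting exactly at 0.5 carries no evidence either way and is
    mapped to the policy's tie_rule (default 0: event absent).
    """
    if isinstance(y, StepOutput):
        y = y.y
    y = np.asarray(y)
    tie = 0 if policy is None else policy.tie_rule
    out = np.where(y > 0.5, 1, np.where(y < 0.5, 0, tie))
    return out.astype(np.int8)


def softmax_action_probs(y: np.ndarray | StepOutput, policy: ActionPolicy) -> np.ndarray:
    """P(action i) = exp(beta * y_i) / sum_j exp(beta * y_j) over the action set."""
    if isinstance(y, StepOutput):
        y = y.y
    idx = policy.action_indices
    if idx.size == 0:
        raise ValueError("policy has an empty action set")
    if not np.isfinite(policy.beta):
        raise ValueError("beta must be finite")
    a = policy.beta * np.asarray(y, dtype=np.float64)[idx]
    a -= a.max()
    e = np.exp(a)
    return e / e.sum()


def sample_action(y: np.ndarray | StepOutput, policy: ActionPolicy, rng: np.random.Generator) -> int:
    """Draw one action index (into the full output vector) from the softmax."""
    p = softmax_action_probs(y, policy)
    k = rng.choice(p.size, p=p)
    return int(policy.action_indices[k])


def run_open_loop(
    params: GRUParams, seq: EventSequence, record_hidden: bool = True
) -> tuple[np.ndarray | None, np.ndarray]:
    """Teacher-forced pass over a recorded sequence with a per-trial state reset.

    Returns ``(hidden_trace, output_trace)`` of shapes ``(T, n_hidden)`` and
    ``(T, n_out)``.  No action sampling takes place; this is the pass used by
    the trainer and by the unit-level analyses.
    """
    from ._kernels import gru_forward

    X = np.ascontiguousarray(seq.activations, dtype=np.float64)
    if X.shape[1] != params.n_in:
        raise ValueError("sequence width does not match the network input size")
    h0 = np.zeros(params.n_hidden)
    H, _, _, _, _, Y = gru_forward(*params.tensors(), X, h0)
    return (H if record_hidden else None), Y


def run_closed_loop(
    params: GRUParams,
    env,
    policy: ActionPolicy,
    rng: np.random.Generator,
    carry_state: bool = False,
    state: NetworkState | None = None,
    record_hidden: bool = False,
) -> TrialRecord:
    """Run one trial with the network in the loop.

    At every step the network sees the current input frame, the sampled action
    is handed to the environment, and the environment answers with the next
    frame (or a terminal status).  The hidden state starts at zero unless
    ``carry_state`` is set and a ``state`` from the previous trial is given.
    """
    if carry_state and state is not None:
        net_state = state
    else:
        net_state = NetworkState.zeros(params.n_hidden)
    x = env.reset(rng)
    frames = [x]
    hidden = [] if record_hidden else None
    while True:
        try:
            net_state, out = gru_step(params, net_state, x)
        except ValueError as exc:
            raise RuntimeError(f"environment produced an invalid frame: {exc}") from exc
        if record_hidden:
            hidden.append(net_state.h.copy())
        if env.samples_action():
            action = sample_action(out, policy, rng)
        else:
            action = env.scripted_action()
        x, done = env.step(action, rng)
        if done:
            break
        frames.append(x)
    record = env.trial_record(np.asarray(frames))
    if record_hidden:
        record.hidden = np.asarray(hidden)
    record.info["final_state"] = net_state
    return record
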