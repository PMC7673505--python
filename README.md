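# seqdecide

Sequence-learning models of flexible and adaptive decision making.

The package asks how much of trained decision-making behavior falls out of
one simple objective: predict the next event. A three-layer gated recurrent
network receives a time-discretized stream of sensory, action, and reward
events and is trained, by supervised learning, to predict the next input
frame; its action predictions, passed through a softmax, *are* its behavior
at test time. The same architecture, retrained on each task's event
statistics, reproduces the signatures of evidence accumulation, Bayesian cue
integration, decision confidence, and model-based reinforcement learning —
without any dedicated decision circuitry.

It is aimed at computational/systems neuroscientists who want to train,
probe, and lesion such models, and at anyone who needs clean generative
implementations of the four tasks.

## The model

The hidden layer is a GRU with rectified (non-negative) state:

    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)           update gate
    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)           reset gate
    s_t = (1 − z_t)∘h_{t−1} + z_t∘tanh(W_h x_t + U_h(r_t∘h_{t−1}) + b_h)
    h_t = [s_t]₊                                    N_h = 128 units
    y_t = σ(W_o h_t)                                mirrors the input layer

Training minimizes `L = Σ_t |y_t − x_{t+1}|²/N_OL` per trial with Adam
(as-printed variant, no bias correction; η = 1e-3, or 1e-4 for the two-step
task) and global gradient clipping at 0.25, on rewarded trials only. At test
the executed action is sampled with `P(aᵢ) ∝ exp(β·yᵢ)` over the action
outputs. Backpropagation through time is hand-written (numpy + numba) and
verified against finite differences in the test suite.

## The four tasks

| module | paradigm | teacher / oracle |
|---|---|---|
| `tasks.probreason` | reaction-time probabilistic reasoning over 10 shapes with logLRs in ±0.9 | drift-diffusion on accumulated logLR, bounds ±(1.5 − 0.1·n) |
| `tasks.multisensory` | visual/vestibular heading discrimination (8-unit Poisson populations, σ = 45°, g = 300) | discretized Bayesian posterior; bimodal = product of unimodal |
| `tasks.wagering` | random-dot motion with a post-decision sure target | accumulated evidence vs. threshold θ(T) = 5 + 2.5·T |
| `tasks.twostep` | two-step bandit, common/rare transitions, 0.8/0.2 rewards reversing each 50-trial block | — (random-choice training set) |

`behavior` holds the choice-level analyses (psychometric and subjective-
weight regressions, exact collapsing-bound DDM fitting, stay probabilities,
L1 trial-history and five-factor regressions, the six-parameter hybrid
model-free/model-based RL fit, Q-value decoding); `units` the unit-level
ones (selectivity regression, response variability, when/which indices,
virtual lesions, connectivity-graph geodesics and max flows, shape-
prediction KL profiles). `harness` orchestrates train → test → analyze runs
and checkpointing; `seqdecide` is also a CLI (`seqdecide gen/run/report`).

## Worked example

Train the probabilistic-reasoning model on 20,000 drift-diffusion teacher
trials (about a minute on one CPU), test it closed-loop, and fit the DDM to
its behavior:

```python
import numpy as np
from seqdecide import behavior
from seqdecide.harness import train_task1, test_task1

params, log, codebook = train_task1(n_trials=20_000, seed=11)
records, metrics = test_task1(params, codebook, n_sequences=1500, seed=2)
print(f"abort rate:             {metrics['abort_pct']:.2f} %")
print(f"choice accuracy:        {metrics['accuracy_pct']:.2f} %")
print(f"last-shape consistency: {metrics['last_shape_consistency_pct']:.2f} %")
print(f"mean reaction time:     {metrics['mean_rt_epochs']:.2f} shapes")

completed = [r for r in records if not r.aborted]
ddm = behavior.fit_ddm_collapsing(completed, codebook)
print(f"DDM fit: bound0={ddm.bound0:.2f}, collapse={ddm.collapse:.3f}, "
      f"variance captured={100 * ddm.variance_captured:.1f} %")
```

prints

```
abort rate:             4.93 %
choice accuracy:        96.07 %
last-shape consistency: 99.72 %
mean reaction time:     3.88 shapes
DDM fit: bound0=1.31, collapse=0.052, variance captured=89.7 %
```

Reading these numbers: the network almost never responds at a disallowed
moment (aborts), chooses the target supported by the accumulated evidence
(~96% rewarded), and its final shape before commitment almost always agrees
with its choice — the hallmark of a bound-crossing policy. Fitting the
two-parameter collapsing-bound DDM to the joint reaction-time/evidence
curves recovers a bound near the teacher's 1.5 that shrinks over time, and
captures most of the variance of the behavior. (At this deliberately small
training scale the fit is a little looser than with the longer recipe used
by the acceptance script below.)

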