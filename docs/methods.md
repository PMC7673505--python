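# Methods

## Model

The network has three layers. An input layer of `N_IL` units carries a
time-discretized (100 ms steps) stream of sensory, action, and reward events;
each unit is a binary event indicator or a continuous response in [0, 1]. The
hidden layer has `N_h = 128` gated recurrent units with one modification to
the standard cell: the new state is rectified so activities stay
non-negative, like firing rates,

    z_t = σ(W_z x_t + U_z h_{t−1} + b_z)
    r_t = σ(W_r x_t + U_r h_{t−1} + b_r)
    s_t = (1 − z_t) ∘ h_{t−1} + z_t ∘ tanh(W_h x_t + U_h (r_t ∘ h_{t−1}) + b_h)
    h_t = [s_t]₊
    y_t = σ(W_o h_t)

The output layer mirrors the input layer: `y_t` is the prediction of the next
input frame `x_{t+1}`. Sensory/reward predictions threshold at 0.5 (an exact
0.5 maps to "absent"; configurable tie rule). The executed action is sampled
from a softmax over the action output units with inverse temperature β; the
fixation/hold action competes in the softmax at every step.

Training minimizes the summed per-step mean squared prediction error
`L = Σ_t |y_t − x_{t+1}|² / N_OL`, updated at the end of each trial by the
Adam recurrences *without* bias correction (a config switch restores standard
Adam), after clipping the global gradient norm at 0.25. Learning rate is
1e-3, except 1e-4 for the two-step task. Only rewarded teacher trials are
trained. Hidden state resets to zero per trial, except in the two-step task
where it is carried across trials and gradients unroll over the current plus
the previous trial (loss masked to the current trial's frames, truncation at
the previous trial's start). Both passes are hand-written in numpy with
numba-compiled kernels; the backward pass is verified against central finite
differences, and the forward pass against an independent per-equation
transcription, in the test suite.

Initialization (not specified by the model description): uniform(−k, k) with
k = 1/√fan-in per weight matrix, zero biases — keeps the sigmoids
unsaturated at the start.

## Inverse temperature β

β is a free parameter. It is pinned behaviorally: on the trained
probabilistic-reasoning model, β controls the rate of spurious saccades and
hence the abort rate of closed-loop testing. `scripts/calibrate_beta.py`
sweeps β on a trained model; the default `DEFAULT_BETA = 7.2` puts the abort
rate in the low single-digit percent range (≈3.5%) where the analysis battery
operates. The same default is used for all tasks.

## Tasks (synthetic-data generators)

All data are synthetic; the generators double as the study conditions.

**Probabilistic reasoning (Task 1).** Ten shapes with base-10 logLR weights
{±0.9, ±0.7, ±0.5, ±0.3, ±0.1} (the printed range is ±0.9; the even spacing
is this package's choice, config-overridable). Sampling distributions are the
unique mirror-symmetric solution `p_left ∝ 10^{w/2}`, `p_right ∝ 10^{−w/2}`,
which makes the per-shape log-probability ratio equal the assigned logLR
exactly. The teacher is a DDM on the accumulated logLR with bounds
±(1.5 − 0.1·n) checked after each shape; reward iff the committed side is
the drawn correct target. Trial timing at 100 ms (the step size is given;
the frame counts are package choices, config-exposed): 3 fixation frames, 2
target frames, then epochs of 2 shape-on + 2 inter-shape frames. A saccade is
valid only when sampled at the second shape-on frame (the teacher's commit
slot); other saccades, "other location" responses, and running past 25 shapes
abort the trial. Input codec: 10 shapes + 3 targets + 1 blank + 4 actions +
2 reward = 20 units.

**Multisensory heading (Task 2).** Two 8-unit populations (visual,
vestibular) with Gaussian tuning (σ = 45°, preferred directions from −90° to
90°), Poisson spike counts at gain g = 300, responses r = 1/(1+e^{1−s}).
Training presents unimodal trials only (absent modality fixed at 0.5,
noise-free — including off-stimulus frames); the bimodal condition is a
generalization probe. The teacher/oracle is the discretized Bayesian
posterior over a 1° heading grid computed in log space; the bimodal posterior
is the normalized product of the unimodal ones. Positive headings are
"leftward" by package convention; 0° is excluded from the left/right mass
comparison, exact ties break by fair coin (or deterministically rightward
without an rng). Codec: 16 tuned + 3 targets + 1 blank + 4 actions + 2
reward = 26 units.

**Post-decision wagering (Task 3).** Ten motion units (5 per direction) with
internal activation coh/10 ± N(0, 2.5²) per 100 ms frame, logistic response;
durations uniform on {1,2,3,4,6,8} steps; coherences {0, 3.2, 6.4, 12.8,
25.6, 51.2}% with random sign. Accumulated internal evidence E drives the
teacher: direction by sign(E) when no sure target; with the sure target
(present on half of trials, shown on the delay frame after the movie) a
direction is taken only when |E| > θ(T) = 5 + 2.5·T. The sure choice pays
the same binary reward unit as a correct direction choice — reward magnitude
is not modeled, a known limitation of the binary reward channel. Codec: 10
motion + 4 targets + 1 blank + 5 actions + 2 reward = 22 units.

**Two-step task (Task 4).** Options A1/A2 lead to intermediate states B1/B2
with common-transition probability 0.8 (the source text gives only "more
likely"; 0.8 is this package's choice, config-overridable), rewards
Bernoulli 0.8/0.2 reversing every 50 trials (test variant 70). Training
choices are uniform random; trials are 4 frames (inter-trial blank, options,
transition + efference, outcome). Codec: 5 sensory + 3 actions + 2 reward =
10 units. At test the softmax is restricted to the A1/A2 outputs on the
options frame; the other frames are scripted holds.

## Analyses

**Psychometric fits.** Logistic by Newton MLE; cumulative Gaussian by direct
NLL minimization. The heading-discrimination threshold is the fitted SD; for
logistic fits the matched probit SD (1.7/slope) is reported so the two forms
are comparable. (Quasi-)separation is flagged and refit with a weak ridge.

**Subjective weights / shape order.** Ridge logistic regression of choice on
per-shape counts (or on the positional logLR regressors: epochs 1–3, summed
middle epochs 4..N−3, and the second/third-from-last; the final shape is
excluded and only trials with more than six epochs enter). The penalty is
chosen by ten-fold cross-validated log-loss; standard errors are sandwich
estimates at the penalized optimum; coefficients are reported in base-10
units so they compare directly to the assigned logLRs.

**Collapsing-bound DDM fit.** Because shape logLRs live on a 0.1 lattice,
the forward model's joint RT-by-choice distribution and mean accumulated
logLR at commit are computed exactly by dynamic programming over integer
evidence states (no simulation noise). Two parameters (initial bound,
collapse rate) are fit by normalized least squares on four curves
(RT-frequency and mean-logLR per choice; bins with fewer than 5 trials
masked), coarse grid then Nelder-Mead. "Variance captured" is the mean
per-curve R². Self-consistency: refitting data generated by the teacher
recovers (1.5, 0.1) within 10% with R² > 99%.

**Two-step battery.** Stay probabilities are exact counts by CR/CU/RR/RU
previous-trial type. The trial-history regression uses, per lag, one signed
predictor per trial type with an L1 penalty (cross-validated); significance
comes from an unpenalized refit on the surviving support. The five-factor
logistic model uses ±1 contrasts (Correct, Repeat, Outcome, Transition,
Trans×Out).

**Hybrid RL fit.** Six parameters (α₁, α₂, λ, β, perseveration p, w_mb):
model-free TD with eligibility on Q(A) and V(B); model-based values as the
transition-probability-weighted V(B); softmax with a perseveration bonus on
the previous choice. Maximum likelihood with 20 random L-BFGS-B starts.
Identifiability caveats: this task variant has no second-stage choice, so a
dead pathway leaves w on a likelihood ridge — α₂ = 0 identifies only
β(1−w), α₁ = 0 only β·w. Degenerate optima are canonicalized to w = 0 or
w = 1 by the exact reparameterization, and an AIC-style rule prefers the
pure model-free profile (w = 0) unless the full model gains more than 2
nats (one per extra effective parameter). Even away from the ridges the
likelihood can hold two well-separated optima — a conventional hybrid and a
"slow-drift" solution whose near-zero α₁ integrates reward over hundreds of
trials — that describe nearly identical stay-probability behavior, so the
fitted mixture weight is a higher-variance statistic than the stay table or
the factorial regression. Q-value
differences for decoding are the fitted mixture values replayed over the
test sequence; decoding is OLS with 10-fold cross-validated R².

**Unit analyses.** Selectivity: per aligned-step OLS of every hidden unit on
[1, ΣlogLR, |ΣlogLR|, epoch index, choice(±1, 0 before commit)], pooling
(trial, epoch) samples; a unit is selective if the effect is significant at
all four aligned steps (Bonferroni across steps, α = 0.05). Response
variability: across-trial SD of epoch-mean responses, trials with more than
five shapes, averaged over evidence-selective units, optionally
choice-aligned and split by each unit's preferred target (per-unit SDs are
averaged after the split). When/which indices come from the output rows for
fixation and the two saccades; groups use the cumulative-50% rule (top
sorted units exceeding half the same-sign mass). Lesions zero W_o columns
only. The connectivity graph takes the top 30% of off-diagonal |U_h|
entries (self-connections excluded) with edge length 1/w and capacity w;
geodesics via Dijkstra (inverse distance 0 for disconnected pairs), max
flows by networkx's exact max-flow; both are validated against brute-force
enumeration on small graphs. The shape-prediction analysis normalizes the
ten shape outputs at the frame before each shape onset, bins epochs into ten
equal-count accumulated-logLR groups, and reports KL divergences (nats,
1e-12 smoothing) of each bin's mean profile against both sampling
distributions.

## Problem sizes and reproducibility

Full-scale conditions are 7.5e5 training trials per run and 20 runs. This
package's replication scale, used by `scripts/acceptance.py`, is one run of
7.5e4 trials for the reasoning task (test: 5000 sequences of 25 shapes) and
5000 blocks × 50 trials for the two-step task (test: 100 frozen-weight
blocks) — reductions a single CPU completes in minutes. The two-step scale
is the smallest at which across-trial learning completed on every
initialization probed; below it, learning onset is seed-dependent. The
test suite uses further-reduced sizes (20k trials; 1600 blocks, just above
the scale where across-trial contingency learning reliably emerges at
η = 1e-4) and asserts the qualitative signatures: evidence integration and
collapsing-bound RT structure; the transition-by-outcome stay pattern,
model-based mixture weight above 0.5, and linear decodability of the fitted
value difference.

Every random draw flows from explicit `numpy` Generators; component seeds
are spawned from one master seed. Training is single-threaded and
bit-reproducible given the seed.

## What the synthetic conditions do not show

The generators realize the tasks' nominal statistics, not the sensory or
motor noise of real subjects: there are no lapses, no motor errors beyond
the softmax, no session nonstationarity, and reward magnitude is binary.
Passing tests demonstrate fidelity of the implementation to the model and
task definitions and the emergence of the described behavioral signatures
in the trained networks — not that the model fits any particular animal or
human dataset. Scaled-down runs train one network per task rather than 20,
so run-to-run dispersion is not estimated.
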