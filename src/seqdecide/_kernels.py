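"""Compiled inner loops for the recurrent forward and backward passes.

The trainer spends essentially all of its time here, so both passes are
numba-jitted.  ``gru_forward`` is the single source of truth for the cell
equations at training time; its agreement with the step-by-step numpy
implementation in :mod:`seqdecide.core` is enforced by the test suite, and the
backward pass is checked against central finite differences.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gru_forward", "gru_backward", "hybrid_rl_nll"]


@njit(cache=True)
def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


@njit(cache=True)
def gru_forward(W_z, W_r, W_h, U_z, U_r, U_h, b_z, b_r, b_h, W_o, X, h0):
    """Run the rectified GRU over the rows of X starting from state h0.

    Returns the stacks (H, S, Z, R, C, Y): post-rectification states, raw
    states, update gates, reset gates, tanh candidates, and outputs.  The raw
    intermediates are kept because the backward pass needs them.
    """
    T = X.shape[0]
    nh = h0.shape[0]
    no = W_o.shape[0]
    H = np.empty((T, nh))
    S = np.empty((T, nh))
    Z = np.empty((T, nh))
    R = np.empty((T, nh))
    C = np.empty((T, nh))
    Y = np.empty((T, no))
    h = h0.copy()
    for t in range(T):
        x = X[t]
        z = _sigmoid(W_z @ x + U_z @ h + b_z)
        r = _sigmoid(W_r @ x + U_r @ h + b_r)
        c = np.tanh(W_h @ x + U_h @ (r * h) + b_h)
        s = (1.0 - z) * h + z * c
        h = np.maximum(s, 0.0)
        Z[t] = z
        R[t] = r
        C[t] = c
        S[t] = s
        H[t] = h
        Y[t] = _sigmoid(W_o @ h)
    return H, S, Z, R, C, Y


@njit(cache=True)
def gru_backward(
    W_z, W_r, W_h, U_z, U_r, U_h, b_z, b_r, b_h, W_o,
    X, h0, H, S, Z, R, C, Y, loss_mask,
    gW_z, gW_r, gW_h, gU_z, gU_r, gU_h, gb_z, gb_r, gb_h, gW_o,
):
    """Backpropagate the next-event MSE loss through time.

    The output at step t is scored against X[t+1] with per-step weight
    ``loss_mask[t]`` (length T-1; a zero masks the step, which is how the
    cross-trial truncation window restricts the loss to the current trial
    while letting gradients flow into the previous one).  Gradients are
    accumulated into the ``g*`` arrays, which the caller must zero.  Returns
    the masked loss.
    """
    T = X.shape[0]
    nh = H.shape[1]
    no = Y.shape[1]
    loss = 0.0
    dh_next = np.zeros(nh)
    for t in range(T - 1, -1, -1):
        h = H[t]
        h_prev = H[t - 1] if t > 0 else h0
        dh = dh_next.copy()
        if t < T - 1 and loss_mask[t] > 0.0:
            e = Y[t] - X[t + 1]
            loss += loss_mask[t] * np.sum(e * e) / no
            da_y = (2.0 * loss_mask[t] / no) * e * Y[t] * (1.0 - Y[t])
            gW_o += np.outer(da_y, h)
            dh += W_o.T @ da_y
        ds = dh * (S[t] > 0.0)
        z = Z[t]
        r = R[t]
        c = C[t]
        dz = ds * (c - h_prev)
        da_h = ds * z * (1.0 - c * c)
        dh_prev = ds * (1.0 - z)
        x = X[t]
        gW_h += np.outer(da_h, x)
        gU_h += np.outer(da_h, r * h_prev)
        gb_h += da_h
        drh = U_h.T @ da_h
        dh_prev += drh * r
        da_r = drh * h_prev * r * (1.0 - r)
        gW_r += np.outer(da_r, x)
        gU_r += np.outer(da_r, h_prev)
        gb_r += da_r
        dh_prev += U_r.T @ da_r
        da_z = dz * z * (1.0 - z)
        gW_z += np.outer(da_z, x)
        gU_z += np.outer(da_z, h_prev)
        gb_z += da_z
        dh_prev += U_z.T @ da_z
        dh_next = dh_prev
    return loss


@njit(cache=True)
def hybrid_rl_nll(choices, outcomes, rewards, alpha1, alpha2, lam, beta, persev, w_mb, p_common):
    """Negative log-likelihood of first-stage choices under the hybrid agent.

    ``choices``/``outcomes`` are 0/1 arrays (option index, intermediate-state
    index), ``rewards`` is 0/1.  Model-free action values are updated by
    temporal differences with learning rate alpha1 and eligibility lam;
    model-based values combine intermediate-state values (learned at rate
    alpha2) with the known transition matrix.  Choice follows a softmax over
    the w_mb-weighted value mixture with a perseveration bonus.
    """
    q_mf = np.zeros(2)
    v_mf = np.zeros(2)
    v_mb = np.zeros(2)
    nll = 0.0
    prev_choice = -1
    n = choices.shape[0]
    for i in range(n):
        q_mb0 = p_common * v_mb[0] + (1.0 - p_common) * v_mb[1]
        q_mb1 = (1.0 - p_common) * v_mb[0] + p_common * v_mb[1]
        u0 = beta * (w_mb * q_mb0 + (1.0 - w_mb) * q_mf[0])
        u1 = beta * (w_mb * q_mb1 + (1.0 - w_mb) * q_mf[1])
        if prev_choice == 0:
            u0 += persev
        elif prev_choice == 1:
            u1 += persev
        m = max(u0, u1)
        logz = m + np.log(np.exp(u0 - m) + np.exp(u1 - m))
        if choices[i] == 0:
            nll -= u0 - logz
        else:
            nll -= u1 - logz
        a = choices[i]
        b = outcomes[i]
        r = rewards[i]
        d1 = v_mf[b] - q_mf[a]
        q_mf[a] += alpha1 * d1
        d2 = r - v_mf[b]
        v_mf[b] += alpha1 * d2
        q_mf[a] += lam * alpha1 * d2
        v_mb[b] += alpha2 * (r - v_mb[b])
        prev_choice = a
    return nll
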