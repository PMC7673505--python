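"""Unit-level dissection of trained networks.

Selectivity is assessed by per-time-step linear regression of each hidden
unit's activity on the accumulated evidence, its absolute value, an urgency
regressor (elapsed stimulus epochs), and the choice.  Output projections
define when/which indices that split the hidden layer into populations
controlling response timing versus response identity; these are probed by
severing output connections (virtual lesions) and by geodesic-distance and
maximum-flow statistics on the recurrent connectivity graph.  The
prediction-profile analysis compares the normalized shape-output activities
against the two sampling distributions via KL divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GRUParams
from .sequences import TrialRecord
from .tasks.probreason import LEFT, ShapeCodebook, Task1Timing

__all__ = [
    "SelectivityResult",
    "WhenWhichIndices",
    "GraphMetrics",
    "fit_unit_selectivity",
    "response_variability",
    "compute_when_which",
    "select_units_by_cumulative_index",
    "lesion_output",
    "graph_metrics",
    "shape_prediction_kl",
    "choice_selective_units_task3",
    "kl_divergence",
]

_VARIABLES = ("evidence", "abs_evidence", "urgency", "choice")


@dataclass
class SelectivityResult:
    """Per-unit regression coefficients by aligned step, and selectivity flags.

    ``coef``/``pvalues`` have shape (n_steps, 5, n_units) with coefficient
    order (intercept, evidence, |evidence|, urgency, choice).  A unit is
    flagged selective to a variable when the effect is significant at every
    aligned step of the epoch (two-tailed t-tests, Bonferroni across steps).
    """

    coef: np.ndarray
    pvalues: np.ndarray
    flags: dict
    preferred_target: np.ndarray
    n_samples: int

    def selective(self, variable: str) -> np.ndarray:
        return np.flatnonzero(self.flags[variable])


def _epoch_samples(traces, trials, codebook, timing, step_in_epoch):
    """Pool (trial, epoch) samples at one epoch-aligned step."""
    rows_h, rows_x = [], []
    for trace, t in zip(traces, trials):
        if t.choice is None or t.aborted:
            continue
        w = codebook.weights[np.asarray(t.stimuli, dtype=np.intp)]
        k = t.rt_epochs
        for e in range(1, k + 1):
            idx = timing.shape_onset(e) + step_in_epoch
            if idx >= len(trace) or idx > timing.commit_slot(k):
                continue
            cum = w[:e].sum()
            c = 0.0
            if e == k:
                c = 1.0 if t.choice == LEFT else -1.0
            rows_h.append(trace[idx])
            rows_x.append([1.0, cum, abs(cum), float(e), c])
    return np.asarray(rows_x), np.asarray(rows_h)


def fit_unit_selectivity(
    traces: list[np.ndarray],
    trials: list[TrialRecord],
    codebook: ShapeCodebook,
    timing: Task1Timing = Task1Timing(),
    alpha: float = 0.05,
) -> SelectivityResult:
    """OLS selectivity regression at every epoch-aligned time step.

    All hidden units are fit jointly (shared design matrix, one least-squares
    solve per aligned step).  Epochs after the commitment do not exist in the
    trace and are skipped; the choice regressor is +-1 only in the epoch the
    choice is made, 0 while fixation is maintained.
    """
    n_steps = timing.epoch_len
    coefs, pvals = [], []
    n_total = 0
    for s in range(n_steps):
        X, H = _epoch_samples(traces, trials, codebook, timing, s)
        if len(X) <= X.shape[1]:
            raise ValueError("too few samples for the selectivity regression")
        cond = np.linalg.cond(X.T @ X)
        if cond > 1e10:
            import warnings

            warnings.warn(f"ill-conditioned selectivity design (cond={cond:.2g})")
        n_total += len(X)
        B, res, rank, _ = np.linalg.lstsq(X, H, rcond=None)
        dof = len(X) - X.shape[1]
        resid = H - X @ B
        sigma2 = np.sum(resid**2, axis=0) / dof
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        tstat = np.divide(B, se, out=np.zeros_like(B), where=se > 0)
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        coefs.append(B)
        pvals.append(p)
    coef = np.asarray(coefs)
    pv = np.asarray(pvals)
    thr = alpha / n_steps  # Bonferroni across the aligned steps
    flags = {
        var: np.all(pv[:, j + 1, :] < thr, axis=0)
        for j, var in enumerate(_VARIABLES)
    }
    preferred = np.where(coef[:, 1, :].mean(axis=0) >= 0, LEFT, 1 - LEFT)
    return SelectivityResult(
        coef=coef, pvalues=pv, flags=flags, preferred_target=preferred, n_samples=n_total
    )


def response_variability(
    traces: list[np.ndarray],
    trials: list[TrialRecord],
    unit_ids: np.ndarray,
    timing: Task1Timing = Task1Timing(),
    alignment: str = "stimulus",
    preferred_target: np.ndarray | None = None,
    min_shapes: int = 6,
    min_trials: int = 2,
) -> dict:
    """Across-trial SD of epoch-mean unit responses, averaged over units.

    Only trials with more than five shapes enter.  Stimulus alignment indexes
    epochs from trial start; choice alignment indexes them backwards from the
    commitment and, when ``preferred_target`` is given, splits trials by
    whether each unit's preferred target was chosen.
    """
    sel = [
        (tr, t)
        for tr, t in zip(traces, trials)
        if t.choice is not None and not t.aborted and t.rt_epochs >= min_shapes
    ]
    if not sel:
        raise ValueError("no qualifying trials")
    max_e = max(t.rt_epochs for _, t in sel)

    def epoch_mean(trace, t, e):
        steps = [
            i
            for i in timing.epoch_steps(e)
            if i < len(trace) and i <= timing.commit_slot(t.rt_epochs)
        ]
        return trace[steps].mean(axis=0) if steps else None

    def sd_curve(pairs, epochs_of):
        curves = {}
        for lag_or_epoch in epochs_of:
            per_trial = []
            for trace, t in pairs:
                e = lag_or_epoch if alignment == "stimulus" else t.rt_epochs + lag_or_epoch
                if e < 1 or e > t.rt_epochs:
                    continue
                m = epoch_mean(trace, t, e)
                if m is not None:
                    per_trial.append(m)
            if len(per_trial) >= min_trials:
                sd = np.std(np.asarray(per_trial)[:, unit_ids], axis=0, ddof=1)
                curves[lag_or_epoch] = float(sd.mean())
        return curves

    if alignment == "stimulus":
        return {"all": sd_curve(sel, range(1, max_e + 1))}
    if alignment != "choice":
        raise ValueError("alignment must be 'stimulus' or 'choice'")
    lags = range(-max_e + 1, 1)
    if preferred_target is None:
        return {"all": sd_curve(sel, lags)}
    out = {"preferred": {}, "nonpreferred": {}}
    # split per unit, then average the per-unit SD curves across units
    for key, want_pref in (("preferred", True), ("nonpreferred", False)):
        acc: dict[int, list[float]] = {}
        for u in unit_ids:
            pairs = [
                (tr, t)
                for tr, t in sel
                if (t.choice == preferred_target[u]) == want_pref
            ]
            for lag in lags:
                per_trial = []
                for trace, t in pairs:
                    e = t.rt_epochs + lag
                    if e < 1:
                        continue
                    m = epoch_mean(trace, t, e)
                    if m is not None:
                        per_trial.append(m[u])
                if len(per_trial) >= min_trials:
                    acc.setdefault(lag, []).append(float(np.std(per_trial, ddof=1)))
        out[key] = {lag: float(np.mean(v)) for lag, v in acc.items()}
    return out


@dataclass
class WhenWhichIndices:
    """Per-unit output-projection indices and the derived unit groups.

    ``i_when = (w_LT + w_RT)/2 - w_FP`` promotes responding over fixating;
    ``i_which = w_LT - w_RT`` biases the response leftward.  Groups hold the
    top units whose sorted indices first exceed half the total same-sign
    mass (the cumulative-50% rule).
    """

    i_when: np.ndarray
    i_which: np.ndarray
    groups: dict = field(default_factory=dict)

    def label(self, unit: int) -> str:
        for name, ids in self.groups.items():
            if unit in ids:
                return name
        return "none"


def select_units_by_cumulative_index(values: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Units of positive ``values`` whose sorted cumulative sum first exceeds
    ``frac`` of the total positive mass (pass ``-values`` for the negative group)."""
    pos = np.flatnonzero(values > 0)
    if pos.size == 0:
        return pos
    order = pos[np.argsort(values[pos])[::-1]]
    cum = np.cumsum(values[order])
    m = int(np.searchsorted(cum, frac * cum[-1], side="right")) + 1
    return np.sort(order[:m])


def compute_when_which(
    params: GRUParams, fix_row: int, left_row: int, right_row: int, frac: float = 0.5
) -> WhenWhichIndices:
    """When/which indices from the output rows for fixation and the two saccades."""
    w_fp = params.W_o[fix_row]
    w_lt = params.W_o[left_row]
    w_rt = params.W_o[right_row]
    i_when = (w_lt + w_rt) / 2.0 - w_fp
    i_which = w_lt - w_rt
    groups = {
        "+when": select_units_by_cumulative_index(i_when, frac),
        "-when": select_units_by_cumulative_index(-i_when, frac),
        "+which": select_units_by_cumulative_index(i_which, frac),
        "-which": select_units_by_cumulative_index(-i_which, frac),
    }
    return WhenWhichIndices(i_when=i_when, i_which=i_which, groups=groups)


def lesion_output(params: GRUParams, unit_set) -> GRUParams:
    """Sever the output connections of a unit set (W_o columns zeroed).

    The hidden layer itself -- input and recurrent weights -- is untouched,
    so the lesioned units still participate in the dynamics; they just stop
    talking to the output layer.
    """
    unit_set = np.asarray(list(unit_set), dtype=np.intp)
    out = params.copy()
    if unit_set.size == 0:
        import warnings

        warnings.warn("empty lesion set: returning an unmodified copy")
        return out
    if unit_set.min() < 0 or unit_set.max() >= params.n_hidden:
        raise ValueError("lesion set contains invalid unit ids")
    out.W_o[:, unit_set] = 0.0
    return out


@dataclass
class GraphMetrics:
    """Connectivity-graph statistics on the thresholded recurrent weights."""

    inverse_distance: np.ndarray
    max_flow: np.ndarray | None
    edges: list
    keep_fraction: float


def graph_metrics(
    params: GRUParams, keep_fraction: float = 0.3, flow_pairs=None
) -> GraphMetrics:
    """Geodesic distances and maximum flows on the |U_h| graph.

    Edges are the top ``keep_fraction`` of off-diagonal |U_h| entries
    (U_h[i, j] is the connection j -> i); each edge has length 1/|w| and
    capacity |w|.  Geodesic distance is the minimum summed inverse weight
    (Dijkstra); disconnected pairs get inverse distance 0.  Max flows are
    computed for ``flow_pairs`` (all ordered pairs if None -- quadratic, so
    restrict the pairs on large graphs).
    """
    import networkx as nx

    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    W = np.abs(params.U_h.copy())
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    offdiag = W[~np.eye(n, dtype=bool)]
    k = max(1, int(round(keep_fraction * offdiag.size)))
    thr = np.sort(offdiag)[-k]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    edges = []
    for i, j in zip(*np.nonzero(W >= thr)):
        w = W[i, j]
        G.add_edge(int(j), int(i), length=1.0 / w, capacity=w)
        edges.append((int(j), int(i), float(w)))
    inv = np.zeros((n, n))
    for src, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for dst, d in dists.items():
            if src != dst and d > 0:
                inv[src, dst] = 1.0 / d
    flows = None
    if flow_pairs is None:
        flow_pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    if flow_pairs:
        flows = np.full((n, n), np.nan)
        for u, v in flow_pairs:
            flows[u, v] = nx.maximum_flow_value(G, u, v, capacity="capacity")
    return GraphMetrics(inverse_distance=inv, max_flow=flows, edges=edges, keep_fraction=keep_fraction)


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> float:
    """KL(p || q) in nats with epsilon smoothing and renormalization."""
    p = np.clip(np.asarray(p, dtype=float), eps, None)
    q = np.clip(np.asarray(q, dtype=float), eps, None)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def shape_prediction_kl(
    output_traces: list[np.ndarray],
    trials: list[TrialRecord],
    codebook: ShapeCodebook,
    timing: Task1Timing = Task1Timing(),
    n_bins: int = 10,
) -> dict:
    """Compare the shape-output profile before each shape to the codebook.

    Snapshots are taken at the step immediately before each shape onset; the
    ten shape-output activities are normalized to a distribution, epochs are
    grouped into ``n_bins`` equal-count bins of the accumulated logLR, and
    the mean profile of each bin is scored by KL divergence against the two
    sampling distributions.
    """
    llrs, profiles = [], []
    for trace, t in zip(output_traces, trials):
        if t.choice is None or t.aborted:
            continue
        w = codebook.weights[np.asarray(t.stimuli, dtype=np.intp)]
        for e in range(1, t.rt_epochs + 1):
            idx = timing.shape_onset(e) - 1
            if idx < 0 or idx >= len(trace):
                continue
            act = trace[idx][:10]
            s = act.sum()
            if s <= 0:
                continue
            llrs.append(w[: e - 1].sum())
            profiles.append(act / s)
    llrs = np.asarray(llrs)
    profiles = np.asarray(profiles)
    order = np.argsort(llrs, kind="stable")
    bins = np.array_split(order, n_bins)
    out = {"bin_mean_llr": [], "kl_left": [], "kl_right": [], "profiles": []}
    for b in bins:
        if len(b) == 0:
            continue
        prof = profiles[b].mean(axis=0)
        prof = prof / prof.sum()
        out["bin_mean_llr"].append(float(llrs[b].mean()))
        out["kl_left"].append(kl_divergence(prof, codebook.p_left))
        out["kl_right"].append(kl_divergence(prof, codebook.p_right))
        out["profiles"].append(prof)
    return {k: np.asarray(v) for k, v in out.items()}


def choice_selective_units_task3(
    traces: list[np.ndarray],
    trials: list[TrialRecord],
    alpha: float = 0.05,
) -> dict:
    """Direction-selective hidden units in the wagering task.

    Uses the pre-choice snapshot of trials without the sure target; units
    with a significant left/right response difference (two-tailed t-test,
    Bonferroni across units) are labelled by the side with the larger mean.
    """
    from .tasks.wagering import LEFT as T3_LEFT
    from .tasks.wagering import RIGHT as T3_RIGHT
    from .tasks.wagering import prechoice_index

    snaps = {T3_LEFT: [], T3_RIGHT: []}
    for trace, t in zip(traces, trials):
        if t.aborted or t.info.get("sure_available") or t.choice not in snaps:
            continue
        idx = prechoice_index(t.info["duration"])
        if idx < len(trace):
            snaps[t.choice].append(trace[idx])
    L = np.asarray(snaps[T3_LEFT])
    R = np.asarray(snaps[T3_RIGHT])
    if len(L) < 2 or len(R) < 2:
        raise ValueError("need at least two trials per choice")
    tstat, p = stats.ttest_ind(L, R, axis=0)
    n_units = L.shape[1]
    sig = p < alpha / n_units
    left_units = np.flatnonzero(sig & (L.mean(axis=0) > R.mean(axis=0)))
    right_units = np.flatnonzero(sig & (L.mean(axis=0) < R.mean(axis=0)))
    return {
        "left_units": left_units,
        "right_units": right_units,
        "pvalues": p,
        "n_selective": int(sig.sum()),
    }
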