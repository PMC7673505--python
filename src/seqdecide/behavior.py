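"""Choice-level analyses of teacher and network behavior.

Covers the psychometric and evidence-weight regressions for the
probabilistic-reasoning task, the collapsing-bound DDM fit to reaction times,
cumulative-Gaussian thresholds for heading discrimination, and the two-step
battery: stay probabilities, L1-penalized trial-history regression, the
five-factor logistic model, and the six-parameter hybrid model-free /
model-based reinforcement-learning fit with Q-value decoding from hidden
activity.

Penalized logistic fits are done by Newton iteration on the ridge-penalized
cross-entropy with the penalty chosen by ten-fold cross-validation; standard
errors come from the sandwich covariance at the penalized optimum.
Regressions that mirror base-10 evidence models report coefficients in
base-10 units (natural-log coefficients divided by ln 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._kernels import hybrid_rl_nll
from .sequences import TrialRecord
from .tasks.probreason import LEFT, DDMPolicyConfig, ShapeCodebook
from .tasks.twostep import TwoStepConfig, TwoStepWorld, encode_task4_trial

__all__ = [
    "RegressionResult",
    "PsychometricFit",
    "DDMFit",
    "StayTable",
    "HybridRLFit",
    "fit_psychometric",
    "fit_subjective_weights",
    "fit_shape_order",
    "fit_ddm_collapsing",
    "ddm_forward_curves",
    "stay_probability_table",
    "fit_history_lasso",
    "fit_five_factor",
    "simulate_hybrid_rl",
    "fit_hybrid_rl",
    "hybrid_q_values",
    "decode_value_difference",
    "compare_output_fits",
]

LN10 = np.log(10.0)


@dataclass
class RegressionResult:
    """Coefficient table of a (possibly penalized) regression fit."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    alpha: float = 0.0
    cv_folds: int = 0
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"name": self.names, "coef": self.coef, "se": self.se, "p": self.pvalues}
        )


# ---------------------------------------------------------------- logistic core


def _logistic_newton(X, y, alpha, penalize_intercept=False, max_iter=100, tol=1e-10):
    """Ridge-penalized logistic regression (natural-log scale) by Newton steps.

    Returns (beta, cov) where cov is the sandwich covariance
    H^-1 (X'WX) H^-1 with H the penalized Hessian.  The intercept (column 0)
    is unpenalized unless requested.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, 2.0 * alpha)
    if not penalize_intercept:
        pen[0] = 0.0
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (mu - y) + pen * beta
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(p)
            step = np.linalg.solve(H, grad)
        beta_new = beta - step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = np.clip(beta_new, -60.0, 60.0)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    XtWX = (X.T * w) @ X
    H = XtWX + np.diag(pen)
    Hinv = np.linalg.pinv(H)
    cov = Hinv @ XtWX @ Hinv
    return beta, cov


def _cv_cross_entropy(X, y, alpha, folds, rng):
    idx = rng.permutation(len(y))
    splits = np.array_split(idx, folds)
    total = 0.0
    for k in range(folds):
        test = splits[k]
        train = np.concatenate([splits[j] for j in range(folds) if j != k])
        beta, _ = _logistic_newton(X[train], y[train], alpha)
        eta = np.clip(X[test] @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        total -= np.sum(y[test] * np.log(mu) + (1 - y[test]) * np.log(1 - mu))
    return total


def ridge_logistic_cv(
    X, y, alphas=None, folds: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit logistic regression with an L2 penalty chosen by k-fold CV.

    ``X`` should NOT contain an intercept column; one is prepended and left
    unpenalized.  Returns (beta, cov, alpha) on the natural-log scale with
    the intercept first.
    """
    if alphas is None:
        alphas = np.logspace(-3, 3, 9)
    Xd = np.column_stack([np.ones(len(y)), X])
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    scores = [_cv_cross_entropy(Xd, y, a, folds, np.random.default_rng(seed)) for a in alphas]
    alpha = float(alphas[int(np.argmin(scores))])
    beta, cov = _logistic_newton(Xd, y, alpha)
    return beta, cov, alpha


def _result_from_fit(names, beta, cov, alpha, folds, base10=False) -> RegressionResult:
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    scale = LN10 if base10 else 1.0
    return RegressionResult(
        names=list(names), coef=beta / scale, se=se / scale, pvalues=p, alpha=alpha, cv_folds=folds
    )


# ---------------------------------------------------------------- psychometrics


@dataclass
class PsychometricFit:
    form: str
    params: dict
    threshold: float
    separation_flag: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "logistic":
            return 1.0 / (1.0 + np.exp(-(self.params["bias"] + self.params["slope"] * x)))
        return stats.norm.cdf((x - self.params["mu"]) / self.params["sigma"])


def fit_psychometric(
    evidence: np.ndarray, choices: np.ndarray, form: str = "logistic"
) -> PsychometricFit:
    """MLE psychometric fit of P(choose left) against signed evidence.

    ``choices`` codes left as 1.  For the cumulative-Gaussian form the
    performance threshold is the fitted SD; for the logistic form the SD of
    the matched probit (1.7/slope, the standard logit-probit scaling) is
    reported so thresholds are comparable across forms.
    """
    x = np.asarray(evidence, dtype=float)
    y = np.asarray(choices, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct evidence levels")
    if form == "logistic":
        beta, cov = _logistic_newton(np.column_stack([np.ones_like(x), x]), y, 0.0)
        flag = bool(np.max(np.abs(beta)) >= 30.0)
        if flag:  # (quasi-)separated: refit with a weak ridge
            beta, cov = _logistic_newton(np.column_stack([np.ones_like(x), x]), y, 1e-2)
        return PsychometricFit(
            form="logistic",
            params={"bias": beta[0], "slope": beta[1], "cov": cov},
            threshold=1.7 / abs(beta[1]) if beta[1] != 0 else np.inf,
            separation_flag=flag,
        )
    if form != "cumulative_gaussian":
        raise ValueError(f"unknown form {form!r}")

    def nll(theta):
        mu, log_sigma = theta
        p = stats.norm.cdf((x - mu) / np.exp(log_sigma))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    x_scale = max(np.std(x), 1e-3)
    best = None
    for s0 in (x_scale / 2, x_scale, 2 * x_scale):
        res = optimize.minimize(nll, [np.mean(x * 0.0), np.log(s0)], method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    flag = sigma < 1e-3 * x_scale
    return PsychometricFit(
        form="cumulative_gaussian",
        params={"mu": mu, "sigma": sigma},
        threshold=sigma,
        separation_flag=flag,
    )


# -------------------------------------------------- shape-weight regressions


def fit_subjective_weights(
    trials: list[TrialRecord], folds: int = 10, seed: int = 0
) -> RegressionResult:
    """Subjective weight of evidence per shape, by ridge logistic regression.

    The model is ``P(left) = 1 / (1 + 10^-Q)`` with ``Q`` linear in the
    per-trial shape counts, so coefficients are directly comparable to the
    assigned base-10 logLRs.  Ridge shrinkage (CV-chosen) stabilizes the
    correlated count regressors.
    """
    done = [t for t in trials if t.choice is not None and not t.aborted]
    X = np.zeros((len(done), 10))
    y = np.zeros(len(done))
    for i, t in enumerate(done):
        counts = np.bincount(np.asarray(t.stimuli, dtype=np.intp), minlength=10)
        X[i] = counts
        y[i] = 1.0 if t.choice == LEFT else 0.0
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < 11:
        import warnings

        warnings.warn("shape-count design is rank deficient; ridge shrinkage will dominate")
    beta, cov, alpha = ridge_logistic_cv(X, y, folds=folds, seed=seed)
    names = ["bias"] + [f"shape_{m}" for m in range(10)]
    return _result_from_fit(names, beta, cov, alpha, folds, base10=True)


def fit_shape_order(
    trials: list[TrialRecord],
    codebook: ShapeCodebook,
    folds: int = 10,
    seed: int = 0,
    min_epochs: int = 7,
) -> RegressionResult:
    """Leverage of shape position on choice (trials with more than six epochs).

    Regressors: logLR of the first three epochs, the summed logLR of the
    middle epochs, and the second- and third-from-last epochs.  The final
    shape is excluded -- under a bound-crossing policy it is almost always
    consistent with the choice, which would swamp the comparison.
    """
    rows, ys = [], []
    for t in trials:
        if t.choice is None or t.aborted or t.rt_epochs is None or t.rt_epochs < min_epochs:
            continue
        w = codebook.weights[np.asarray(t.stimuli, dtype=np.intp)]
        N = len(w)
        middle = w[3 : N - 3].sum()  # epochs 4 .. N-3 (1-based)
        rows.append([w[0], w[1], w[2], middle, w[N - 2], w[N - 3]])
        ys.append(1.0 if t.choice == LEFT else 0.0)
    if len(rows) < 50:
        raise ValueError(f"only {len(rows)} qualifying trials; need more long trials")
    X = np.asarray(rows)
    y = np.asarray(ys)
    beta, cov, alpha = ridge_logistic_cv(X, y, folds=folds, seed=seed)
    names = ["bias", "epoch_1", "epoch_2", "epoch_3", "middle", "last_minus_1", "last_minus_2"]
    return _result_from_fit(names, beta, cov, alpha, folds, base10=True)


# ------------------------------------------------------------------- DDM fit


def ddm_forward_curves(
    codebook: ShapeCodebook, bound0: float, collapse: float, max_shapes: int = 25
):
    """Exact RT/choice/evidence predictions of the collapsing-bound DDM.

    Shape logLRs lie on a 0.1 lattice, so the accumulated total is tracked
    exactly by dynamic programming over integer states (units of 0.1).
    Returns ``p_rt`` of shape (max_shapes, 2) -- the joint probability of
    committing at epoch k to choice c under a 50/50 mixture of correct
    targets -- and ``mean_llr`` the mean accumulated logLR at commit, NaN
    where the commit probability is zero.
    """
    w10 = np.rint(codebook.weights * 10).astype(int)
    span = int(np.max(np.abs(w10))) * max_shapes
    n_states = 2 * span + 1
    dist = np.zeros(n_states)
    dist[span] = 1.0  # cum = 0
    p_rt = np.zeros((max_shapes, 2))
    sum_llr = np.zeros((max_shapes, 2))
    # conditioned on correct = left; mirror afterwards
    p_shape = codebook.p_left
    cums = (np.arange(n_states) - span) / 10.0
    for n in range(1, max_shapes + 1):
        new = np.zeros(n_states)
        for i, wi in enumerate(w10):
            if wi >= 0:
                new[wi:] += p_shape[i] * dist[: n_states - wi] if wi else p_shape[i] * dist
            else:
                new[:wi] += p_shape[i] * dist[-wi:]
        b = bound0 - collapse * n
        if b > 0:
            up = cums >= b - 1e-9
            down = cums <= -b + 1e-9
        else:
            up = cums >= 0.0
            down = cums < 0.0
            both = cums == 0.0
            # a fully collapsed bound splits an exactly-zero total evenly
            p_rt[n - 1, 0] += 0.5 * new[both].sum()
            p_rt[n - 1, 1] += 0.5 * new[both].sum()
            up &= ~both
            down &= ~both
        p_rt[n - 1, 0] += new[up].sum()
        p_rt[n - 1, 1] += new[down].sum()
        sum_llr[n - 1, 0] = np.sum(new[up] * cums[up])
        sum_llr[n - 1, 1] = np.sum(new[down] * cums[down])
        new[up | down] = 0.0
        dist = new
    # mixture over the two (symmetric) correct targets
    p_mix = 0.5 * (p_rt + p_rt[:, ::-1])
    sum_mix = 0.5 * (sum_llr - sum_llr[:, ::-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_llr = np.where(p_mix > 0, sum_mix / np.maximum(p_mix, 1e-300), np.nan)
    return p_mix, mean_llr


@dataclass
class DDMFit:
    bound0: float
    collapse: float
    variance_captured: float
    per_curve_r2: dict
    success: bool = True


def _ddm_data_curves(trials, max_shapes):
    done = [t for t in trials if t.choice is not None and not t.aborted]
    n = len(done)
    freq = np.zeros((max_shapes, 2))
    sums = np.zeros((max_shapes, 2))
    for t in done:
        k = min(t.rt_epochs, max_shapes) - 1
        c = 0 if t.choice == LEFT else 1
        freq[k, c] += 1
        sums[k, c] += t.info["total_logLR"]
    counts = freq.copy()
    freq /= max(n, 1)
    with np.errstate(invalid="ignore"):
        mean_llr = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return freq, mean_llr, counts


def fit_ddm_collapsing(
    trials: list[TrialRecord],
    codebook: ShapeCodebook,
    max_shapes: int = 25,
    min_bin_count: int = 5,
) -> DDMFit:
    """Fit the two-parameter collapsing-bound DDM to RT and evidence curves.

    The forward model's joint RT-by-choice distribution and mean total logLR
    at commit are matched to the observed curves (bins with fewer than
    ``min_bin_count`` trials are masked).  The objective is the summed
    per-curve normalized squared error; a coarse grid seeds a Nelder-Mead
    refinement.  ``variance_captured`` is the mean per-curve R^2 -- RT
    frequency and mean-logLR curves for each choice weighted equally.
    """
    freq_d, mllr_d, counts = _ddm_data_curves(trials, max_shapes)
    mask = counts >= min_bin_count

    def curves_sse(theta, return_r2=False):
        b0, c = theta
        if not (0.05 <= b0 <= 5.0 and 0.0 <= c <= 0.5):
            return 1e6
        freq_m, mllr_m = ddm_forward_curves(codebook, b0, c, max_shapes)
        total = 0.0
        r2 = {}
        for ci, cname in enumerate(("left", "right")):
            m = mask[:, ci]
            for dat, mod, what in ((freq_d, freq_m, "rt_freq"), (mllr_d, mllr_m, "mean_llr")):
                d = dat[m, ci]
                mo = np.nan_to_num(mod[m, ci], nan=0.0)
                sst = np.sum((d - d.mean()) ** 2)
                ssr = np.sum((d - mo) ** 2)
                frac = ssr / sst if sst > 0 else (0.0 if ssr < 1e-12 else 1.0)
                total += frac
                r2[f"{what}_{cname}"] = 1.0 - frac
        if return_r2:
            return total, r2
        return total

    grid = [
        (b0, c)
        for b0 in np.arange(0.6, 2.6, 0.2)
        for c in np.arange(0.0, 0.26, 0.05)
    ]
    best = min(grid, key=curves_sse)
    res = optimize.minimize(curves_sse, best, method="Nelder-Mead", options={"xatol": 1e-3, "fatol": 1e-6})
    theta = res.x if res.fun <= curves_sse(best) else np.asarray(best)
    total, r2 = curves_sse(theta, return_r2=True)
    return DDMFit(
        bound0=float(theta[0]),
        collapse=float(theta[1]),
        variance_captured=float(np.mean(list(r2.values()))),
        per_curve_r2=r2,
        success=bool(res.success or res.fun <= curves_sse(best)),
    )


# ------------------------------------------------------------------ two-step


@dataclass
class StayTable:
    """P(repeat previous first-stage choice) by previous-trial type."""

    p_stay: dict
    se: dict
    counts: dict
    missing: list[str] = field(default_factory=list)


def _trial_type(t: TrialRecord) -> str:
    return ("C" if t.info["common"] else "R") + ("R" if t.rewarded else "U")


def stay_probability_table(trials: list[TrialRecord]) -> StayTable:
    """Exact stay counts/totals by CR / CU / RR / RU previous-trial type."""
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    stays = {k: [0, 0] for k in ("CR", "CU", "RR", "RU")}
    for prev, cur in zip(trials[:-1], trials[1:]):
        k = _trial_type(prev)
        stays[k][1] += 1
        if cur.choice == prev.choice:
            stays[k][0] += 1
    p, se, counts, missing = {}, {}, {}, []
    for k, (s, n) in stays.items():
        counts[k] = n
        if n == 0:
            missing.append(k)
            p[k] = np.nan
            se[k] = np.nan
        else:
            p[k] = s / n
            se[k] = np.sqrt(p[k] * (1 - p[k]) / n)
    return StayTable(p_stay=p, se=se, counts=counts, missing=missing)


def _choice_sign(c: int) -> float:
    return 1.0 if c == 0 else -1.0


def fit_history_lasso(
    trials: list[TrialRecord], n_back: int = 5, seed: int = 0, folds: int = 10
) -> RegressionResult:
    """Trial-history influence by L1-penalized logistic regression.

    For each lag j and previous-trial type (CR/CU/RR/RU) the predictor is the
    signed lag-j choice if that trial was of the type, else 0; the target is
    the current choice.  The penalty is chosen by cross-validated
    log-loss; significance is assessed by an unpenalized refit restricted to
    the surviving predictors (zeroed coefficients get SE = 0, p = 1).
    """
    from sklearn.linear_model import LogisticRegressionCV

    types = ("CR", "CU", "RR", "RU")
    rows, ys = [], []
    for i in range(n_back, len(trials)):
        row = []
        for j in range(1, n_back + 1):
            prev = trials[i - j]
            k = _trial_type(prev)
            row.extend(_choice_sign(prev.choice) if k == tt else 0.0 for tt in types)
        rows.append(row)
        ys.append(1 if trials[i].choice == 0 else 0)
    X = np.asarray(rows)
    y = np.asarray(ys)
    names = [f"{tt}_lag{j}" for j in range(1, n_back + 1) for tt in types]
    clf = LogisticRegressionCV(
        penalty="l1", solver="liblinear", Cs=10, cv=folds, random_state=seed, max_iter=1000
    ).fit(X, y)
    coef = clf.coef_.ravel()
    support = np.abs(coef) > 1e-8
    se = np.zeros_like(coef)
    pv = np.ones_like(coef)
    if support.any():
        Xs = np.column_stack([np.ones(len(y)), X[:, support]])
        b, cov = _logistic_newton(Xs, y.astype(float), 0.0)
        ses = np.sqrt(np.maximum(np.diag(cov)[1:], 0))
        zs = np.divide(b[1:], ses, out=np.zeros_like(ses), where=ses > 0)
        se[support] = ses
        pv[support] = 2 * stats.norm.sf(np.abs(zs))
    return RegressionResult(
        names=["bias"] + names,
        coef=np.concatenate([[clf.intercept_[0]], coef]),
        se=np.concatenate([[np.nan], se]),
        pvalues=np.concatenate([[np.nan], pv]),
        alpha=float(1.0 / clf.C_[0]),
        cv_folds=folds,
    )


def fit_five_factor(trials: list[TrialRecord]) -> RegressionResult:
    """Five-factor logistic model of the current first-stage choice.

    Factors (+-1 contrasts, A1 positive): Correct (currently better option),
    Repeat (previous choice), Outcome (repeat-if-rewarded), Transition
    (repeat-if-common), and the Trans x Out interaction (repeat after CR/RU,
    switch after CU/RR) -- the model-based signature.
    """
    rows, ys = [], []
    for prev, cur in zip(trials[:-1], trials[1:]):
        s = _choice_sign(prev.choice)
        out = 1.0 if prev.rewarded else -1.0
        trans = 1.0 if prev.info["common"] else -1.0
        correct = 1.0 if cur.info.get("good_b", cur.correct_target) == 0 else -1.0
        rows.append([correct, s, s * out, s * trans, s * out * trans])
        ys.append(1.0 if cur.choice == 0 else 0.0)
    X = np.asarray(rows)
    y = np.asarray(ys)
    beta, cov = _logistic_newton(np.column_stack([np.ones(len(y)), X]), y, 1e-6)
    names = ["bias", "Correct", "Repeat", "Outcome", "Transition", "TransxOut"]
    return _result_from_fit(names, beta, cov, 1e-6, 0)


# --------------------------------------------------------------- hybrid RL


@dataclass
class HybridRLFit:
    """Six-parameter mixed model-free/model-based agent."""

    alpha1: float
    alpha2: float
    lam: float
    beta: float
    persev: float
    w_mb: float
    nll: float = np.nan
    converged: bool = True

    @property
    def w_mf(self) -> float:
        return 1.0 - self.w_mb

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.lam, self.beta, self.persev, self.w_mb])


def _hybrid_values(fit: HybridRLFit, cfg: TwoStepConfig, choices, outcomes, rewards):
    """Replay the hybrid agent over a trial sequence; per-trial pre-choice values."""
    q_mf = np.zeros(2)
    v_mf = np.zeros(2)
    v_mb = np.zeros(2)
    pc = cfg.p_common
    n = len(choices)
    values = np.zeros((n, 2))
    for i in range(n):
        q_mb = np.array(
            [pc * v_mb[0] + (1 - pc) * v_mb[1], (1 - pc) * v_mb[0] + pc * v_mb[1]]
        )
        values[i] = fit.w_mb * q_mb + (1 - fit.w_mb) * q_mf
        a, b, r = choices[i], outcomes[i], rewards[i]
        d1 = v_mf[b] - q_mf[a]
        q_mf[a] += fit.alpha1 * d1
        d2 = r - v_mf[b]
        v_mf[b] += fit.alpha1 * d2
        q_mf[a] += fit.lam * fit.alpha1 * d2
        v_mb[b] += fit.alpha2 * (r - v_mb[b])
    return values


def simulate_hybrid_rl(
    fit: HybridRLFit,
    cfg: TwoStepConfig,
    n_trials: int,
    rng: np.random.Generator,
    block_len: int | None = None,
) -> list[TrialRecord]:
    """Generative counterpart of the fitted model, run through the task blocks."""
    world = TwoStepWorld(cfg, block_len)
    q_mf = np.zeros(2)
    v_mf = np.zeros(2)
    v_mb = np.zeros(2)
    pc = cfg.p_common
    prev_choice = -1
    out = []
    for _ in range(n_trials):
        q_mb = np.array(
            [pc * v_mb[0] + (1 - pc) * v_mb[1], (1 - pc) * v_mb[0] + pc * v_mb[1]]
        )
        u = fit.beta * (fit.w_mb * q_mb + (1 - fit.w_mb) * q_mf)
        if prev_choice >= 0:
            u[prev_choice] += fit.persev
        p1 = 1.0 / (1.0 + np.exp(u[1] - u[0]))
        choice = 0 if rng.random() < p1 else 1
        idx = world.trial_index
        good_b = world.good_b
        b, rewarded = world.transition(choice, rng)
        r = 1.0 if rewarded else 0.0
        d1 = v_mf[b] - q_mf[choice]
        q_mf[choice] += fit.alpha1 * d1
        d2 = r - v_mf[b]
        v_mf[b] += fit.alpha1 * d2
        q_mf[choice] += fit.lam * fit.alpha1 * d2
        v_mb[b] += fit.alpha2 * (r - v_mb[b])
        prev_choice = choice
        out.append(
            TrialRecord(
                events=encode_task4_trial(choice, b, rewarded),
                correct_target=good_b,
                stimuli=None,
                choice=choice,
                rt_epochs=1,
                rewarded=rewarded,
                info={"b_state": b, "common": b == choice, "trial_index": idx, "good_b": good_b},
            )
        )
    return out


def _extract_task4_arrays(trials):
    choices = np.array([t.choice for t in trials], dtype=np.int64)
    outcomes = np.array([t.info["b_state"] for t in trials], dtype=np.int64)
    rewards = np.array([1.0 if t.rewarded else 0.0 for t in trials])
    return choices, outcomes, rewards


_BOUNDS = [(0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 30.0), (-5.0, 5.0), (0.0, 1.0)]


def fit_hybrid_rl(
    trials: list[TrialRecord],
    cfg: TwoStepConfig = TwoStepConfig(),
    n_starts: int = 20,
    seed: int = 0,
) -> HybridRLFit:
    """Maximum-likelihood fit of the six hybrid-agent parameters.

    The likelihood surface is multimodal, so L-BFGS-B runs from ``n_starts``
    random interior points; the best optimum is returned with its NLL.
    A fit is flagged non-converged if no start terminates successfully.

    Identifiability: with no second-stage choice, a dead pathway leaves the
    mixture weight on a likelihood ridge.  If the optimum has ``alpha2 ~ 0``
    (model-based values never move) only ``beta * (1 - w)`` is identified,
    and if ``alpha1 ~ 0`` (model-free values never move) only ``beta * w``
    is.  Such optima are canonicalized -- an exact reparameterization -- to
    ``w = 0`` or ``w = 1`` with beta rescaled accordingly.  On top of that,
    an AIC-style parsimony rule prefers the pure model-free profile
    (``w = 0``, idling both model-based parameters) unless the full model
    gains more than 2 nats of log-likelihood, one per extra effective
    parameter.
    """
    choices, outcomes, rewards = _extract_task4_arrays(trials)

    def nll(theta):
        return hybrid_rl_nll(choices, outcomes, rewards, *theta, cfg.p_common)

    rng = np.random.default_rng(seed)
    best, best_ok = None, False
    for k in range(n_starts):
        x0 = np.array(
            [
                rng.uniform(0.05, 0.95),
                rng.uniform(0.05, 0.95),
                rng.uniform(0.05, 0.95),
                rng.uniform(0.5, 10.0),
                rng.uniform(-1.0, 1.0),
                rng.uniform(0.05, 0.95),
            ]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
            best_ok = bool(res.success)
    theta = best.x.copy()
    a1, a2, lam, beta_t, pers, w = theta
    eps = 1e-2
    if a2 <= eps and w < 1.0:
        theta = np.array([a1, 0.0, lam, beta_t * (1.0 - w), pers, 0.0])
    elif a1 <= eps and w > 0.0:
        theta = np.array([0.0, a2, 0.0, beta_t * w, pers, 1.0])
    # accept the canonical form if it is likelihood-equivalent (the tiny
    # residual learning rate it zeroes was fitting essentially nothing)
    if nll(theta) <= best.fun + 0.5:
        best.x, best.fun = theta, float(nll(theta))
    else:
        theta = best.x.copy()
    mf_bounds = _BOUNDS[:5] + [(0.0, 0.0)]
    mf_best = None
    for k in range(max(3, n_starts // 4)):
        x0 = np.concatenate([theta[:5], [0.0]]) if k == 0 else np.array(
            [rng.uniform(0.05, 0.95), 0.5, rng.uniform(0.05, 0.95), rng.uniform(0.5, 10.0), 0.0, 0.0]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=mf_bounds)
        if mf_best is None or res.fun < mf_best.fun:
            mf_best = res
    if mf_best.fun <= best.fun + 2.0:
        best, best_ok = mf_best, best_ok or bool(mf_best.success)
    return HybridRLFit(*best.x, nll=float(best.fun), converged=best_ok)


def hybrid_q_values(
    trials: list[TrialRecord], fit: HybridRLFit, cfg: TwoStepConfig = TwoStepConfig()
) -> np.ndarray:
    """Per-trial fitted value difference v(A1) - v(A2) before each choice."""
    choices, outcomes, rewards = _extract_task4_arrays(trials)
    values = _hybrid_values(fit, cfg, choices, outcomes, rewards)
    return values[:, 0] - values[:, 1]


# ------------------------------------------------------------ value decoding


def decode_value_difference(
    hidden: np.ndarray, q_diff: np.ndarray, folds: int = 10, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Linearly decode the fitted Q-value difference from hidden activity.

    OLS on the full data provides the weights; the reported explained
    variance is cross-validated R^2 x 100.  A singular design falls back to a
    small ridge.
    """
    H = np.column_stack([np.ones(len(q_diff)), np.asarray(hidden)])
    q = np.asarray(q_diff, dtype=float)

    def solve(A, b):
        try:
            w = np.linalg.lstsq(A, b, rcond=None)[0]
            if not np.all(np.isfinite(w)):
                raise np.linalg.LinAlgError
            return w
        except np.linalg.LinAlgError:
            return np.linalg.solve(A.T @ A + 1e-6 * np.eye(A.shape[1]), A.T @ b)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(q))
    splits = np.array_split(idx, folds)
    ss_res = 0.0
    ss_tot = 0.0
    for k in range(folds):
        test = splits[k]
        train = np.concatenate([splits[j] for j in range(folds) if j != k])
        w = solve(H[train], q[train])
        pred = H[test] @ w
        ss_res += np.sum((q[test] - pred) ** 2)
        ss_tot += np.sum((q[test] - q[train].mean()) ** 2)
    # a (near-)constant target carries no decodable variance
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-9 * len(q) else 0.0
    weights = solve(H, q)
    return weights, float(r2 * 100.0)


def compare_output_fits(response_diff: np.ndarray, q_diff: np.ndarray) -> dict:
    """Sigmoid-versus-linear fit comparison under Gaussian residuals.

    Fits ``a + b*x`` (2 parameters) and the 4-parameter logistic
    ``lo + (hi - lo) / (1 + exp(-(x - c)/s))`` by least squares and returns
    AIC/BIC differences (sigmoid minus linear; negative favors the sigmoid).
    """
    x = np.asarray(q_diff, dtype=float)
    y = np.asarray(response_diff, dtype=float)
    n = len(x)
    # linear
    A = np.column_stack([np.ones(n), x])
    wlin = np.linalg.lstsq(A, y, rcond=None)[0]
    ss_lin = float(np.sum((y - A @ wlin) ** 2))

    def sig(theta, xx):
        lo, hi, c, log_s = theta
        return lo + (hi - lo) / (1.0 + np.exp(-(xx - c) / np.exp(log_s)))

    def resid(theta):
        return sig(theta, x) - y

    spread = max(np.std(x), 1e-6)
    best = None
    for s0 in (spread / 20, spread / 5, spread):
        theta0 = np.array([np.min(y), np.max(y), np.median(x), np.log(s0)])
        res = optimize.least_squares(resid, theta0, method="lm", max_nfev=5000)
        if best is None or res.cost < best.cost:
            best = res
    ss_sig = float(2 * best.cost)

    def aic(ss, k):  # Gaussian likelihood with sigma^2 profiled out; +1 for sigma
        return n * np.log(max(ss, 1e-300) / n) + 2 * (k + 1)

    def bic(ss, k):
        return n * np.log(max(ss, 1e-300) / n) + np.log(n) * (k + 1)

    return {
        "delta_aic": aic(ss_sig, 4) - aic(ss_lin, 2),
        "delta_bic": bic(ss_sig, 4) - bic(ss_lin, 2),
        "ss_sigmoid": ss_sig,
        "ss_linear": ss_lin,
        "sigmoid_params": best.x,
        "linear_params": wlin,
    }
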