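"""Behavioral fitters: parameter recovery on data simulated from each model."""

import numpy as np
import pytest

from seqdecide import behavior
from seqdecide.sequences import TrialRecord
from seqdecide.tasks.probreason import LEFT, RIGHT, DDMPolicyConfig, sample_task1_trial
from seqdecide.tasks.twostep import TwoStepConfig, sample_task4_dataset


def _fake_trial(stimuli, choice, total_llr=None, rt=None, weights=None):
    info = {}
    if total_llr is not None:
        info["total_logLR"] = total_llr
    return TrialRecord(
        events=None,
        correct_target=None,
        stimuli=np.asarray(stimuli),
        choice=choice,
        rt_epochs=rt if rt is not None else len(stimuli),
        rewarded=False,
        info=info,
    )


class TestPsychometric:
    def test_cumulative_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.choice([-8, -4, -2, -1, 1, 2, 4, 8], size=5000).astype(float)
        y = (rng.normal(x, 3.0) > 0).astype(float)  # true sigma = 3
        fit = behavior.fit_psychometric(x, y, form="cumulative_gaussian")
        assert fit.threshold == pytest.approx(3.0, rel=0.10)
        assert abs(fit.params["mu"]) < 0.3

    def test_logistic_symmetric_data_has_no_bias(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(-3, 3, 4000)])
        y = (rng.random(4000) < 1 / (1 + np.exp(-1.5 * x))).astype(float)
        fit = behavior.fit_psychometric(x, y, form="logistic")
        assert abs(fit.params["bias"]) < 0.15
        assert fit.params["slope"] == pytest.approx(1.5, rel=0.15)

    def test_perfect_separation_flagged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 10)
        y = (x > 0).astype(float)
        fit = behavior.fit_psychometric(x, y, form="logistic")
        assert fit.separation_flag
        assert np.isfinite(fit.params["slope"])

    def test_requires_two_evidence_levels(self):
        with pytest.raises(ValueError):
            behavior.fit_psychometric(np.ones(10), np.ones(10))


class TestSubjectiveWeights:
    def _simulate(self, weights, n, seed, present=range(10)):
        # choices straight from the base-10 logistic evidence model
        rng = np.random.default_rng(seed)
        trials = []
        present = np.asarray(list(present))
        for _ in range(n):
            k = rng.integers(2, 9)
            shapes = rng.choice(present, size=k)
            q = weights[shapes].sum()
            p_left = 1.0 / (1.0 + 10.0 ** (-q))
            trials.append(_fake_trial(shapes, LEFT if rng.random() < p_left else RIGHT))
        return trials

    def test_recovers_known_weights(self, codebook):
        trials = self._simulate(codebook.weights, 20_000, seed=2)
        res = behavior.fit_subjective_weights(trials, seed=0)
        w_hat = res.coef[1:]
        r = np.corrcoef(w_hat, codebook.weights)[0, 1]
        assert r > 0.98
        assert np.all(np.diff(w_hat) < 0.2)  # near-monotone in assigned logLR

    def test_absent_shape_shrunk_to_zero(self, codebook):
        trials = self._simulate(codebook.weights, 5000, seed=3, present=range(1, 10))
        res = behavior.fit_subjective_weights(trials, seed=0)
        assert abs(res.coef[1]) < 0.05  # shape 0 never appeared

    def test_reproducible_under_fixed_cv_seed(self, codebook):
        trials = self._simulate(codebook.weights, 3000, seed=4)
        a = behavior.fit_subjective_weights(trials, seed=7)
        b = behavior.fit_subjective_weights(trials, seed=7)
        assert np.array_equal(a.coef, b.coef) and a.alpha == b.alpha


class TestShapeOrder:
    def _agent_trials(self, codebook, n, seed, primacy=False):
        rng = np.random.default_rng(seed)
        trials = []
        while len(trials) < n:
            k = int(rng.integers(7, 13))
            shapes = rng.integers(0, 10, size=k)
            w = codebook.weights[shapes]
            q = 3.0 * w[0] if primacy else w[:-1].sum()
            p_left = 1.0 / (1.0 + 10.0 ** (-q))
            trials.append(_fake_trial(shapes, LEFT if rng.random() < p_left else RIGHT))
        return trials

    def test_equal_weight_integrator_has_flat_coefficients(self, codebook):
        res = behavior.fit_shape_order(
            self._agent_trials(codebook, 15_000, seed=5), codebook, seed=0
        )
        c, s = res.coef[1:], res.se[1:]
        for i in range(len(c)):
            for j in range(i + 1, len(c)):
                z = abs(c[i] - c[j]) / np.sqrt(s[i] ** 2 + s[j] ** 2)
                assert z < 3.5  # no pair significantly different

    def test_primacy_agent_loads_first_epoch(self, codebook):
        res = behavior.fit_shape_order(
            self._agent_trials(codebook, 15_000, seed=6, primacy=True), codebook, seed=0
        )
        names = res.names
        b1 = res.coef[names.index("epoch_1")]
        b4 = res.coef[names.index("middle")]
        assert b1 > 5 * max(b4, 0.01)

    def test_too_few_trials_raises(self, codebook):
        with pytest.raises(ValueError):
            behavior.fit_shape_order([], codebook)


class TestDDMFit:
    def test_recovers_teacher_parameters(self, codebook):
        rng = np.random.default_rng(7)
        trials = [sample_task1_trial(codebook, DDMPolicyConfig(), rng) for _ in range(30_000)]
        fit = behavior.fit_ddm_collapsing([t for t in trials if t.choice is not None], codebook)
        assert fit.bound0 == pytest.approx(1.5, rel=0.10)
        assert fit.collapse == pytest.approx(0.1, abs=0.01)
        assert fit.variance_captured > 0.99

    def test_random_choices_capture_little_variance(self, codebook):
        rng = np.random.default_rng(8)
        trials = [
            _fake_trial(
                rng.integers(0, 10, 3),
                int(rng.integers(2)),
                total_llr=float(rng.normal(0, 2)),
                rt=int(rng.integers(1, 15)),
            )
            for _ in range(5000)
        ]
        fit = behavior.fit_ddm_collapsing(trials, codebook)
        assert fit.variance_captured < 0.5

    def test_forward_curves_are_probabilities(self, codebook):
        p, mllr = behavior.ddm_forward_curves(codebook, 1.5, 0.1)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)
        # commit-side evidence has the right sign where commits happen
        assert np.nanmin(mllr[:12, 0]) > 0 and np.nanmax(mllr[:12, 1]) < 0


class TestStayTable:
    def test_always_repeat_agent(self):
        cfg = TwoStepConfig()
        trials = list(sample_task4_dataset(cfg, 4, np.random.default_rng(9)))
        for t in trials:
            t.choice = 0
        table = behavior.stay_probability_table(trials)
        assert all(v == 1.0 for v in table.p_stay.values())

    def test_exact_counts_on_hand_built_sequence(self):
        def t(choice, common, rewarded):
            return TrialRecord(
                events=None,
                correct_target=None,
                stimuli=None,
                choice=choice,
                rt_epochs=1,
                rewarded=rewarded,
                info={"common": common, "b_state": 0},
            )

        seq = [t(0, True, True), t(0, True, True), t(1, False, False), t(1, True, False)]
        table = behavior.stay_probability_table(seq)
        assert table.p_stay["CR"] == 0.5 and table.counts["CR"] == 2
        assert table.p_stay["RU"] == 1.0 and table.counts["RU"] == 1
        assert "RR" in table.missing

    def test_model_based_agent_signature(self):
        fit = behavior.HybridRLFit(alpha1=0.5, alpha2=0.5, lam=0.5, beta=6.0, persev=0.0, w_mb=1.0)
        trials = behavior.simulate_hybrid_rl(fit, TwoStepConfig(), 8000, np.random.default_rng(10))
        p = behavior.stay_probability_table(trials).p_stay
        assert p["CR"] > p["CU"] and p["CR"] > p["RR"]
        assert p["RU"] > p["CU"] and p["RU"] > p["RR"]

    def test_model_free_agent_signature(self):
        fit = behavior.HybridRLFit(alpha1=0.6, alpha2=0.5, lam=0.9, beta=6.0, persev=0.0, w_mb=0.0)
        trials = behavior.simulate_hybrid_rl(fit, TwoStepConfig(), 8000, np.random.default_rng(11))
        p = behavior.stay_probability_table(trials).p_stay
        assert p["CR"] > p["CU"] and p["RR"] > p["RU"]  # reward raises stay either way


class TestHistoryLasso:
    def test_iid_choices_give_null_coefficients(self):
        cfg = TwoStepConfig()
        trials = list(sample_task4_dataset(cfg, 60, np.random.default_rng(12)))
        res = behavior.fit_history_lasso(trials, n_back=3, seed=0)
        assert np.max(np.abs(res.coef[1:])) < 0.2

    def test_one_back_dependence_recovered_sparsely(self):
        # agent: repeat after reward, switch after no reward (pure lag-1 rule)
        cfg = TwoStepConfig()
        rng = np.random.default_rng(13)
        base = list(sample_task4_dataset(cfg, 60, rng))
        choice = 0
        for t in base:
            t.choice = choice
            choice = choice if (rng.random() < 0.9) == t.rewarded else 1 - choice
        res = behavior.fit_history_lasso(base, n_back=4, seed=0)
        coef = dict(zip(res.names, res.coef))
        lag1 = max(abs(coef[f"{k}_lag1"]) for k in ("CR", "CU", "RR", "RU"))
        lag4 = max(abs(coef[f"{k}_lag4"]) for k in ("CR", "CU", "RR", "RU"))
        assert lag1 > 1.0 and lag4 < 0.5 * lag1


class TestFiveFactor:
    def test_win_stay_lose_shift_agent_loads_outcome(self):
        cfg = TwoStepConfig()
        rng = np.random.default_rng(14)
        trials = list(sample_task4_dataset(cfg, 60, rng))
        prev_choice, prev_rew = 0, True
        for t in trials:
            t.choice = prev_choice if prev_rew else 1 - prev_choice
            prev_choice, prev_rew = t.choice, t.rewarded
        res = behavior.fit_five_factor(trials)
        coef = dict(zip(res.names, np.abs(res.coef)))
        assert coef["Outcome"] > 2 * max(coef["TransxOut"], coef["Transition"], 0.05)

    def test_model_based_agent_loads_interaction(self):
        fit = behavior.HybridRLFit(alpha1=0.5, alpha2=0.5, lam=0.5, beta=6.0, persev=0.0, w_mb=1.0)
        trials = behavior.simulate_hybrid_rl(fit, TwoStepConfig(), 6000, np.random.default_rng(15))
        res = behavior.fit_five_factor(trials)
        coef = dict(zip(res.names, np.abs(res.coef)))
        assert coef["TransxOut"] > coef["Outcome"]
        assert coef["TransxOut"] > coef["Transition"]


class TestHybridRL:
    @pytest.mark.parametrize("w_true,lo,hi", [(1.0, 0.85, 1.0), (0.0, 0.0, 0.15)])
    def test_recovers_mixture_weight(self, w_true, lo, hi):
        fit_true = behavior.HybridRLFit(
            alpha1=0.4, alpha2=0.6, lam=0.5, beta=5.0, persev=0.2, w_mb=w_true
        )
        trials = behavior.simulate_hybrid_rl(
            fit_true, TwoStepConfig(), 5000, np.random.default_rng(16)
        )
        fit = behavior.fit_hybrid_rl(trials, n_starts=12, seed=0)
        assert lo <= fit.w_mb <= hi

    def test_nll_beats_random_model(self):
        cfg = TwoStepConfig()
        trials = list(sample_task4_dataset(cfg, 40, np.random.default_rng(17)))
        fit = behavior.fit_hybrid_rl(trials, n_starts=6, seed=0)
        assert fit.nll <= len(trials) * np.log(2.0) + 1e-6

    def test_zero_beta_simulation_is_random(self):
        fit = behavior.HybridRLFit(alpha1=0.5, alpha2=0.5, lam=0.5, beta=0.0, persev=0.0, w_mb=0.5)
        trials = behavior.simulate_hybrid_rl(fit, TwoStepConfig(), 4000, np.random.default_rng(18))
        p = np.mean([t.choice == 0 for t in trials])
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(4000)

    def test_strong_perseveration_limit(self):
        fit = behavior.HybridRLFit(alpha1=0.5, alpha2=0.5, lam=0.5, beta=0.0, persev=4.5, w_mb=0.5)
        trials = behavior.simulate_hybrid_rl(fit, TwoStepConfig(), 2000, np.random.default_rng(19))
        stays = np.mean([a.choice == b.choice for a, b in zip(trials[:-1], trials[1:])])
        assert stays > 0.95


class TestValueDecoding:
    def test_linear_map_decodes_cleanly(self):
        rng = np.random.default_rng(20)
        q = rng.normal(0, 1, 3000)
        W = rng.normal(0, 1, 32)
        H = np.outer(q, W) + rng.normal(0, 0.05, (3000, 32))
        _, ev = behavior.decode_value_difference(H, q)
        assert ev > 95.0

    def test_pure_noise_has_no_cross_validated_variance(self):
        rng = np.random.default_rng(21)
        q = rng.normal(0, 1, 2000)
        H = rng.normal(0, 1, (2000, 32))
        _, ev = behavior.decode_value_difference(H, q)
        assert ev < 5.0


class TestOutputFitComparison:
    def test_sigmoid_data_strongly_favors_sigmoid(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 2000)
        y = 1.0 / (1.0 + np.exp(-x / 0.05)) + rng.normal(0, 0.03, 2000)
        res = behavior.compare_output_fits(y, x)
        assert res["delta_aic"] < -100
        assert res["delta_bic"] < -100

    def test_linear_data_gives_no_sigmoid_advantage(self):
        rng = np.random.default_rng(23)
        x = rng.normal(0, 1, 2000)
        y = 0.3 * x + rng.normal(0, 0.1, 2000)
        res = behavior.compare_output_fits(y, x)
        assert res["delta_aic"] >= -2.0
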