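"""Experiment orchestration and serialization.

Builds the per-task training pipelines (generator -> trainer -> closed-loop
test -> analyses), round-trips checkpoints as ``.npz`` archives with a JSON
manifest, and exports tidy result tables.  Seeds for the generator, trainer,
test stream, and policy sampling are all spawned from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import behavior, units
from .core import ActionPolicy, GRUParams, NetworkState, init_params, run_closed_loop, run_open_loop
from .sequences import TrialRecord
from .tasks import multisensory, probreason, twostep, wagering
from .training import AdamState, TrainConfig, train

__all__ = [
    "ExperimentConfig",
    "DEFAULT_BETA",
    "child_seeds",
    "save_checkpoint",
    "load_checkpoint",
    "train_task1",
    "test_task1",
    "train_task4",
    "test_task4",
    "run_experiment",
    "export_results",
]

SCHEMA_VERSION = 1
# Softmax inverse temperature; see ActionPolicy and scripts/calibrate_beta.py.
DEFAULT_BETA = 7.2

TASKS = ("probreason", "multisensory", "wagering", "twostep")


@dataclass
class ExperimentConfig:
    """One run's worth of configuration.

    Full-scale study conditions are 7.5e5 training trials and, for the
    probabilistic-reasoning task, 5000 25-shape test sequences; the defaults
    here are the ~10x-reduced sizes used for single-CPU replication.
    """

    task: str = "probreason"
    n_hidden: int = 128
    n_train_trials: int = 75_000
    n_test: int = 5000  # sequences (task 1) or trials; task 4 uses n_test_blocks
    n_test_blocks: int = 100
    seed: int = 0
    beta: float = DEFAULT_BETA
    unique_sequences: int | None = None
    test_block_len: int | None = None
    checkpoint_every: int = 5000

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def child_seeds(master: int, n: int) -> list[int]:
    """Independent component seeds spawned from a master seed (all < 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------- checkpoints


def save_checkpoint(params: GRUParams, path, manifest: dict | None = None, adam: AdamState | None = None) -> None:
    """Write all parameter tensors plus a JSON manifest to one .npz archive."""
    manifest = dict(manifest or {})
    manifest.update(
        schema_version=SCHEMA_VERSION,
        n_in=params.n_in,
        n_hidden=params.n_hidden,
        n_out=params.n_out,
    )
    arrays = {"flat": params.flat, "manifest": np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)}
    if adam is not None:
        arrays.update(adam_m=adam.m, adam_v=adam.v, adam_t=np.array([adam.t]), adam_eta=np.array([adam.eta]))
    np.savez_compressed(path, **arrays)


def load_checkpoint(path, expect_task: str | None = None):
    """Round-trip a checkpoint; returns (params, manifest, adam-or-None)."""
    import zipfile

    try:
        with np.load(path) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            if manifest.get("schema_version") != SCHEMA_VERSION:
                raise ValueError(f"unsupported checkpoint schema: {manifest.get('schema_version')}")
            params = GRUParams(manifest["n_in"], manifest["n_hidden"], manifest["n_out"], z["flat"])
            adam = None
            if "adam_m" in z:
                adam = AdamState(m=z["adam_m"], v=z["adam_v"], t=int(z["adam_t"][0]), eta=float(z["adam_eta"][0]))
    except ValueError as exc:
        if "schema" in str(exc):
            raise
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    except (OSError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ValueError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    if expect_task is not None and manifest.get("task") != expect_task:
        raise ValueError(f"checkpoint is for task {manifest.get('task')!r}, expected {expect_task!r}")
    return params, manifest, adam


# -------------------------------------------------------------------- task 1


def train_task1(
    n_trials: int = 75_000,
    n_hidden: int = 128,
    seed: int = 0,
    unique_sequences: int | None = None,
    checkpoint_every: int = 5000,
) -> tuple[GRUParams, object, probreason.ShapeCodebook]:
    s_init, s_gen = child_seeds(seed, 2)
    cb = probreason.build_codebook()
    params = init_params(probreason.N_IN, n_hidden, probreason.N_IN, seed=s_init)
    gen = probreason.teacher_trials(cb, seed=s_gen, unique_sequences=unique_sequences)
    cfg = TrainConfig(eta=1e-3, n_trials=n_trials, seed=seed, checkpoint_every=checkpoint_every)
    params, log = train(params, gen, cfg)
    return params, log, cb


def test_task1(
    params: GRUParams,
    cb: probreason.ShapeCodebook,
    n_sequences: int = 5000,
    seed: int = 1,
    beta: float = DEFAULT_BETA,
    record_hidden: bool = False,
) -> tuple[list[TrialRecord], dict]:
    """Frozen-weight closed-loop test on random 25-shape sequences.

    Returns the trial records and the headline behavioral metrics: abort
    percentage, accuracy, the percentage of completed trials whose choice
    matches the sign of the final shape's logLR, and the mean reaction time.
    """
    s_stream, s_policy = child_seeds(seed, 2)
    pol = ActionPolicy(beta=beta, action_indices=probreason.CHANNELS.action_indices())
    rng = np.random.default_rng(s_policy)
    recs = []
    for tgt, shapes in probreason.random_test_stream(cb, n_sequences, seed=s_stream):
        env = probreason.Task1Environment(shapes, tgt, cb)
        recs.append(run_closed_loop(params, env, pol, rng, record_hidden=record_hidden))
    done = [r for r in recs if not r.aborted]
    consist = [
        (r.info["final_logLR"] > 0) == (r.choice == probreason.LEFT)
        for r in done
        if r.info["final_logLR"] != 0
    ]
    metrics = {
        "n_trials": len(recs),
        "abort_pct": 100.0 * (1 - len(done) / max(len(recs), 1)),
        "accuracy_pct": 100.0 * float(np.mean([r.rewarded for r in done])) if done else np.nan,
        "last_shape_consistency_pct": 100.0 * float(np.mean(consist)) if consist else np.nan,
        "mean_rt_epochs": float(np.mean([r.rt_epochs for r in done])) if done else np.nan,
    }
    return recs, metrics


# -------------------------------------------------------------------- task 4


def train_task4(
    n_blocks: int = 2000,
    n_hidden: int = 128,
    seed: int = 0,
    checkpoint_every: int = 5000,
) -> tuple[GRUParams, object, twostep.TwoStepConfig]:
    s_init, s_gen = child_seeds(seed, 2)
    cfg = twostep.TwoStepConfig()
    params = init_params(twostep.N_IN, n_hidden, twostep.N_IN, seed=s_init)
    gen = twostep.sample_task4_dataset(cfg, n_blocks, np.random.default_rng(s_gen))
    tcfg = TrainConfig(
        eta=1e-4,
        n_trials=n_blocks * cfg.block_len,
        carry_state=True,
        bptt_trials=2,
        seed=seed,
        checkpoint_every=checkpoint_every,
    )
    params, log = train(params, gen, tcfg)
    return params, log, cfg


def test_task4(
    params: GRUParams,
    cfg: twostep.TwoStepConfig,
    n_blocks: int = 100,
    seed: int = 1,
    beta: float = DEFAULT_BETA,
    block_len: int | None = None,
) -> tuple[list[TrialRecord], np.ndarray]:
    """Frozen-weight closed-loop test blocks with the state carried throughout.

    Returns the trial records and the per-trial hidden snapshot at the
    decision step (the frame on which the first-stage choice is sampled).
    """
    _, s_policy = child_seeds(seed, 2)
    world = twostep.TwoStepWorld(cfg, block_len)
    pol = ActionPolicy(beta=beta, action_indices=np.array([twostep.ACT_A1, twostep.ACT_A2]))
    rng = np.random.default_rng(s_policy)
    recs: list[TrialRecord] = []
    snaps = []
    state = NetworkState.zeros(params.n_hidden)
    n_trials = n_blocks * (block_len or cfg.block_len)
    for _ in range(n_trials):
        env = twostep.TwoStepEnvironment(world)
        rec = run_closed_loop(
            params, env, pol, rng, carry_state=True, state=state, record_hidden=True
        )
        state = rec.info.pop("final_state")
        snaps.append(rec.hidden[twostep.DECISION_STEP])
        rec.hidden = None  # keep memory bounded over thousands of trials
        recs.append(rec)
    return recs, np.asarray(snaps)


# ------------------------------------------------------------ orchestration


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    metrics: dict
    tables: dict = field(default_factory=dict)


def run_experiment(cfg: ExperimentConfig, outdir) -> ExperimentResult:
    """Train, test, analyze, and export one run into ``outdir``.

    The directory receives the checkpoint, the training log, a JSONL trial
    log of the test phase, tidy CSV tables for the task's analyses, and a
    ``metrics.json`` summary.  Everything is reproducible from the config
    (its hash is embedded in the manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hex(abs(hash(json.dumps(asdict(cfg), sort_keys=True))) % 16**8)
    s_train, s_test = child_seeds(cfg.seed, 2)
    metrics: dict = {}
    tables: dict = {}

    if cfg.task == "probreason":
        params, log, cb = train_task1(
            cfg.n_train_trials, cfg.n_hidden, s_train, cfg.unique_sequences, cfg.checkpoint_every
        )
        recs, metrics = test_task1(params, cb, cfg.n_test, s_test, cfg.beta)
        done = [r for r in recs if not r.aborted]
        if len(done) < 100:  # e.g. a deliberately undertrained smoke run
            metrics["analyses_skipped"] = "fewer than 100 completed trials"
            done = []
        if done:
            _task1_analyses(params, done, cb, metrics, tables)
    elif cfg.task == "twostep":
        params, log, tcfg = train_task4(
            cfg.n_train_trials // twostep.TwoStepConfig().block_len,
            cfg.n_hidden,
            s_train,
            cfg.checkpoint_every,
        )
        cb = None
        recs, snaps = test_task4(
            params, tcfg, cfg.n_test_blocks, s_test, cfg.beta, cfg.test_block_len
        )
        stay = behavior.stay_probability_table(recs)
        fit = behavior.fit_hybrid_rl(recs, tcfg)
        qdiff = behavior.hybrid_q_values(recs, fit, tcfg)
        _, ev = behavior.decode_value_difference(snaps, qdiff)
        metrics = {
            "reward_rate": float(np.mean([r.rewarded for r in recs])),
            "w_model_based": fit.w_mb,
            "w_model_free": fit.w_mf,
            "rl_nll": fit.nll,
            "q_decoding_explained_variance_pct": ev,
            **{f"p_stay_{k}": v for k, v in stay.p_stay.items()},
        }
        five = behavior.fit_five_factor(recs)
        tables["five_factor"] = five.to_frame()
    elif cfg.task == "multisensory":
        params, log, recs, metrics = _run_task2(cfg, s_train, s_test)
    else:
        params, log, recs, metrics = _run_task3(cfg, s_train, s_test)

    save_checkpoint(
        params,
        outdir / "checkpoint.npz",
        {"task": cfg.task, "seed": cfg.seed, "config_hash": cfg_hash, "n_train_trials": cfg.n_train_trials},
    )
    log.to_jsonl(outdir / "train_log.jsonl")
    with open(outdir / "trials.jsonl", "w") as fh:
        for r in recs:
            fh.write(json.dumps(r.to_json_dict()) + "\n")
    metrics["config_hash"] = cfg_hash
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    return ExperimentResult(config=cfg, metrics=metrics, tables=tables)


def _task1_analyses(params, done, cb, metrics, tables):
    psy = behavior.fit_psychometric(
        np.array([r.info["total_logLR"] for r in done]),
        np.array([1.0 if r.choice == probreason.LEFT else 0.0 for r in done]),
    )
    metrics["psychometric_slope"] = float(psy.params["slope"])
    ddm = behavior.fit_ddm_collapsing(done, cb)
    metrics.update(
        ddm_bound0=ddm.bound0,
        ddm_collapse=ddm.collapse,
        ddm_variance_captured_pct=100.0 * ddm.variance_captured,
    )
    tables["subjective_weights"] = behavior.fit_subjective_weights(done).to_frame()
    ww = units.compute_when_which(
        params, probreason.ACT_FIX, probreason.ACT_LEFT, probreason.ACT_RIGHT
    )
    metrics["n_plus_when"] = int(len(ww.groups["+when"]))
    out_traces = [run_open_loop(params, r.events, record_hidden=False)[1] for r in done[:1000]]
    kl = units.shape_prediction_kl(out_traces, done[:1000], cb)
    tables["kl_curves"] = _kl_frame(kl)


def _kl_frame(kl: dict):
    import pandas as pd

    return pd.DataFrame(
        {
            "bin_mean_llr": kl["bin_mean_llr"],
            "kl_left": kl["kl_left"],
            "kl_right": kl["kl_right"],
        }
    )


def _run_task2(cfg: ExperimentConfig, s_train: int, s_test: int):
    t2 = multisensory.Task2Config()
    s_init, s_gen = child_seeds(s_train, 2)
    params = init_params(multisensory.N_IN, cfg.n_hidden, multisensory.N_IN, seed=s_init)
    rng = np.random.default_rng(s_gen)

    def gen():
        while True:
            cond = "visual" if rng.random() < 0.5 else "vestibular"
            yield multisensory.sample_task2_trial(t2, rng, cond)

    params, log = train(
        params, gen(), TrainConfig(eta=1e-3, n_trials=cfg.n_train_trials, seed=cfg.seed, checkpoint_every=cfg.checkpoint_every)
    )
    pol = ActionPolicy(beta=cfg.beta, action_indices=multisensory.CHANNELS.action_indices())
    rng_t = np.random.default_rng(s_test)
    metrics = {}
    recs = []
    for cond in ("visual", "vestibular", "bimodal"):
        cond_recs = []
        for _ in range(cfg.n_test):
            heading = float(rng_t.choice(t2.stimulus_headings))
            env = multisensory.Task2Environment(t2, cond, heading, rng_t)
            cond_recs.append(run_closed_loop(params, env, pol, rng_t))
        done = [r for r in cond_recs if not r.aborted]
        if len({r.info["heading"] for r in done}) >= 2:
            fit = behavior.fit_psychometric(
                np.array([r.info["heading"] for r in done]),
                np.array([1.0 if r.choice == multisensory.LEFT else 0.0 for r in done]),
                form="cumulative_gaussian",
            )
            metrics[f"threshold_{cond}"] = fit.threshold
        metrics[f"accuracy_{cond}"] = float(np.mean([r.rewarded for r in done])) if done else np.nan
        recs.extend(cond_recs)
    return params, log, recs, metrics


def _run_task3(cfg: ExperimentConfig, s_train: int, s_test: int):
    t3 = wagering.Task3Config()
    s_init, s_gen = child_seeds(s_train, 2)
    params = init_params(wagering.N_IN, cfg.n_hidden, wagering.N_IN, seed=s_init)
    rng = np.random.default_rng(s_gen)

    def gen():
        while True:
            yield wagering.sample_task3_trial(t3, rng)

    params, log = train(
        params, gen(), TrainConfig(eta=1e-3, n_trials=cfg.n_train_trials, seed=cfg.seed, checkpoint_every=cfg.checkpoint_every)
    )
    pol = ActionPolicy(beta=cfg.beta, action_indices=wagering.CHANNELS.action_indices())
    rng_t = np.random.default_rng(s_test)
    recs = []
    for _ in range(cfg.n_test):
        env = wagering.Task3Environment(t3, rng_t)
        recs.append(run_closed_loop(params, env, pol, rng_t))
    done = [r for r in recs if not r.aborted]
    with_sure = [r for r in done if r.info["sure_available"]]
    no_sure = [r for r in done if not r.info["sure_available"]]
    dir_with_sure = [r for r in with_sure if r.choice != wagering.SURE]
    metrics = {
        "abort_pct": 100.0 * (1 - len(done) / max(len(recs), 1)),
        "p_sure_given_available": float(np.mean([r.choice == wagering.SURE for r in with_sure]))
        if with_sure
        else np.nan,
        "accuracy_no_sure": float(np.mean([r.rewarded for r in no_sure])) if no_sure else np.nan,
        "accuracy_direction_with_sure": float(np.mean([r.rewarded for r in dir_with_sure]))
        if dir_with_sure
        else np.nan,
    }
    return params, log, recs, metrics


def export_trace(trace: np.ndarray, path, prefix: str = "u") -> None:
    """Write a hidden or output trace as CSV, one row per time step."""
    import pandas as pd

    trace = np.asarray(trace)
    pd.DataFrame(trace, columns=[f"{prefix}{i}" for i in range(trace.shape[1])]).to_csv(
        path, index_label="step"
    )


def export_results(run_dir) -> dict:
    """Bundle manifest of a run directory: which tables/artifacts are present."""
    run_dir = Path(run_dir)
    expected = ["checkpoint.npz", "train_log.jsonl", "trials.jsonl", "metrics.json"]
    manifest = {"present": [], "missing": []}
    for name in expected:
        (manifest["present"] if (run_dir / name).exists() else manifest["missing"]).append(name)
    manifest["tables"] = sorted(p.name for p in run_dir.glob("*.csv"))
    with open(run_dir / "bundle_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
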