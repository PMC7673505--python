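#!/usr/bin/env python
"""Calibrate the softmax inverse temperature of the action policy.

The model description leaves beta free.  The package pins it by a behavioral
criterion: on the trained probabilistic-reasoning model, the closed-loop
abort rate (spurious or missing responses) should land near a few percent of
test trials -- the regime in which the rest of the analysis battery is run.
This script trains a scaled model (or loads a checkpoint), sweeps beta, and
prints the abort/accuracy trade-off so the default in
``seqdecide.harness.DEFAULT_BETA`` can be chosen.

Usage:
    python scripts/calibrate_beta.py --seed 0 --trials 75000
    python scripts/calibrate_beta.py --checkpoint run/checkpoint.npz
"""

from __future__ import annotations

import argparse

import numpy as np

from seqdecide.harness import load_checkpoint, test_task1, train_task1
from seqdecide.tasks.probreason import build_codebook

TARGET_ABORT_PCT = 3.45


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--trials", type=int, default=75_000)
    ap.add_argument("--checkpoint", type=str, default=None)
    ap.add_argument("--n-test", type=int, default=2000)
    ap.add_argument("--betas", type=float, nargs="*", default=[5, 6, 6.5, 7, 7.2, 7.5, 8, 10])
    args = ap.parse_args()

    if args.checkpoint:
        params, _, _ = load_checkpoint(args.checkpoint)
        cb = build_codebook()
    else:
        print(f"training a {args.trials}-trial model (seed {args.seed})...", flush=True)
        params, _, cb = train_task1(n_trials=args.trials, seed=args.seed)

    best = None
    print(f"{'beta':>6} {'abort%':>8} {'accuracy%':>10} {'last-shape%':>12} {'mean RT':>8}")
    for beta in args.betas:
        _, m = test_task1(params, cb, n_sequences=args.n_test, seed=args.seed + 1, beta=beta)
        print(
            f"{beta:6.2f} {m['abort_pct']:8.2f} {m['accuracy_pct']:10.2f} "
            f"{m['last_shape_consistency_pct']:12.2f} {m['mean_rt_epochs']:8.2f}"
        )
        gap = abs(m["abort_pct"] - TARGET_ABORT_PCT)
        if best is None or gap < best[1]:
            best = (beta, gap)
    print(f"\nclosest to the {TARGET_ABORT_PCT}% abort criterion: beta = {best[0]}")


if __name__ == "__main__":
    main()
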