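#!/usr/bin/env python
"""Sweep the generalization error against the number of selected features.

For a chosen prediction scenario, repeatedly simulates data, fits the
stacked elastic net and the lasso on the training subsample, constrains
both to 1..cap_max non-zero coefficients (post-hoc adaptive-lasso
selection for the stacked model, path truncation for the lasso), and
writes the median out-of-sample MSE per support size as a tidy TSV. The
dashed-line references (unrestricted stacked model and lasso) are included
as support size -1.

Usage: python scripts/posthoc_sweep.py --scenario 1 --reps 20 --seed 1 \
           --out results/posthoc_sweep_s1.tsv
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from stackenet import glm_core as gc
from stackenet import simulation_bench as sb
from stackenet.posthoc_selection import dss_path
from stackenet.stacking import extract_base, fit_stacked_elastic_net


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scenario", type=int, default=1, choices=(1, 2, 3))
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--n-train", type=int, default=100)
    ap.add_argument("--cap-max", type=int, default=50)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args(argv)

    scenario = sb.prediction_scenario(args.scenario)
    records = []
    for rep in range(args.reps):
        rs = args.seed + rep
        X, y = sb.simulate_prediction(scenario, rs)
        Xtr, ytr = X[: args.n_train], y[: args.n_train]
        Xte, yte = X[args.n_train:], y[args.n_train:]
        model = fit_stacked_elastic_net(Xtr, ytr, "gaussian", seed=rs)
        lasso = extract_base(model.base, 1.0)

        def record(method, nz, b0, b):
            mse = float(np.mean((yte - (b0 + Xte @ b)) ** 2))
            records.append({"rep": rep, "method": method, "nonzero": nz,
                            "test_mse": mse})

        record("stack", -1, model.pooled_intercept, model.pooled_slopes)
        record("lasso", -1, lasso.intercept, lasso.slopes)
        for approx in dss_path(Xtr, model):
            if 0 < approx.nonzero <= args.cap_max:
                record("stack_dss", approx.nonzero, approx.gamma0, approx.gamma)
        _, B, b0s, _ = gc.enet_path(Xtr, ytr, "gaussian", 1.0,
                                    scale_outcome=True)
        for il in range(B.shape[0]):
            nz = int(np.count_nonzero(B[il]))
            if 0 < nz <= args.cap_max:
                record("lasso_capped", nz, float(b0s[il]), B[il])

    rows = pd.DataFrame.from_records(records)
    # keep the sparsest fit per (rep, method, nonzero), then take medians
    rows = rows.groupby(["rep", "method", "nonzero"], as_index=False).first()
    med = rows.groupby(["method", "nonzero"], as_index=False)["test_mse"].median()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    med.to_csv(args.out, sep="\t", index=False)
    print(f"wrote {args.out} ({len(med)} rows)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
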