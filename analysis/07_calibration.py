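#!/usr/bin/env python
"""Statistical calibration benchmarks of the moderated test.

Three checks on generator output: type-I error under a fully null
experiment, FDR and sensitivity at q < 0.05 under the default planted
configuration (20 replicate experiments), and recovery of the variance
prior (d0, s0^2) from scaled-chi-square draws. Writes a JSON summary.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from phosq import SimConfig, fit_ebayes, fit_normalization, glog_transform, moderated_test
from phosq.simulate import simulate_experiment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/calibration.json"))
    args = ap.parse_args()
    out = {}

    null_cfg = SimConfig(n_proteins=1667, fraction_differential=0.0,
                         pathway_n_proteins=0, n_motif_sites=0,
                         protein_diff_fraction=0.0, seed=args.seed)
    _, ph, _, design, _, _ = simulate_experiment(null_cfg)
    p = moderated_test(glog_transform(ph, fit_normalization(ph)), design)["p"].dropna()
    out["type_i_error_rate"] = float((p < 0.05).mean())
    print(f"type-I error (null, {len(p)} sites): {out['type_i_error_rate']:.4f}")

    fdrs, sens = [], []
    for r in range(20):
        cfg = SimConfig(n_proteins=667, seed=args.seed + r)
        _, ph, _, dsg, _, truth = simulate_experiment(cfg)
        res = moderated_test(glog_transform(ph, fit_normalization(ph)), dsg).set_index("site_id")
        tested = res["p"].notna()
        called = (res["q"] < 0.05) & tested
        truly = truth.site_effects["total_log2_effect"].reindex(res.index) != 0
        nc = int(called.sum())
        fdrs.append(float((called & ~truly).sum() / nc) if nc else 0.0)
        sens.append(float((called & truly).sum() / (truly & tested).sum()))
    out["empirical_fdr_q05"] = float(np.mean(fdrs))
    out["sensitivity_q05"] = float(np.mean(sens))
    print(f"FDR at q<0.05 over 20 experiments: {out['empirical_fdr_q05']:.4f} "
          f"(sensitivity {out['sensitivity_q05']:.4f})")

    rng = np.random.default_rng(args.seed)
    s2 = 0.04 * rng.chisquare(4, 5000) / 4.0
    hyper = fit_ebayes(s2, np.inf)
    out["ebayes_recovered_d0"] = float(hyper.d0)
    out["ebayes_recovered_s0_sq"] = float(hyper.s0_sq)
    print(f"variance prior recovery: d0 = {hyper.d0:.2f} (true 4), "
          f"s0^2 = {hyper.s0_sq:.4f} (true 0.04)")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
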