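#!/usr/bin/env python
"""Group-level tests: pathway shift (Welch) and kinase-motif shifts (rank-sum).

Tests whether sites of the planted insulin/TOR-like pathway group are less
phosphorylated than the rest (Welch two-sample t on fold changes) and
whether any kinase consensus-motif group is shifted against the total site
population (Wilcoxon rank-sum, BH across kinases).
"""

import argparse
from pathlib import Path

import pandas as pd

from phosq import pathway_group_test
from phosq import io as pio
from phosq.motifs import assign_groups, default_motifs, motif_shift_test


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    design = pio.read_design(args.datadir / "design.tsv")
    sites, _ = pio.read_site_table(args.datadir / "sites.tsv", design)
    stats = pio.read_results(args.outdir / "site_stats.tsv")
    fc = stats.set_index("site_id")["log2fc_adj"]

    membership = {
        line.strip()
        for line in (args.datadir / "truth_pathway_sites.txt").read_text().splitlines()
        if line.strip()
    }
    res = pathway_group_test(fc, membership)
    pio.write_results(
        pd.DataFrame([{"label": res.label, "n_in": res.n_in, "n_out": res.n_out,
                       "t": res.statistic, "df": res.df, "p": res.p, "shift": res.shift}]),
        args.outdir / "pathway_test.tsv",
    )
    print(f"pathway group ({res.n_in} sites): shift {res.shift:+.3f} log2 units, "
          f"Welch t = {res.statistic:.2f}, p = {res.p:.3g}")

    groups = assign_groups(sites, default_motifs())
    motif_res = motif_shift_test(fc, groups)
    pio.write_results(motif_res, args.outdir / "motif_results.tsv")
    top = motif_res[motif_res["testable"]].sort_values("p").head(3)
    print("top kinase groups by rank-sum p:")
    for row in top.itertuples(index=False):
        print(f"  {row.kinase:10s} n={row.n_matched:4d} shift {row.median_shift:+.3f} "
              f"p={row.p:.3g} q={row.q:.3g}")


if __name__ == "__main__":
    main()
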