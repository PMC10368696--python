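#!/usr/bin/env python
"""GO over-representation among proteins with regulated phospho-sites.

Builds down- and up-regulated protein queries (any site with p below the
threshold in the stated direction, protein-adjusted fold changes) against
the quantified-protein universe and scores each annotation term with the
upper-tail hypergeometric test, BH-corrected.
"""

import argparse
from pathlib import Path

from phosq import io as pio
from phosq.go import build_query_sets, hypergeom_enrich


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--p-threshold", type=float, default=0.05)
    args = ap.parse_args()

    stats = pio.read_results(args.outdir / "site_stats.tsv")
    ann = pio.read_annotations(args.datadir / "annotations.tsv")

    for direction in ("down", "up"):
        query, universe = build_query_sets(stats, direction, args.p_threshold)
        enr = hypergeom_enrich(query, universe, ann)
        pio.write_results(enr, args.outdir / f"go_{direction}.tsv")
        print(f"{direction}: query {len(query)} of {len(universe)} proteins, "
              f"{len(enr)} terms tested")
        if len(enr):
            top = enr.iloc[0]
            print(f"  top term {top['term_id']} ({top['term_name']}): "
                  f"k/K = {top['k']}/{top['K']}, q = {top['q']:.3g}")


if __name__ == "__main__":
    main()
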