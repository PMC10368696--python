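"""GO over-representation analysis of regulated proteins.

Query sets are proteins carrying at least one phospho-site significantly
regulated in the stated direction; the universe is all proteins with at
least one tested site (quantified-protein background, guarding against
detection bias). Each term is scored with the upper-tail hypergeometric
probability P(X >= k) for drawing k annotated proteins in a query of size n
from a universe of N containing K annotated proteins, BH-corrected across
terms. Annotations are used as given (no ontology-graph propagation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import GOAnnotation, ValidationError
from .stats import bh_adjust

log = logging.getLogger(__name__)

GO_RESULT_COLUMNS = ["term_id", "term_name", "N", "K", "n", "k", "p", "q"]


def build_query_sets(
    results: pd.DataFrame,
    direction: str,
    p_threshold: float = 0.05,
    *,
    use_adjusted_fc: bool = True,
) -> tuple[set[str], set[str]]:
    """(query, universe) protein sets for one regulation direction.

    ``results`` must carry ``protein_id``, ``p`` and a fold-change column;
    the protein-adjusted fold change is used for the direction when present.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if "protein_id" not in results.columns:
        raise ValidationError("results must carry a protein_id column")
    fc_col = "log2fc_adj" if use_adjusted_fc and "log2fc_adj" in results.columns else "log2fc_raw"
    tested = results[results["p"].notna()]
    universe = set(tested["protein_id"])
    if not universe:
        raise ValidationError("empty universe: no tested sites")
    sig = tested[tested["p"] < p_threshold]
    if direction == "down":
        sig = sig[sig[fc_col] < 0]
    else:
        sig = sig[sig[fc_col] > 0]
    return set(sig["protein_id"]), universe


def hypergeom_enrich(
    query: set[str],
    universe: set[str],
    annotations: GOAnnotation,
    *,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the query set."""
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    if not universe:
        raise ValidationError("empty universe")
    ann = annotations.restrict_to(universe)
    members = ann.term_members()
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(members):
        term_set = members[term_id]
        K = len(term_set)
        if K == 0:
            log.info("term %s absent from universe after intersection; skipped", term_id)
            continue
        if K < min_term_size:
            continue
        k = len(term_set & query)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            dict(term_id=term_id, term_name=annotations.term_names.get(term_id, ""),
                 N=N, K=K, n=n, k=k, p=min(p, 1.0))
        )
    df = pd.DataFrame(rows, columns=GO_RESULT_COLUMNS[:-1])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = np.nan
    return df
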