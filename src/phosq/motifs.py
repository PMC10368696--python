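"""Kinase consensus-motif scanning and group shift tests.

A motif is a map from signed offsets (relative to the phospho-acceptor at
offset 0) to allowed residue sets, written in the compact linear notation
``X-(S/T)-X-X-(D/E)``: each dash-separated element is either ``X``
(unconstrained), a single residue, or a ``(A/B/...)`` alternative set. The
acceptor element is the first element whose allowed set is a subset of
{S, T, Y}; an element may be suffixed with ``*`` to mark the acceptor
explicitly (needed for doubly S/T-constrained motifs such as GSK3).

Group-level regulation is assessed with the Wilcoxon rank-sum test of the
matched sites' fold changes against all sites' fold changes (group-vs-total;
a group-vs-complement variant is available), with BH correction across
kinases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ACCEPTORS, PAD, RESIDUES, PhosphoSite, ValidationError
from .stats import bh_adjust, wilcoxon_rank_sum


@dataclass(frozen=True)
class MotifDef:
    """A kinase consensus pattern anchored at the phospho-acceptor (offset 0)."""

    kinase: str
    offsets: dict[int, frozenset[str]] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if 0 not in self.offsets:
            raise ValidationError(f"motif {self.kinase}: no acceptor (offset 0) constraint")
        if not set(self.offsets[0]) <= set(ACCEPTORS):
            raise ValidationError(
                f"motif {self.kinase}: acceptor set {sorted(self.offsets[0])} "
                "is not a subset of S/T/Y"
            )
        for off, allowed in self.offsets.items():
            if not allowed:
                raise ValidationError(f"motif {self.kinase}: empty allowed set at {off:+d}")
            bad = set(allowed) - set(RESIDUES)
            if bad:
                raise ValidationError(
                    f"motif {self.kinase}: non-residue characters {sorted(bad)} at {off:+d}"
                )

    @property
    def half_span(self) -> int:
        return max(abs(o) for o in self.offsets)


def parse_motif_pattern(kinase: str, pattern: str, description: str = "") -> MotifDef:
    """Parse linear notation like ``X-(S/T)-X-X-(D/E)`` into a :class:`MotifDef`."""
    elements = pattern.strip().split("-")
    parsed: list[tuple[frozenset[str] | None, bool]] = []  # (allowed or None for X, starred)
    for el in elements:
        el = el.strip()
        starred = el.endswith("*")
        if starred:
            el = el[:-1]
        if el.upper() == "X":
            parsed.append((None, starred))
        elif el.startswith("(") and el.endswith(")"):
            allowed = frozenset(r.strip().upper() for r in el[1:-1].split("/"))
            parsed.append((allowed, starred))
        elif len(el) == 1:
            parsed.append((frozenset(el.upper()), starred))
        else:
            raise ValidationError(f"motif {kinase}: cannot parse element {el!r} in {pattern!r}")

    anchor = None
    for i, (allowed, starred) in enumerate(parsed):
        if starred:
            anchor = i
            break
    if anchor is None:
        for i, (allowed, _) in enumerate(parsed):
            if allowed is not None and allowed <= set(ACCEPTORS):
                anchor = i
                break
    if anchor is None:
        raise ValidationError(f"motif {kinase}: no acceptor element (S/T/Y subset) in {pattern!r}")

    offsets = {
        i - anchor: allowed
        for i, (allowed, _) in enumerate(parsed)
        if allowed is not None
    }
    return MotifDef(kinase=kinase, offsets=offsets, description=description or pattern)


#: Default consensus patterns for the kinases analysed as groups. Only the CK2
#: consensus (acceptor with an acidic residue at +3) is specific to this
#: pipeline's primary use case; the others are literature-standard defaults and
#: should be replaced with the user's own definitions where exact membership
#: matters.
DEFAULT_MOTIF_TABLE: list[tuple[str, str, str]] = [
    ("Akt", "R-X-R-X-X-(S/T)", "basophilic RxRxxS/T"),
    ("AMPK", "(L/M)-X-R-X-X-(S/T)", "hydrophobic-basic context"),
    ("Aurora", "(R/K)-X-(S/T)", "basic at -2"),
    ("CaMK2", "R-X-X-(S/T)", "basic at -3"),
    ("Cdc2", "(S/T)-P-X-X-(K/R)", "proline-directed, basic at +4"),
    ("CDK1", "(S/T)-P-X-(K/R)", "proline-directed, basic at +3"),
    ("CK1", "(D/E)-(D/E)-X-X-(S/T)", "acidic upstream"),
    ("CK2", "X-(S/T)-X-X-(D/E)", "acidic at +3"),
    ("ERK/MAPK", "P-X-(S/T)-P", "proline at -2 and +1"),
    ("GSK3", "(S/T)*-X-X-X-(S/T)", "primed S/T at +4"),
    ("PKA", "R-(R/K)-X-(S/T)", "basic at -3/-2"),
    ("S6K", "(K/R)-X-(K/R)-X-X-(S/T)", "basophilic"),
    ("TOR", "(F/L)-X-X-(S/T)", "hydrophobic at -3"),
]


def default_motifs() -> list[MotifDef]:
    return [parse_motif_pattern(k, p, d) for k, p, d in DEFAULT_MOTIF_TABLE]


def read_motif_table(path) -> list[MotifDef]:
    """Read a tab-separated kinase / pattern [/ description] motif file."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("kinase", "pattern"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    motifs = []
    for row in df.itertuples(index=False):
        desc = getattr(row, "description", "") or ""
        motifs.append(parse_motif_pattern(str(row.kinase), str(row.pattern), str(desc)))
    return motifs


def match_motif(window: str, motif: MotifDef) -> bool:
    """True iff every constrained offset's residue is in its allowed set.

    'X' padding (protein terminus) never satisfies a constrained offset.
    """
    half = len(window) // 2
    if motif.half_span > half:
        raise ValidationError(
            f"motif {motif.kinase} spans {motif.half_span} but window half-width is {half}"
        )
    for off, allowed in motif.offsets.items():
        residue = window[half + off]
        if residue == PAD or residue not in allowed:
            return False
    return True


def assign_groups(sites: list[PhosphoSite], motifs: list[MotifDef]) -> dict[str, set[str]]:
    """Map kinase → matching site ids. Groups are non-exclusive and order-invariant."""
    names = [m.kinase for m in motifs]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate kinase names: {dups}")
    groups: dict[str, set[str]] = {}
    for motif in motifs:
        groups[motif.kinase] = {s.site_id for s in sites if match_motif(s.window, motif)}
    return groups


MOTIF_RESULT_COLUMNS = [
    "kinase", "n_matched", "n_total", "statistic", "p", "q", "median_shift", "testable",
]


def motif_shift_test(
    fold_changes: pd.Series,
    groups: dict[str, set[str]],
    *,
    comparison: str = "total",
) -> pd.DataFrame:
    """Wilcoxon rank-sum shift test of each kinase group's fold changes.

    ``fold_changes`` is indexed by site id. With ``comparison='total'`` each
    group is tested against all sites (the group included); 'complement'
    tests against the non-members. BH correction is applied across kinases.
    Empty (or all-missing) groups are flagged untestable, never dropped.
    """
    if comparison not in ("total", "complement"):
        raise ValueError(f"unknown comparison {comparison!r}")
    fc = fold_changes.dropna()
    all_values = fc.to_numpy(dtype=float)
    rows = []
    for kinase in sorted(groups):
        member_ids = groups[kinase] & set(fc.index)
        x = fc.loc[sorted(member_ids)].to_numpy(dtype=float)
        ref = all_values if comparison == "total" else fc.drop(index=sorted(member_ids)).to_numpy()
        if len(x) == 0 or len(ref) == 0:
            rows.append(
                dict(kinase=kinase, n_matched=len(x), n_total=len(fc),
                     statistic=np.nan, p=np.nan, q=np.nan,
                     median_shift=np.nan, testable=False)
            )
            continue
        res = wilcoxon_rank_sum(x, ref, mode="approx")
        rows.append(
            dict(kinase=kinase, n_matched=len(x), n_total=len(fc),
                 statistic=res.statistic, p=res.p, q=np.nan,
                 median_shift=float(np.median(x) - np.median(all_values)),
                 testable=True)
        )
    df = pd.DataFrame(rows, columns=MOTIF_RESULT_COLUMNS)
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "q"] = bh_adjust(df.loc[testable, "p"].to_numpy())
    return df
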