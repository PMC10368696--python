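"""Core domain types for the phospho-quantification pipeline.

The pipeline operates on a small set of in-memory containers:

* :class:`PhosphoSite` — identity and sequence context of one phospho-acceptor
  residue (S/T/Y) on a protein, with a fixed-width flanking window and a
  localization probability.
* :class:`Design` — the channel layout of an isobaric-label experiment
  (channel → condition / replicate / fraction).
* :class:`QuantTable` — a rows × channels matrix of reporter intensities
  (raw scale) or variance-stabilized values (glog scale).
* :class:`GOAnnotation` — protein → GO-term membership plus term names.

Tabular results (per-site statistics, group tests, enrichment) are plain
pandas DataFrames with documented column schemas; see the module that
produces each one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the 20 standard amino-acid one-letter codes
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: phospho-acceptor residues
ACCEPTORS = ("S", "T", "Y")

#: padding character used where a flanking window runs past a protein terminus
PAD = "X"

#: valid experimental conditions
CONDITIONS = ("fed", "deprived")

#: valid fractions of the TiO2 enrichment
FRACTIONS = ("phospho", "flowthrough")


class FormatError(ValueError):
    """A file does not have the expected structure (missing columns, bad header)."""


class ValidationError(ValueError):
    """Structurally well-formed input violates a domain invariant."""


class ConfigError(ValueError):
    """A configuration value violates its declared constraints."""


def extract_window(sequence: str, position: int, width: int = 15) -> str:
    """Extract the residue window of odd ``width`` centred on 1-based ``position``.

    Positions outside the protein are padded with ``'X'`` so the window always
    has exactly ``width`` characters.
    """
    if width % 2 != 1 or width < 1:
        raise ValueError(f"window width must be a positive odd integer, got {width}")
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    half = width // 2
    i = position - 1  # 0-based centre
    left = sequence[max(0, i - half): i]
    right = sequence[i + 1: i + 1 + half]
    return PAD * (half - len(left)) + left + sequence[i] + right + PAD * (half - len(right))


@dataclass(frozen=True)
class PhosphoSite:
    """One phospho-acceptor residue on a protein.

    ``position`` is 1-based (site names like ``S391`` index the protein this
    way). ``window`` is an odd-width flanking sequence centred on the acceptor,
    'X'-padded at the termini. ``loc_prob`` is the phosphate localization
    probability in [0, 1].
    """

    site_id: str
    protein_id: str
    residue: str
    position: int
    window: str
    loc_prob: float = 1.0

    def validate(self, width: int | None = None) -> None:
        if self.residue not in ACCEPTORS:
            raise ValidationError(
                f"site {self.site_id}: residue {self.residue!r} is not one of S/T/Y"
            )
        w = len(self.window)
        if w % 2 != 1 or (width is not None and w != width):
            raise ValidationError(
                f"site {self.site_id}: window length {w} is not the configured odd width"
            )
        if self.window[w // 2] != self.residue:
            raise ValidationError(
                f"site {self.site_id}: window centre {self.window[w // 2]!r} "
                f"!= residue {self.residue!r}"
            )
        if self.position < 1:
            raise ValidationError(f"site {self.site_id}: position must be >= 1")
        if not 0.0 <= self.loc_prob <= 1.0:
            raise ValidationError(
                f"site {self.site_id}: loc_prob {self.loc_prob} outside [0, 1]"
            )
        bad = set(self.window) - set(RESIDUES) - {PAD}
        if bad:
            raise ValidationError(
                f"site {self.site_id}: window contains non-residue characters {sorted(bad)}"
            )

    @staticmethod
    def make_site_id(protein_id: str, residue: str, position: int) -> str:
        return f"{protein_id}_{residue}{position}"


@dataclass
class Design:
    """Channel layout: one row per (channel, fraction) with condition/replicate.

    Channel ids must be unique within a fraction; statistical operations
    require at least two channels per condition per fraction.
    """

    table: pd.DataFrame  # columns: channel_id, condition, replicate, fraction

    REQUIRED = ("channel_id", "condition", "replicate", "fraction")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def validate(self, for_stats: bool = False) -> None:
        t = self.table
        bad_cond = set(t["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown conditions in design: {sorted(bad_cond)}")
        bad_frac = set(t["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise ValidationError(f"unknown fractions in design: {sorted(bad_frac)}")
        for frac, sub in t.groupby("fraction"):
            if sub["channel_id"].duplicated().any():
                dups = sub.loc[sub["channel_id"].duplicated(), "channel_id"].tolist()
                raise ValidationError(
                    f"duplicate channel ids in fraction {frac}: {dups}"
                )
            if for_stats:
                counts = sub.groupby("condition")["channel_id"].count()
                for cond in CONDITIONS:
                    if counts.get(cond, 0) < 2:
                        raise ValidationError(
                            f"fraction {frac}: condition {cond} has "
                            f"{counts.get(cond, 0)} channels (need >= 2)"
                        )

    def channels(self, fraction: str, condition: str | None = None) -> list[str]:
        t = self.table
        sel = t["fraction"] == fraction
        if condition is not None:
            sel &= t["condition"] == condition
        return t.loc[sel, "channel_id"].tolist()


@dataclass
class QuantTable:
    """Rows × channels matrix of intensities with a scale tag.

    ``values`` is a DataFrame indexed by row id (site or protein ids) with one
    column per channel. Raw-scale values are non-negative where present;
    missing values are NaN, never zero.
    """

    values: pd.DataFrame
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("raw", "glog"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate row ids: {dups[:5]}")
        if self.scale_tag == "raw":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=np.inf) < 0:
                raise ValidationError("raw intensities must be non-negative")

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    def subset(self, channels: list[str]) -> "QuantTable":
        return QuantTable(self.values[channels].copy(), self.scale_tag)


@dataclass
class GOAnnotation:
    """Protein → GO-term membership and term names."""

    protein_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def restrict_to(self, universe: set[str]) -> "GOAnnotation":
        """Intersect annotations with a protein universe."""
        kept = {p: set(ts) for p, ts in self.protein_to_terms.items() if p in universe}
        return GOAnnotation(kept, dict(self.term_names))

    def term_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {}
        for protein, terms in self.protein_to_terms.items():
            for t in terms:
                members.setdefault(t, set()).add(protein)
        return members
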