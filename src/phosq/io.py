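"""Readers and writers for every table/format the pipeline touches.

All tables are tab-separated text with a header row. Floats are written with
12 significant digits so write→read round-trips are exact to that precision.
Missing intensities are empty cells and come back as NaN (never zero).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    RESIDUES,
    Design,
    FormatError,
    GOAnnotation,
    PhosphoSite,
    QuantTable,
    ValidationError,
)

log = logging.getLogger(__name__)

SITE_META_COLUMNS = ["site_id", "protein_id", "residue", "position", "window", "loc_prob"]

_FLOAT_FMT = "%.12g"


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"channel_id": str})
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"{path}: empty or header-less file") from e


def _write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def read_design(path) -> Design:
    df = _read_tsv(path)
    design = Design(df)
    design.validate()
    return design


def write_design(design: Design, path) -> None:
    _write_tsv(design.table, path)


# ---------------------------------------------------------------------------
# site / protein quantification tables
# ---------------------------------------------------------------------------

def read_site_table(
    path, design: Design, *, fraction: str = "phospho", window_width: int | None = None
) -> tuple[list[PhosphoSite], QuantTable]:
    """Read a phospho-site quantification table.

    Rows violating per-site invariants (window/residue mismatch, bad
    position or localization probability) are rejected with row-numbered
    diagnostics emitted through the module logger; structural problems
    (missing columns, duplicate ids, negative intensities) raise.
    """
    df = _read_tsv(path)
    missing = [c for c in SITE_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    channels = design.channels(fraction)
    missing_ch = [c for c in channels if c not in df.columns]
    if missing_ch:
        raise FormatError(f"{path}: missing intensity columns {missing_ch}")

    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValidationError(f"{path}: duplicate site ids {dups[:5]}")
    inten = df[channels].astype(float)
    if (inten.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative intensities present")

    sites: list[PhosphoSite] = []
    keep: list[int] = []
    diagnostics: list[str] = []
    for i, row in df.iterrows():
        site = PhosphoSite(
            site_id=str(row["site_id"]),
            protein_id=str(row["protein_id"]),
            residue=str(row["residue"]),
            position=int(row["position"]),
            window=str(row["window"]),
            loc_prob=float(row["loc_prob"]),
        )
        try:
            site.validate(width=window_width)
        except ValidationError as e:
            diagnostics.append(f"row {i + 2}: {e}")  # +2: header line, 1-based
            continue
        sites.append(site)
        keep.append(i)
    for d in diagnostics:
        log.warning("%s: rejected %s", path, d)

    values = inten.loc[keep]
    values.index = pd.Index(df.loc[keep, "site_id"], name="site_id")
    table = QuantTable(values, scale_tag="raw")
    table.validate()
    return sites, table


def write_site_table(sites: list[PhosphoSite], table: QuantTable, path) -> None:
    meta = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "protein_id": s.protein_id,
                "residue": s.residue,
                "position": s.position,
                "window": s.window,
                "loc_prob": s.loc_prob,
            }
            for s in sites
        ]
    )
    df = meta.merge(
        table.values.reset_index().rename(columns={"index": "site_id"}), on="site_id"
    )
    _write_tsv(df, path)


def read_protein_table(path, design: Design, *, fraction: str = "flowthrough") -> QuantTable:
    df = _read_tsv(path)
    if "protein_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'protein_id'")
    channels = design.channels(fraction)
    missing_ch = [c for c in channels if c not in df.columns]
    if missing_ch:
        raise FormatError(f"{path}: missing intensity columns {missing_ch}")
    if df["protein_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate protein ids")
    values = df[channels].astype(float)
    values.index = pd.Index(df["protein_id"], name="protein_id")
    table = QuantTable(values, scale_tag="raw")
    table.validate()
    return table


def write_protein_table(table: QuantTable, path) -> None:
    df = table.values.reset_index()
    df = df.rename(columns={df.columns[0]: "protein_id"})
    _write_tsv(df, path)


# ---------------------------------------------------------------------------
# generic results tables
# ---------------------------------------------------------------------------

def write_results(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write any result table with a deterministic column order.

    Columns are written in the DataFrame's own order; floats carry 12
    significant digits so a read-back equals the written values to that
    precision.
    """
    _write_tsv(df.reset_index(drop=True), path, header_lines)


def read_results(path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# annotations & sequences
# ---------------------------------------------------------------------------

def read_annotations(path) -> GOAnnotation:
    """Read a protein→term table (columns: protein_id, term_id[, term_name])."""
    df = _read_tsv(path)
    for col in ("protein_id", "term_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ann = GOAnnotation()
    has_names = "term_name" in df.columns
    for row in df.itertuples(index=False):
        ann.protein_to_terms.setdefault(str(row.protein_id), set()).add(str(row.term_id))
        if has_names and isinstance(row.term_name, str):
            ann.term_names[str(row.term_id)] = row.term_name
    return ann


def write_annotations(ann: GOAnnotation, path) -> None:
    rows = [
        {"protein_id": p, "term_id": t, "term_name": ann.term_names.get(t, "")}
        for p in sorted(ann.protein_to_terms)
        for t in sorted(ann.protein_to_terms[p])
    ]
    _write_tsv(pd.DataFrame(rows, columns=["protein_id", "term_id", "term_name"]), path)


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences; ids are the first whitespace token of the header."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set(RESIDUES)
        if bad:
            raise ValidationError(
                f"{path}: record {record.id!r} contains non-residue characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    return sequences
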