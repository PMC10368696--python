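"""Domain types, window extraction, and table round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phosq import (
    Design,
    FormatError,
    PhosphoSite,
    QuantTable,
    ValidationError,
    bh_adjust,
    extract_window,
)
from phosq import io as pio
from phosq.datamodel import RESIDUES
from phosq.simulate import SimConfig, simulate_experiment


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def test_window_center_matches_direct_string_indexing():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list(RESIDUES), 600))
    w = extract_window(seq, 391, width=15)
    assert len(w) == 15
    assert w[7] == seq[390]  # 1-based position 391
    assert w == seq[383:398]


@given(
    pos=st.integers(min_value=1, max_value=40),
    width=st.sampled_from([7, 11, 15]),
)
def test_window_padding_near_termini(pos, width):
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # 40 residues
    w = extract_window(seq, pos, width=width)
    assert len(w) == width
    assert w[width // 2] == seq[pos - 1]
    # padding appears only where the window runs past a terminus
    half = width // 2
    n_left_pad = max(0, half - (pos - 1))
    n_right_pad = max(0, half - (len(seq) - pos))
    assert w.startswith("X" * n_left_pad)
    assert w.endswith("X" * n_right_pad) if n_right_pad else True
    assert w.count("X") == n_left_pad + n_right_pad


def test_window_requires_odd_width_and_valid_position():
    with pytest.raises(ValueError):
        extract_window("ACDEF", 2, width=4)
    with pytest.raises(ValueError):
        extract_window("ACDEF", 6, width=3)


def test_site_invariants():
    good = PhosphoSite("P1_S8", "P1", "S", 8, "AAAAAAASAAAAAAA", 0.9)
    good.validate(width=15)
    with pytest.raises(ValidationError):
        PhosphoSite("P1_S8", "P1", "S", 8, "AAAAAAATAAAAAAA", 0.9).validate()
    with pytest.raises(ValidationError):
        PhosphoSite("P1_S8", "P1", "S", 0, "AAAAAAASAAAAAAA", 0.9).validate()
    with pytest.raises(ValidationError):
        PhosphoSite("P1_S8", "P1", "S", 8, "AAAAAAASAAAAAAA", 1.2).validate()


# ---------------------------------------------------------------------------
# site-table round trip
# ---------------------------------------------------------------------------

@pytest.fixture()
def small_experiment():
    return simulate_experiment(SimConfig(n_proteins=30, seed=3))


def test_site_table_roundtrip(tmp_path, small_experiment):
    sites, phospho, _, design, _, _ = small_experiment
    path = tmp_path / "sites.tsv"
    pio.write_site_table(sites, phospho, path)
    sites2, table2 = pio.read_site_table(path, design)
    assert [s.site_id for s in sites2] == [s.site_id for s in sites]
    assert sites2[0] == sites[0]
    # values identical to 12 significant digits, NaN pattern preserved
    a, b = phospho.values.to_numpy(), table2.values.to_numpy()
    assert np.array_equal(np.isnan(a), np.isnan(b))
    np.testing.assert_allclose(a[~np.isnan(a)], b[~np.isnan(b)], rtol=1e-11)


def test_blank_cell_read_as_missing(tmp_path, small_experiment):
    sites, phospho, _, design, _, _ = small_experiment
    values = phospho.values.copy()
    values.iloc[1, 2] = np.nan
    pio.write_site_table(sites, QuantTable(values, "raw"), tmp_path / "s.tsv")
    text = (tmp_path / "s.tsv").read_text()
    assert "\t\t" in text or "\t\n" in text  # a genuinely empty cell on disk
    _, table2 = pio.read_site_table(tmp_path / "s.tsv", design)
    assert np.isnan(table2.values.iloc[1, 2])


def test_invalid_row_rejected_with_diagnostic(tmp_path, small_experiment, caplog):
    sites, phospho, _, design, _, _ = small_experiment
    path = tmp_path / "sites.tsv"
    pio.write_site_table(sites, phospho, path)
    lines = path.read_text().splitlines()
    # corrupt the window centre of the first data row
    fields = lines[1].split("\t")
    w = list(fields[4])
    w[len(w) // 2] = "G"
    fields[4] = "".join(w)
    lines[1] = "\t".join(fields)
    path.write_text("\n".join(lines) + "\n")
    with caplog.at_level("WARNING"):
        sites2, table2 = pio.read_site_table(path, design)
    assert len(sites2) == len(sites) - 1
    assert any("row 2" in rec.message for rec in caplog.records)


def test_structural_errors_raise(tmp_path, small_experiment):
    sites, phospho, _, design, _, _ = small_experiment
    path = tmp_path / "sites.tsv"
    pio.write_site_table(sites, phospho, path)
    df = pd.read_csv(path, sep="\t")
    df.drop(columns=["window"]).to_csv(tmp_path / "nocol.tsv", sep="\t", index=False)
    with pytest.raises(FormatError):
        pio.read_site_table(tmp_path / "nocol.tsv", design)
    dup = pd.concat([df, df.iloc[[0]]])
    dup.to_csv(tmp_path / "dup.tsv", sep="\t", index=False)
    with pytest.raises(ValidationError):
        pio.read_site_table(tmp_path / "dup.tsv", design)
    neg = df.copy()
    neg.iloc[0, 6] = -5.0
    neg.to_csv(tmp_path / "neg.tsv", sep="\t", index=False)
    with pytest.raises(ValidationError):
        pio.read_site_table(tmp_path / "neg.tsv", design)


# ---------------------------------------------------------------------------
# results writer
# ---------------------------------------------------------------------------

def test_write_results_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    p = np.sort(rng.uniform(size=10))
    df = pd.DataFrame({
        "site_id": [f"P{i}_S{i}" for i in range(10)],
        "log2fc_raw": rng.normal(size=10),
        "p": p,
        "q": bh_adjust(p),
    })
    pio.write_results(df, tmp_path / "r.tsv")
    back = pio.read_results(tmp_path / "r.tsv")
    assert list(back.columns) == list(df.columns)
    np.testing.assert_allclose(back["log2fc_raw"], df["log2fc_raw"], rtol=1e-11)
    # q regenerated from the stored p matches the stored q
    np.testing.assert_allclose(bh_adjust(back["p"].to_numpy()), back["q"], rtol=1e-9)


def test_write_results_empty_gives_header_only(tmp_path):
    df = pd.DataFrame(columns=["site_id", "p", "q"])
    pio.write_results(df, tmp_path / "empty.tsv")
    lines = (tmp_path / "empty.tsv").read_text().splitlines()
    assert lines == ["site_id\tp\tq"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_read_fasta(tmp_path):
    (tmp_path / "a.fa").write_text(">P1 desc here\nacdef\nGHIKL\n>P2\nMNPQR\n")
    seqs = pio.read_fasta(tmp_path / "a.fa")
    assert seqs == {"P1": "ACDEFGHIKL", "P2": "MNPQR"}


def test_read_fasta_errors(tmp_path):
    (tmp_path / "dup.fa").write_text(">P1\nACDEF\n>P1\nACDEF\n")
    with pytest.raises(ValidationError):
        pio.read_fasta(tmp_path / "dup.fa")
    (tmp_path / "bad.fa").write_text(">P1\nAC1EF\n")
    with pytest.raises(ValidationError, match="P1"):
        pio.read_fasta(tmp_path / "bad.fa")


def test_fasta_window_extraction_oracle(tmp_path):
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list(RESIDUES), 600))
    (tmp_path / "p.fa").write_text(f">PROT\n{seq}\n")
    seqs = pio.read_fasta(tmp_path / "p.fa")
    w = extract_window(seqs["PROT"], 391, width=15)
    assert len(w) == 15 and w[7] == seq[390]


def test_design_validation():
    rows = [
        dict(channel_id=f"{c}_{r}", condition=c, replicate=r, fraction=f)
        for f in ("phospho", "flowthrough")
        for c in ("fed", "deprived")
        for r in (1, 2, 3)
    ]
    Design(pd.DataFrame(rows)).validate(for_stats=True)
    single = Design(pd.DataFrame([r for r in rows if not (r["condition"] == "fed" and r["replicate"] > 1)]))
    with pytest.raises(ValidationError):
        single.validate(for_stats=True)
    dup = Design(pd.DataFrame(rows + [rows[0]]))
    with pytest.raises(ValidationError):
        dup.validate()
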