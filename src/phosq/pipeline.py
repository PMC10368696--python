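"""End-to-end orchestration: config, staging, logging, reproducible runs.

A run executes the analysis in the order the science dictates: variance-
stabilizing normalization per fraction → site-wise moderated statistics →
protein adjustment of fold changes from the flow-through → kinase-motif and
pathway group tests → GO over-representation. Inputs either come from the
synthetic generator (``sim:`` block) or from files (``inputs:`` block).

All randomness flows from the single config seed; rerunning with the same
config produces bitwise-identical numeric tables. Every table carries a
provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .datamodel import ConfigError, Design, GOAnnotation, QuantTable, ValidationError
from .go import build_query_sets, hypergeom_enrich
from .motifs import assign_groups, default_motifs, motif_shift_test, read_motif_table
from .normalize import fit_normalization, glog_transform
from .simulate import SimConfig, config_from_dict, simulate_experiment
from .stats import (
    adjust_by_protein,
    moderated_test,
    pathway_group_test,
    protein_fold_changes,
)

_KNOWN_TOP_KEYS = {"seed", "outdir", "sim", "inputs", "thresholds", "flags"}


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "phosq_run"
    sim: SimConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    loc_prob_threshold: float = 0.75
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    motif_comparison: str = "total"
    use_adjusted_fc: bool = True
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        problems, warnings_ = _check_config_dict(d)
        if problems:
            raise ConfigError("; ".join(problems))
        thresholds = d.get("thresholds", {}) or {}
        flags = d.get("flags", {}) or {}
        sim = None
        if d.get("sim") is not None:
            sim_d = dict(d["sim"])
            sim_d.setdefault("seed", d.get("seed", 0))
            sim = config_from_dict(sim_d)
        cfg = cls(
            seed=int(d.get("seed", 0)),
            outdir=str(d.get("outdir", "phosq_run")),
            sim=sim,
            inputs=dict(d.get("inputs", {}) or {}),
            loc_prob_threshold=float(thresholds.get("loc_prob", 0.75)),
            p_threshold=float(thresholds.get("p", 0.05)),
            q_threshold=float(thresholds.get("q", 0.05)),
            motif_comparison=str(flags.get("motif_comparison", "total")),
            use_adjusted_fc=bool(flags.get("use_adjusted_fc", True)),
            raw=d,
        )
        cfg.warnings = warnings_
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                d = yaml.safe_load(fh) or {}
            except yaml.YAMLError as e:
                mark = getattr(e, "problem_mark", None)
                line = f" at line {mark.line + 1}" if mark else ""
                raise ConfigError(f"cannot parse {path}{line}: {e}") from e
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def config_hash(self) -> str:
        # hash the scientific configuration only: the same analysis run into
        # a different directory must produce byte-identical tables
        scientific = {k: v for k, v in self.raw.items() if k != "outdir"}
        canonical = json.dumps(scientific, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _check_config_dict(d: dict) -> tuple[list[str], list[str]]:
    problems: list[str] = []
    warnings_: list[str] = []
    for key in d:
        if key not in _KNOWN_TOP_KEYS:
            warnings_.append(f"unknown top-level key {key!r} ignored")
    thresholds = d.get("thresholds", {}) or {}
    for name in ("loc_prob", "p", "q"):
        if name in thresholds:
            v = thresholds[name]
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                problems.append(f"threshold {name}={v!r} must lie in [0, 1]")
    flags = d.get("flags", {}) or {}
    if "motif_comparison" in flags and flags["motif_comparison"] not in ("total", "complement"):
        problems.append(f"flags.motif_comparison must be 'total' or 'complement'")
    if d.get("sim") is None and not d.get("inputs"):
        problems.append("config needs either a 'sim' block or an 'inputs' block")
    inputs = d.get("inputs", {}) or {}
    if d.get("sim") is None:
        for required in ("site_table", "protein_table", "design"):
            if required not in inputs:
                problems.append(f"inputs.{required} is required when not simulating")
    for name, path in inputs.items():
        if path and not Path(path).exists():
            problems.append(f"inputs.{name}: file not found: {path}")
    if d.get("sim") is not None:
        try:
            sim_d = dict(d["sim"])
            sim_d.setdefault("seed", d.get("seed", 0))
            config_from_dict(sim_d).validate()
        except (ConfigError, TypeError) as e:
            problems.append(f"sim block invalid: {e}")
    return problems, warnings_


def validate_config(path) -> tuple[list[str], list[str]]:
    """Return (violations, warnings) for a config file; empty violations = valid."""
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh) or {}
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            return [f"cannot parse {path}{line}"], []
    if not isinstance(d, dict):
        return [f"{path}: config must be a mapping"], []
    return _check_config_dict(d)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    On stage failure, tables already written are renamed with a
    ``.partial`` suffix and the error is re-raised with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    written: list[Path] = []
    header = [
        f"phosq {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        pio.write_results(df, path, header_lines=header)
        written.append(path)

    def stage_log(stage: str, n_in: int, n_out: int) -> None:
        log_lines.append(f"{stage}: in={n_in} out={n_out}")

    summary: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                     "version": __version__}
    current_stage = "inputs"
    try:
        # --- inputs --------------------------------------------------------
        truth = None
        if config.sim is not None:
            sites, phospho, flowthrough, design, annotations, truth = simulate_experiment(config.sim)
        else:
            design = pio.read_design(config.inputs["design"])
            sites, phospho = pio.read_site_table(config.inputs["site_table"], design)
            flowthrough = pio.read_protein_table(config.inputs["protein_table"], design)
            annotations = (
                pio.read_annotations(config.inputs["annotations"])
                if config.inputs.get("annotations")
                else GOAnnotation()
            )
        design.validate(for_stats=True)
        stage_log("inputs", len(sites), len(sites))

        # --- localization filter ------------------------------------------
        current_stage = "localization_filter"
        kept = [s for s in sites if s.loc_prob >= config.loc_prob_threshold]
        kept_ids = [s.site_id for s in kept]
        phospho = QuantTable(phospho.values.loc[kept_ids], scale_tag="raw")
        stage_log("localization_filter", len(sites), len(kept))
        sites = kept

        # --- normalization (per fraction) ----------------------------------
        current_stage = "normalization"
        params_ph = fit_normalization(phospho)
        glog_ph = glog_transform(phospho, params_ph)
        params_ft = fit_normalization(flowthrough)
        glog_ft = glog_transform(flowthrough, params_ft)
        emit(params_ph.to_frame(), "normalization_phospho.tsv")
        emit(params_ft.to_frame(), "normalization_flowthrough.tsv")
        stage_log("normalization", len(phospho.row_ids), len(glog_ph.row_ids))

        # --- site statistics ----------------------------------------------
        current_stage = "site_statistics"
        results = moderated_test(glog_ph, design)
        site_to_protein = pd.Series({s.site_id: s.protein_id for s in sites})
        pfc = protein_fold_changes(glog_ft, design)
        results = adjust_by_protein(results, site_to_protein, pfc)
        results.insert(1, "protein_id", results["site_id"].map(site_to_protein))
        emit(results, "site_stats.tsv")
        n_tested = int(results["p"].notna().sum())
        stage_log("site_statistics", len(results), n_tested)
        hyper = results.attrs["ebayes"]
        summary["n_sites"] = len(results)
        summary["n_tested"] = n_tested
        summary["n_significant_p"] = int((results["p"] < config.p_threshold).sum())
        summary["n_significant_q"] = int((results["q"] < config.q_threshold).sum())
        summary["ebayes_d0"] = float(hyper.d0) if np.isfinite(hyper.d0) else "inf"
        summary["ebayes_s0_sq"] = float(hyper.s0_sq)

        fc_col = "log2fc_adj" if config.use_adjusted_fc else "log2fc_raw"
        fc = results.set_index("site_id")[fc_col]

        # --- kinase motif groups -------------------------------------------
        current_stage = "motif_groups"
        motifs = (
            read_motif_table(config.inputs["motif_file"])
            if config.inputs.get("motif_file")
            else default_motifs()
        )
        groups = assign_groups(sites, motifs)
        motif_results = motif_shift_test(fc, groups, comparison=config.motif_comparison)
        emit(motif_results, "motif_results.tsv")
        stage_log("motif_groups", len(motifs), len(motif_results))
        testable = motif_results[motif_results["testable"]]
        if len(testable):
            top = testable.sort_values("p", kind="mergesort").iloc[0]
            summary["top_motif"] = {
                "kinase": str(top["kinase"]), "p": float(top["p"]),
                "median_shift": float(top["median_shift"]),
            }

        # --- pathway group test --------------------------------------------
        current_stage = "pathway_test"
        membership: set[str] = set()
        if truth is not None:
            membership = set(truth.pathway_sites)
        elif config.inputs.get("pathway_sites"):
            membership = {
                line.strip()
                for line in Path(config.inputs["pathway_sites"]).read_text().splitlines()
                if line.strip()
            }
        if membership:
            res = pathway_group_test(fc, membership)
            emit(
                pd.DataFrame([{
                    "label": res.label, "n_in": res.n_in, "n_out": res.n_out,
                    "t": res.statistic, "df": res.df, "p": res.p, "shift": res.shift,
                }]),
                "pathway_test.tsv",
            )
            summary["pathway"] = {"p": res.p, "shift": res.shift, "n_in": res.n_in}
            stage_log("pathway_test", res.n_in + res.n_out, 1)

        # --- GO enrichment --------------------------------------------------
        current_stage = "go_enrichment"
        if annotations.protein_to_terms:
            results_for_go = results
            for direction in ("down", "up"):
                query, universe = build_query_sets(
                    results_for_go, direction, config.p_threshold,
                    use_adjusted_fc=config.use_adjusted_fc,
                )
                if query:
                    enr = hypergeom_enrich(query, universe, annotations)
                    emit(enr, f"go_{direction}.tsv")
                    if len(enr):
                        summary[f"go_top_{direction}"] = {
                            "term_id": str(enr.iloc[0]["term_id"]),
                            "q": float(enr.iloc[0]["q"]),
                        }
                    stage_log(f"go_{direction}", len(universe), len(enr))

        # --- ground-truth comparison (simulation runs only) -----------------
        if truth is not None:
            current_stage = "truth_summary"
            merged = results.merge(
                truth.site_effects.reset_index(), on="site_id", how="left"
            )
            called = merged["q"] < config.q_threshold
            truly = merged["total_log2_effect"] != 0
            n_called = int(called.sum())
            summary["truth"] = {
                "n_called_q": n_called,
                "fdr": float((called & ~truly).sum() / n_called) if n_called else 0.0,
                "sensitivity": float(
                    (called & truly).sum() / truly.sum()) if truly.sum() else 0.0,
            }
    except Exception as e:
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise type(e)(f"stage {current_stage!r}: {e}") from e

    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
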