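"""Ground-truthed synthetic phosphoproteomics experiments.

The generator emulates a 6-plex isobaric-label experiment on egg chambers —
3 well-fed versus 3 nutrient-deprived channels, a TiO2 phospho-enriched
fraction plus its protein-level flow-through — with the statistical
structure the downstream analysis assumes:

* raw reporter intensity of site s in channel c:
      gain_c * (base_s * 2^(effect_s if deprived) * exp(eta)) + offset_c + eps,
  with multiplicative log-normal noise eta ~ N(0, sigma_m^2) and additive
  noise eps ~ N(0, sigma_a^2), truncated at 0;
* flow-through protein intensities generated analogously from protein-level
  effects only;
* a configurable fraction of truly differential sites (log2 effects of
  magnitude ``effect_size_log2``), a pathway group of proteins with coherent
  negative phospho effects, a kinase (CK2 by default) whose matching sites
  receive a positive shift, and protein-level effects planted independently
  of phospho effects so protein adjustment has signal to remove;
* flanking windows drawn from background residue frequencies, except
  motif-seeded sites whose windows are forced to match the kinase consensus;
* intensity-dependent (logistic) missingness;
* GO annotations with one term enriched among the pathway proteins.

A site's phospho-specific effect is ``true_log2_effect``; the total effect
seen in the phospho table is ``true_log2_effect + protein effect`` of its
protein. The single integer seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    ACCEPTORS,
    ConfigError,
    Design,
    GOAnnotation,
    PhosphoSite,
    QuantTable,
)
from .motifs import MotifDef, default_motifs

# Background amino-acid frequencies (Robinson & Robinson vertebrate averages,
# rounded); used for unconstrained window positions.
BACKGROUND_FREQS = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.052, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.065, "W": 0.013, "Y": 0.032,
}

#: acceptor-residue frequencies among phospho-sites (S >> T >> Y)
ACCEPTOR_FREQS = {"S": 0.80, "T": 0.17, "Y": 0.03}


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults encode the experimental design being emulated (3 fed vs 3
    deprived channels, paired phospho and flow-through fractions) and
    planted-signal magnitudes matching the analyses the pipeline runs:
    10% differential sites at |log2 effect| 1.5, a down-regulated pathway
    group (−0.8), an up-shifted CK2 motif group (+0.6), and independent
    protein-level effects (|log2| 1.0 on 5% of proteins).
    """

    n_proteins: int = 500
    mean_sites_per_protein: float = 3.0  # geometric distribution, min 1
    n_per_condition: int = 3
    fraction_differential: float = 0.10
    effect_size_log2: float = 1.5  # magnitude of random differential effects
    effect_size_sd: float = 0.25   # spread of that magnitude
    pathway_n_proteins: int = 25
    pathway_effect_log2: float = -0.8
    motif_kinase: str = "CK2"
    n_motif_sites: int = 100
    motif_effect_log2: float = 0.6
    protein_diff_fraction: float = 0.05
    protein_effect_log2: float = 1.0
    flowthrough_detect_rate: float = 0.9
    sigma_a: float = 20.0   # additive noise sd (raw intensity units)
    sigma_m: float = 0.1    # multiplicative noise sd (natural-log scale)
    gain_range: tuple[float, float] = (0.8, 1.25)
    offset_range: tuple[float, float] = (0.0, 50.0)
    missing_rate: float = 0.05
    base_log10_mean: float = 4.5
    base_log10_sd: float = 0.5
    window_width: int = 15
    loc_prob_low_fraction: float = 0.10  # sites below the usual 0.75 cutoff
    n_go_terms: int = 40
    go_terms_per_protein: float = 3.0  # Poisson mean
    go_background_rate: float = 0.02   # planted term on non-pathway proteins
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "fraction_differential": self.fraction_differential,
            "protein_diff_fraction": self.protein_diff_fraction,
            "flowthrough_detect_rate": self.flowthrough_detect_rate,
            "missing_rate": self.missing_rate,
            "loc_prob_low_fraction": self.loc_prob_low_fraction,
            "go_background_rate": self.go_background_rate,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.sigma_a < 0 or self.sigma_m < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.n_proteins < 1 or self.n_per_condition < 2:
            raise ConfigError("need >= 1 protein and >= 2 channels per condition")
        if self.mean_sites_per_protein < 1:
            raise ConfigError("mean_sites_per_protein must be >= 1")
        if self.window_width % 2 != 1 or self.window_width < 3:
            raise ConfigError("window_width must be an odd integer >= 3")
        if not (self.gain_range[0] > 0 and self.gain_range[1] >= self.gain_range[0]):
            raise ConfigError("gain_range must be positive and ordered")
        if not (self.offset_range[0] >= 0 and self.offset_range[1] >= self.offset_range[0]):
            raise ConfigError("offset_range must be non-negative and ordered")
        if self.pathway_n_proteins + 1 > self.n_proteins:
            raise ConfigError("pathway group larger than protein count")


@dataclass
class GroundTruth:
    """Planted truth for recovery tests.

    ``site_effects['true_log2_effect']`` is the phospho-specific effect;
    ``'total_log2_effect'`` adds the protein-level effect of the site's
    protein (what the phospho table actually shows).
    """

    site_effects: pd.DataFrame  # index site_id: true_log2_effect, total_log2_effect, is_differential, protein_id
    protein_effects: pd.Series  # index protein_id: true protein-level log2 effect
    pathway_proteins: set[str] = field(default_factory=set)
    pathway_sites: set[str] = field(default_factory=set)
    motif_sites: set[str] = field(default_factory=set)
    motif_kinase: str = ""
    enriched_term: str = ""
    term_enriched: dict[str, bool] = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic sub-streams from the one experiment seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def plant_motif_window(
    motif: MotifDef, rng: np.random.Generator, width: int = 15
) -> str:
    """Draw a window matching ``motif``; unconstrained positions use background frequencies."""
    half = width // 2
    if motif.half_span > half:
        raise ConfigError(
            f"motif {motif.kinase} spans {motif.half_span}, window half-width {half}"
        )
    residues = list(BACKGROUND_FREQS)
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    chars = list(rng.choice(residues, size=width, p=probs))
    for off, allowed in motif.offsets.items():
        choices = sorted(allowed)
        chars[half + off] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _random_windows(rng: np.random.Generator, n: int, width: int) -> tuple[list[str], list[str]]:
    """Background windows with phospho-acceptor centres; returns (windows, residues)."""
    half = width // 2
    residues = list(BACKGROUND_FREQS)
    probs = np.array(list(BACKGROUND_FREQS.values()))
    probs = probs / probs.sum()
    flank = rng.choice(residues, size=(n, width), p=probs)
    centres = rng.choice(list(ACCEPTOR_FREQS), size=n, p=list(ACCEPTOR_FREQS.values()))
    flank[:, half] = centres
    return ["".join(row) for row in flank], list(centres)


def _noisy_intensities(
    rng: np.random.Generator,
    base: np.ndarray,
    effects: np.ndarray,
    deprived_mask: np.ndarray,
    gains: np.ndarray,
    offsets: np.ndarray,
    sigma_a: float,
    sigma_m: float,
) -> np.ndarray:
    n, k = len(base), len(gains)
    fold = np.where(deprived_mask[None, :], 2.0 ** effects[:, None], 1.0)
    eta = rng.normal(0.0, sigma_m, size=(n, k))
    eps = rng.normal(0.0, sigma_a, size=(n, k))
    raw = gains[None, :] * (base[:, None] * fold * np.exp(eta)) + offsets[None, :] + eps
    return np.maximum(raw, 0.0)


def _apply_missingness(
    rng: np.random.Generator, values: np.ndarray, rate: float
) -> np.ndarray:
    """Intensity-dependent dropout: lower intensities miss more; mean rate ~= rate."""
    if rate <= 0:
        return values
    flat = values.ravel()
    with np.errstate(divide="ignore"):
        z = -np.log10(np.maximum(flat, 1e-12))
    z = (z - z.mean()) / max(z.std(), 1e-12)
    w = 1.0 / (1.0 + np.exp(-z))  # logistic in -log intensity
    p = np.minimum(rate * w / w.mean(), 0.95)
    drop = rng.random(flat.shape) < p
    out = flat.copy()
    out[drop] = np.nan
    return out.reshape(values.shape)


def make_design(n_per_condition: int = 3) -> Design:
    rows = []
    for fraction in ("phospho", "flowthrough"):
        for cond in ("fed", "deprived"):
            for r in range(1, n_per_condition + 1):
                rows.append(
                    dict(channel_id=f"{cond}_{r}", condition=cond,
                         replicate=r, fraction=fraction)
                )
    return Design(pd.DataFrame(rows))


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[PhosphoSite], QuantTable, QuantTable, Design, GOAnnotation, GroundTruth]:
    """Generate one complete synthetic experiment with ground truth."""
    config.validate()
    seed = config.seed

    # --- proteins and site counts -----------------------------------------
    rng_layout = _rng(seed, 0)
    n_prot = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n_prot + 1)]
    p_geom = 1.0 / config.mean_sites_per_protein
    sites_per_protein = rng_layout.geometric(p_geom, size=n_prot)
    n_sites = int(sites_per_protein.sum())

    site_protein = np.repeat(np.arange(n_prot), sites_per_protein)
    seq_lengths = rng_layout.integers(200, 1200, size=n_prot)
    positions = (rng_layout.random(n_sites) * (seq_lengths[site_protein] - 20) + 10).astype(int)

    # --- windows ----------------------------------------------------------
    rng_win = _rng(seed, 1)
    windows, residues = _random_windows(rng_win, n_sites, config.window_width)

    # --- planted structure -------------------------------------------------
    rng_truth = _rng(seed, 2)
    pathway_prot_idx = rng_truth.choice(n_prot, size=config.pathway_n_proteins, replace=False)
    pathway_prot_set = set(pathway_prot_idx.tolist())
    pathway_site_mask = np.isin(site_protein, pathway_prot_idx)

    motif = next((m for m in default_motifs() if m.kinase == config.motif_kinase), None)
    if motif is None:
        raise ConfigError(f"unknown motif kinase {config.motif_kinase!r}")
    non_pathway_sites = np.flatnonzero(~pathway_site_mask)
    n_motif = min(config.n_motif_sites, len(non_pathway_sites))
    motif_site_idx = rng_truth.choice(non_pathway_sites, size=n_motif, replace=False)
    for i in motif_site_idx:
        windows[i] = plant_motif_window(motif, rng_truth, config.window_width)
        residues[i] = windows[i][config.window_width // 2]

    # random differential sites outside the planted groups
    effects = np.zeros(n_sites)
    effects[pathway_site_mask] = config.pathway_effect_log2
    effects[motif_site_idx] = config.motif_effect_log2
    free = np.flatnonzero(~pathway_site_mask)
    free = free[~np.isin(free, motif_site_idx)]
    n_diff = int(round(config.fraction_differential * n_sites))
    n_diff = min(n_diff, len(free))
    diff_idx = rng_truth.choice(free, size=n_diff, replace=False)
    signs = rng_truth.choice([-1.0, 1.0], size=n_diff)
    mags = np.abs(rng_truth.normal(config.effect_size_log2, config.effect_size_sd, size=n_diff))
    effects[diff_idx] = signs * mags

    # independent protein-level effects
    n_prot_diff = int(round(config.protein_diff_fraction * n_prot))
    prot_diff_idx = rng_truth.choice(n_prot, size=n_prot_diff, replace=False)
    protein_effects = np.zeros(n_prot)
    protein_effects[prot_diff_idx] = (
        rng_truth.choice([-1.0, 1.0], size=n_prot_diff) * config.protein_effect_log2
    )
    total_effects = effects + protein_effects[site_protein]

    # --- identities --------------------------------------------------------
    rng_meta = _rng(seed, 3)
    loc_prob = np.where(
        rng_meta.random(n_sites) < config.loc_prob_low_fraction,
        rng_meta.uniform(0.30, 0.75, size=n_sites),
        rng_meta.uniform(0.75, 1.0, size=n_sites),
    )
    sites: list[PhosphoSite] = []
    used_ids: set[str] = set()
    for i in range(n_sites):
        pid = protein_ids[site_protein[i]]
        sid = PhosphoSite.make_site_id(pid, residues[i], int(positions[i]))
        while sid in used_ids:  # two sampled positions may collide
            positions[i] += 1
            sid = PhosphoSite.make_site_id(pid, residues[i], int(positions[i]))
        used_ids.add(sid)
        sites.append(
            PhosphoSite(sid, pid, residues[i], int(positions[i]), windows[i],
                        float(np.round(loc_prob[i], 4)))
        )
    site_ids = [s.site_id for s in sites]

    # --- design and channel distortions ------------------------------------
    design = make_design(config.n_per_condition)
    k = 2 * config.n_per_condition
    deprived_mask = np.array([False] * config.n_per_condition + [True] * config.n_per_condition)
    channel_order = [f"fed_{r}" for r in range(1, config.n_per_condition + 1)] + \
                    [f"deprived_{r}" for r in range(1, config.n_per_condition + 1)]

    # --- phospho fraction ---------------------------------------------------
    rng_ph = _rng(seed, 4)
    gains_ph = rng_ph.uniform(*config.gain_range, size=k)
    offs_ph = rng_ph.uniform(*config.offset_range, size=k)
    base_sites = 10.0 ** rng_ph.normal(config.base_log10_mean, config.base_log10_sd, size=n_sites)
    ph_values = _noisy_intensities(
        rng_ph, base_sites, total_effects, deprived_mask,
        gains_ph, offs_ph, config.sigma_a, config.sigma_m,
    )
    ph_values = _apply_missingness(_rng(seed, 5), ph_values, config.missing_rate)
    phospho = QuantTable(
        pd.DataFrame(ph_values, index=pd.Index(site_ids, name="site_id"),
                     columns=channel_order),
        scale_tag="raw",
    )

    # --- flow-through fraction ---------------------------------------------
    rng_ft = _rng(seed, 6)
    gains_ft = rng_ft.uniform(*config.gain_range, size=k)
    offs_ft = rng_ft.uniform(*config.offset_range, size=k)
    base_prot = 10.0 ** rng_ft.normal(
        config.base_log10_mean + 0.5, config.base_log10_sd, size=n_prot
    )
    detected = rng_ft.random(n_prot) < config.flowthrough_detect_rate
    ft_values = _noisy_intensities(
        rng_ft, base_prot, protein_effects, deprived_mask,
        gains_ft, offs_ft, config.sigma_a, config.sigma_m,
    )
    ft_values = _apply_missingness(_rng(seed, 7), ft_values, config.missing_rate)
    ft_index = [protein_ids[i] for i in np.flatnonzero(detected)]
    flowthrough = QuantTable(
        pd.DataFrame(ft_values[detected], index=pd.Index(ft_index, name="protein_id"),
                     columns=channel_order),
        scale_tag="raw",
    )

    # --- GO annotations -----------------------------------------------------
    rng_go = _rng(seed, 8)
    terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    enriched_term = terms[0]
    ann = GOAnnotation(term_names={
        t: ("cytoskeleton organization (planted)" if t == enriched_term else f"synthetic process {i}")
        for i, t in enumerate(terms)
    })
    for i, pid in enumerate(protein_ids):
        n_terms = min(rng_go.poisson(config.go_terms_per_protein), config.n_go_terms - 1)
        chosen = set(rng_go.choice(terms[1:], size=n_terms, replace=False)) if n_terms else set()
        if i in pathway_prot_set or rng_go.random() < config.go_background_rate:
            chosen.add(enriched_term)
        if chosen:
            ann.protein_to_terms[pid] = chosen

    # --- ground truth -------------------------------------------------------
    truth = GroundTruth(
        site_effects=pd.DataFrame(
            {
                "true_log2_effect": effects,
                "total_log2_effect": total_effects,
                "is_differential": effects != 0.0,
                "protein_id": [protein_ids[j] for j in site_protein],
            },
            index=pd.Index(site_ids, name="site_id"),
        ),
        protein_effects=pd.Series(protein_effects, index=pd.Index(protein_ids, name="protein_id"),
                                  name="protein_log2_effect"),
        pathway_proteins={protein_ids[i] for i in pathway_prot_set},
        pathway_sites={site_ids[i] for i in np.flatnonzero(pathway_site_mask)},
        motif_sites={site_ids[i] for i in motif_site_idx},
        motif_kinase=config.motif_kinase,
        enriched_term=enriched_term,
        term_enriched={t: (t == enriched_term) for t in terms},
    )
    return sites, phospho, flowthrough, design, ann, truth


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["gain_range"] = list(d["gain_range"])
    d["offset_range"] = list(d["offset_range"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "gain_range" in d:
        d["gain_range"] = tuple(d["gain_range"])
    if "offset_range" in d:
        d["offset_range"] = tuple(d["offset_range"])
    unknown = set(d) - {f.name for f in SimConfig.__dataclass_fields__.values()}
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**d)
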