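# Default end-to-end run on a synthetic experiment (6-plex, 3 fed vs 3 deprived).
seed: 42
outdir: results/run_default
sim:
  n_proteins: 667           # ~2000 phospho-sites at 3 sites/protein
  fraction_differential: 0.10
  effect_size_log2: 1.5
  pathway_n_proteins: 25
  pathway_effect_log2: -0.8
  motif_kinase: CK2
  n_motif_sites: 100
  motif_effect_log2: 0.6
  sigma_a: 20.0
  sigma_m: 0.1
  missing_rate: 0.05
thresholds:
  loc_prob: 0.75
  p: 0.05
  q: 0.05
flags:
  motif_comparison: total
  use_adjusted_fc: true
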