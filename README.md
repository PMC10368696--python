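# phosq

Quantitative phosphoproteomics and mRNP-granule image statistics for
nutritional-stress experiments in the *Drosophila* female germline.

When flies are deprived of dietary protein, egg chambers arrest oogenesis,
microtubules condense at the cell cortex, and maternal mRNAs (such as
*oskar*) aggregate into large P-bodies. The signalling upstream of this
response is phosphorylation-driven: comparing the phosphoproteome of
well-fed and nutrient-deprived egg chambers in a 6-plex isobaric-label
(TMT) experiment — 3 fed vs 3 deprived channels, with a TiO₂
phospho-enriched fraction and its flow-through as a protein-level
reference — reveals which phospho-sites, kinase motifs and pathways
respond to nutritional stress. `phosq` implements that entire analysis as
a tested, reusable pipeline, together with the imaging statistics used to
quantify the cellular phenotype (P-body granularity and cortical boundary
profiles), driven end-to-end by a synthetic-data generator with ground
truth so that every stage is verifiable without any external download.

## What it computes

For site *i* with reporter intensities *x_ic* in channels *c*:

1. **Variance-stabilizing normalization.** Channels are calibrated by a
   robust affine fit (median-ratio scale *b_c*, low-quantile offset *a_c*)
   and transformed with the generalized log
   *h(x) = arsinh((x − a_c)/(2 b_c λ)) / ln 2*, where the dataset-level
   scale λ is estimated from the additive–multiplicative mean–variance
   relation σ²(μ) = σ_a² + σ_m² μ². Differences of *h* are log₂-calibrated
   fold changes.
2. **Moderated differential statistics.** Per-site residual variances s²
   (pooled over fed/deprived) are shrunk toward an empirical-Bayes prior
   (d₀, s₀²) fitted by digamma/trigamma moment matching of log s²;
   the moderated statistic
   *t = Δh̄ / (s̃ √(1/n₁+1/n₂))* with *s̃² = (d₀s₀² + ds²)/(d₀+d)* is
   referred to a t distribution on d₀+d degrees of freedom, with BH
   correction across all tested sites.
3. **Protein adjustment.** Protein fold changes from the flow-through
   fraction are subtracted from the matched phospho-site fold changes,
   separating phosphorylation changes from protein-abundance changes.
4. **Group tests.** Welch two-sample t for pathway site groups (e.g.
   insulin/TOR membership); Wilcoxon rank-sum of kinase consensus-motif
   groups (e.g. CK2: X-(S/T)-X-X-(D/E)) against the total site population,
   BH across kinases.
5. **GO over-representation.** Upper-tail hypergeometric test of each term
   among proteins carrying significantly regulated sites, against the
   quantified-protein universe, BH across terms.
6. **Imaging.** P-body *granularity* = segmented granule area / oocyte
   area (Otsu threshold within the oocyte mask, 8-connected components,
   small-object removal), compared between groups by Welch t; and the
   normalized mean-fluorescence *boundary profile* across a cell–cell
   boundary.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
experiment (~2000 sites on 667 proteins, 10% differential at |log₂| 1.5,
a down-regulated 25-protein pathway group at −0.8, 100 CK2-motif sites
up-shifted +0.6):

```bash
python analysis/01_simulate.py --seed 42
python analysis/02_normalize.py
python analysis/03_differential_sites.py
python analysis/04_group_tests.py
python analysis/05_go_enrichment.py
python analysis/06_imaging.py
python analysis/07_calibration.py
```

which prints (seed 42):

```
simulated 1973 phospho-sites on 667 proteins (390 truly differential, ...)
phospho: ... sd-vs-mean slope 0.3053 (raw) -> 0.0015 (glog), ratio 0.005
tested 1749 sites; shrinkage prior d0 = 54.4, s0^2 = 0.0191
significant: 487 at p<0.05, 437 at q<0.05
against ground truth: empirical FDR 0.037, sensitivity 0.988
pathway group (85 sites): shift -0.751 log2 units, Welch t = -33.11, p = 3.76e-78
  CK2        n= 279 shift +0.110 p=3e-10 q=3.9e-09
down: ... top term GO:0000001 (cytoskeleton organization (planted)): k/K = 27/34, q = 6.22e-10
granularity fed 0.048 vs stressed 0.195: Welch t = 17.30, df = 36.3, p = 4.02e-19
type-I error (null, 4936 sites): 0.0456
variance prior recovery: d0 = 4.04 (true 4), s0^2 = 0.0401 (true 0.04)
```

The normalization flattens the sd-vs-mean trend by ~200×; the moderated
test holds its nominal type-I error and FDR while recovering the planted
pathway (negative shift), the CK2 motif group (positive shift), and the
planted GO term as the top-ranked enrichment.

The same stages are available as a CLI
(`phosq simulate|normalize|diff|motifs|pathway|go|imaging|run-all|validate`);
`phosq run-all --config configs/default.yaml` executes everything into one
run directory with provenance headers and a JSON summary, bitwise
reproducible per seed.

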