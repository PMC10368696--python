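# Methods

This note documents the statistical models, defaults, and design decisions
behind `phosq`, and what the synthetic benchmarks do and do not establish
about real data.

## Data model

The pipeline starts from quantified tables, not spectra. A phospho-site is
identified by protein, residue (S/T/Y) and 1-based position (so the common
"S391"-style names index the protein sequence directly), carries an
odd-width flanking window (default 15, 'X'-padded at termini) and a
localization probability in [0, 1]. Reporter intensities are non-negative
reals with missing values encoded as empty cells and propagated as missing —
never zero-imputed, since a planted zero at the raw scale would be a strong
outlier after the glog transform and would bias both the calibration and
the variance shrinkage. Sites below a localization-probability cutoff
(default 0.75, configurable) are excluded before statistics; the cutoff is
a conventional choice, exposed rather than hard-coded.

## Normalization

The error model is the standard additive–multiplicative one for reporter
intensities: channel *c* observes
`x = gain_c · μ · exp(η) + offset_c + ε` with `η ~ N(0, σ_m²)`,
`ε ~ N(0, σ_a²)`. Calibration is deterministic and closed-form rather than
a full maximum-likelihood fit of the variance-stabilization model — the
model class is the same, but there is no hidden iteration, so a rerun is
bitwise reproducible and each estimator can be tested in isolation:

* scale `b_c`: median ratio to the reference channel over complete rows,
  alternated (12 iterations, geometric convergence) with
* offset `a_c`: the difference of low quantiles (default 5%) between the
  channel and the scaled reference, computed after trimming rows whose
  log-ratio deviates from the median by more than 6 MAD. The trim matters:
  differential rows that move *down* would otherwise populate the low
  quantile and corrupt the offset.
* glog scale λ: row variance is regressed on squared row mean with a
  repeated-median (Siegel) fit, giving `σ_a²` (intercept) and `σ_m²`
  (slope); `λ = σ_a/(2σ_m)`, floored at a small positive value. The
  transform `h(x) = arsinh((x − a_c)/(2 b_c λ))/ln 2` then has
  approximately constant variance and log₂ asymptotics, so differences of
  `h` read as log₂ fold changes.

Fractions (phospho-enriched vs flow-through) are normalized separately:
they are distinct LC-MS analyses with their own channel distortions.
Whether the original study normalized them jointly is not documented;
separate fits are the conservative choice and are flagged here.

## Site-wise statistics

Fold change is the difference of condition means on the glog scale
(deprived − fed). Per-site variances are pooled over both conditions with
`d = n₁ + n₂ − 2` degrees of freedom; a site needs at least two finite
values per condition, otherwise it is reported with a reason code instead
of a statistic. The empirical-Bayes layer models
`s² | σ² ~ σ²χ²_d/d` with a scaled-chi-square variance prior
`σ² ~ s0²χ²_{d0}/d0`. On the log scale both layers contribute additively:

    E[log s²]   = log s0² + g(d) + g(d0),   g(k) = ψ(k/2) − log(k/2)
    Var[log s²] = ψ′(d/2) + ψ′(d0/2)

so `d0` is identified by inverting the trigamma relation (Newton, tolerance
1e-10) and `s0²` by the first moment. If the observed spread of log s² does
not exceed the sampling term, `d0 = ∞` and `s0²` is the geometric-mean-based
estimate. The moderated statistic uses the usual precision-weighted
variance `s̃² = (d0·s0² + d·s²)/(d0 + d)` on `d0 + d` degrees of freedom
(normal reference when `d0 = ∞`). The gamma-form prior (chi-square in the
numerator) rather than the inverse-gamma convention makes the prior the
exact generative law of the recovery benchmark; for the shrinkage weights
and degrees of freedom the two conventions coincide, and the residual
difference in `s0²` is a second-order bias-term sign that the type-I
benchmark shows to be immaterial at these sample sizes.

Multiple testing is BH across all tested sites of the contrast — one
family, per standard practice (the original analysis does not state its
family). "Significant" defaults to p < 0.05, with q-values always reported
alongside.

## Protein adjustment

Protein-level fold changes estimated from the flow-through fraction are
subtracted from the matched site fold changes
(`log2fc_adj = log2fc_raw − protein_log2fc`). Sites on proteins not
quantified in the flow-through keep their raw fold change and are flagged
(`adjusted_flag = False`) rather than dropped — whether the original
analysis dropped them is not recoverable, and flagging preserves the
information. P-values are computed on the phospho data; the adjustment
applies to fold changes only.

## Group tests

* Pathway groups (e.g. insulin/TOR membership, supplied as a site-id set):
  Welch two-sample t of member vs non-member fold changes.
* Kinase motif groups: windows are scanned against consensus patterns in
  linear notation (`X-(S/T)-X-X-(D/E)`; offsets anchored at the acceptor,
  'X' padding never satisfies a constraint). Matched groups are tested with
  the Wilcoxon rank-sum against the **total** site population (the
  group-vs-complement variant is one flag away; for groups below ~5% of
  sites the two agree). Exact enumeration is used for tie-free samples with
  n ≤ 12, otherwise the normal approximation with midranks, tie and
  continuity corrections. BH across kinases.

Only the CK2 consensus (acidic residue at +3) is integral to the default
analysis; the other twelve kinase patterns shipped in `configs/motifs.tsv`
are literature-standard defaults, editable, and not claimed to match any
particular study's definitions.

## GO over-representation

Query = proteins with ≥1 site significant in the stated direction
(protein-adjusted fold-change sign); universe = proteins with ≥1 tested
site. Using the quantified-protein universe rather than the whole proteome
is the standard guard against detection bias. Terms smaller than 3 in the
universe are excluded from the BH family. Annotations are used as given;
ontology-graph propagation is out of scope.

## Imaging

Operations act on 2-D grids (maximum projections of stacks; the projection
is configurable). P-bodies are segmented by thresholding **within** the
oocyte mask — Otsu by default, mean + k·sd as an alternative, since the
original thresholding method (done in a general image tool) is unstated —
followed by removal of 8-connected components smaller than 9 px (default;
suppresses single-pixel noise). Granularity is the pixel-count ratio
|granule mask| / |oocyte mask|, compared between groups with Welch's t.
The boundary profile averages intensity along the boundary-parallel axis
of an axis-aligned ROI (pre-rotation by bilinear interpolation handles
oblique boundaries), normalized to the maximum of the averaged profile;
the ROI's perpendicular extent must be odd so offsets are symmetric about
zero. Coordinates are 0-based, row-major; rectangles are half-open.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions: 3 + 3 channels in two fractions (the 6-plex design being
emulated), site intensities
`gain_c(base_s · 2^{effect} · e^η) + offset_c + ε` truncated at 0, with
per-channel gains in [0.8, 1.25] and offsets in [0, 50] (per-channel
loading variation is not reported in the emulated study; these are
pragmatic ranges), σ_a = 20, σ_m = 0.1, log-normal site abundances
(median ≈ 3·10⁴). Planted structure, with defaults chosen to match the
analyses run on them: 10% random differential sites at |log₂| = 1.5
(±0.25), a 25-protein pathway group at −0.8, 100 CK2-motif sites at +0.6
(their windows forced to match the consensus), and independent
protein-level effects (|log₂| = 1.0 on 5% of proteins) applied to both the
flow-through and the sites of those proteins — so protein adjustment has
planted confounds to remove. A site's phospho-specific effect is
`true_log2_effect`; what the phospho table displays is
`total_log2_effect = phospho + protein` effect, and benchmark FDR counts a
call as false only if the total effect is zero. Missingness is
intensity-dependent (logistic in −log intensity, mean rate 5%). One integer
seed drives deterministic sub-streams for layout, windows, truth, noise,
missingness and annotations.

What the generator does **not** emulate — and what passing benchmarks
therefore do not establish for real data: isobaric co-isolation ratio
compression, peptide-level aggregation to sites, shared peptides,
correlated site abundances within a protein, batch structure across
fractions beyond affine distortion, and heavy-tailed contamination.

The egg-chamber image generator plants non-overlapping disk granules in a
disk oocyte to a target area fraction (achieved granularity is reported as
truth; rasterization makes it slightly discrete), a cortical band of
configurable enrichment for the boundary channel, and Gaussian noise; it
emits the true granule mask and boundary position for oracle tests.

## Numerical choices and degenerate inputs

* Trigamma inversion to 1e-10 by Newton from the asymptotic start.
* Welch t on two identical constant groups returns t = 0, p = 1 (no
  evidence of shift); two different constant groups are an error — never a
  silent NaN.
* BH is capped at 1 and step-up monotone; p-values outside [0, 1] raise.
* Constant images segment to an empty granule mask with a warning; an
  all-zero boundary ROI yields a flagged all-zero profile.
* All tables serialize floats with 12 significant digits; write∘read is
  the identity at that precision, and reruns with one seed are bitwise
  identical.

## Benchmark problem sizes

Calibration benchmarks use ~5000-site null experiments (type-I error),
20 replicate ~2000-site experiments (FDR/sensitivity at q < 0.05),
5000 draws for variance-prior recovery, 100 replicates for motif-group
null calibration, and 10–20 replicates for GO-term recovery — sizes at
which the binomial noise of each estimate is well inside the tolerance
being checked.

## Known limitations

The normalization is a deterministic approximation, not the reference
maximum-likelihood estimator of the variance-stabilization family; its
offset estimator assumes the background (low-quantile) intensities are
comparable across channels after scaling. The moderated test assumes
exchangeable variances given the prior; strongly intensity-structured
variance would be better served by an intensity-dependent prior. Group
tests treat sites as independent, ignoring within-protein correlation.
The motif scanner is pattern-based (no position-specific scoring).
GO results depend entirely on the supplied annotation table.
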