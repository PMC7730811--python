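# Methods

This note records the statistical models implemented in `necmethylome`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Site-level differential methylation

Each CpG site is modelled as a two-group binomial logistic regression of
methylation proportion on condition, weighted by coverage. Because the
design is a single two-level factor, the maximum-likelihood fit has a
closed form: the fitted proportion of each group is its coverage-weighted
pooled rate p̂_g = Σmeth/Σcov, and the group coefficient is
β̂ = logit(p̂_NEC) − logit(p̂_ctrl) with Wald variance
1/(C₁p̂₁(1−p̂₁)) + 1/(C₀p̂₀(1−p̂₀)). The implementation is vectorised
across sites; its equivalence to an iteratively-reweighted GLM fit is
asserted in the test suite against statsmodels to 1e-8.

WGBS replicates are overdispersed relative to the binomial because the
underlying methylation rate varies between individuals. Following the
quasi-likelihood treatment of McCullagh & Nelder, the dispersion is
estimated per site as φ = X²_Pearson/(n−2) over the n covered samples,
floored at 1, and the squared Wald statistic is divided by φ and referred
to χ²(1). With the generator's default between-sample precision
(κ = 30) a 20,000-site null simulation at 5v5 yields an empirical
p < 0.05 rate of ≈ 0.04–0.05, i.e. the floor plus the scaling calibrate
the test at these sample sizes; an F(1, n−2) reference was evaluated and
is conservative (≈ 0.02) because the floor already absorbs most
underestimation of φ.

Degenerate sites — a pooled group rate of exactly 0 or 1, where the logit
diverges — are repaired by adding 0.5 to both counts of each offending
sample at that site only, and the repair count is reported. Sites with
fewer than two covered samples in either group are reported untested
rather than given NaN p-values in the tested set.

Multiple testing uses Benjamini–Hochberg throughout (one shared
implementation wrapping statsmodels). Because q-value conventions differ
between tools, the results also report the realized raw-p threshold
max{p_i : q_i ≤ α}, which lets q-based calls be compared against a fixed
p cutoff. Saturation matters for power: a logit shift applied to a site
with a rate near 1 produces almost no rate change, so power studies in the
tests use intermediate-methylation sites, and genome-wide recall under the
full LM/IM/HM mixture is intrinsically bounded by the HM fraction.

## Global profiling

Sites are classified per condition from the coverage-weighted pooled rate
(one classification per condition, matching the single-rate-per-site
layout of the published tables): LM = [0, 0.20), IM = [0.20, 0.80],
HM = (0.80, 1]. The IM interval is closed on both ends; the boundary
convention is tested explicitly. Element-stratified 2×3 tables are tested
with Pearson's chi-square without continuity correction (df = 2), which
reproduces the published statistics from the published counts to their
printed precision. MDS is classical (Torgerson double-centering +
eigendecomposition) on Euclidean distances between per-sample rate
vectors of sites covered ≥ 5× in every sample; the first coordinate of
the first sample is reflected non-negative to fix orientation.

## Region-level differential methylation

A region's per-sample methylation is the unweighted mean of per-site
rates over its informative CpGs (coverage ≥ 5 in that sample; threshold
exposed). Samples without informative CpGs are missing, never imputed.
Rates are logit-transformed with r clipped to [ε, 1−ε], ε = 0.01 (exposed
in the API; the transform is undefined at 0/1 and WGBS means do reach the
boundaries at low CpG counts).

The two-group test moderates per-region variances with a scaled
inverse-chi-square prior: the hyperparameters (d₀, s₀²) are estimated by
method of moments on log s²_g with the digamma/trigamma corrections that
make the log-variance moments exact, and the trigamma inversion solved by
Newton iteration. The posterior variance replaces s²_g in the t statistic,
which gains d₀ extra degrees of freedom. The d₀ → 0 (ordinary t) and
d₀ → ∞ (fixed-variance z) limits are asserted in tests, and the estimator
is cross-checked against limma::squeezeVar via Rscript on a fixed fixture.

DMR calls require |Δ mean rate| ≥ 0.1 (inclusive), strictly more than 3
informative CpGs in every sample (min_informative = 4, operationalising
"more than three"), and p ≤ 0.05 unadjusted; BH q-values are reported
alongside. The region-level false-discovery control therefore leans on
the effect-size and informativeness filters, which is why the recovery
test checks both recall and realized FDR.

## Differential expression

CPM feeds the abundance filter and the test; median-of-ratios size
factors (median, on the ratio scale, of counts over per-gene geometric
means across reference genes with no zero count) are used only for the
integration's expression values — the two normalisations serve different
stages deliberately. The filter drops genes with total normalised count
< 10 (strict) or with every group mean < 1; the phrase "lowest average
coverage of 1 across all samples" admits an overall-mean reading, which
is available via `mode="overall"`, but the per-group reading is the
default because it keeps genes expressed in only one condition.

The test is the same moderated t on log2(CPM + 0.5) (pseudocount
exposed), with s₀² replaced by a lowess fit of the log variances against
the gene's mean log2 abundance (LS mean) — the mean–variance-trend
variant. Genes whose statistic is undefined even after moderation (zero
posterior variance) are excluded with a reason; a constant gene with a
positive prior yields t = 0, p = 1 rather than an exclusion.
Significance is p ≤ 0.05 with LS mean > 1 (strict).

## Integration

Per gene: Pearson r between per-sample region methylation rate and log2
normalised expression, Student t on n−2 df, BH adjustment. The selection
rule is conjunctive — methylation p ≤ 0.05, |Δ logit| ≥ 1, adjusted
correlation p ≤ 0.1 — with the additional "adjusted p ≤ 0.05" criterion
implemented as a stricter nested tier rather than a replacement, since
the two adjusted-p thresholds would otherwise conflict; both tiers are
reported. Directionality tables count hyper/hypo methylation against
up/down expression with row fractions; the cross-tissue analysis is the
Pearson correlation between the two tissues' per-gene r values over
shared genes.

## Synthetic data generator

The generator emulates the study design the analysis assumes: two
conditions × one tissue, default 10 samples per condition (the colon arm
of the motivating design was 10 sNEC vs 12 non-NEC; a symmetric 10v10 is
used), ~10⁵ CpGs and 2,000 genes on a 50 Mb genome — a chromosome-scale
stand-in that keeps the full pipeline under a minute while preserving
realistic CpG-per-promoter counts (~4 at default density).

* **Annotation.** Non-overlapping gene bodies of 2–20 kb with ≥ 4 kb
  gaps (so promoters never overlap or clip), partitioned into 1–8 exons
  with intervening introns; promoters TSS−1500..TSS+500; CGIs (500–1500
  bp, centred on the TSS) at 60 % of promoters; shores as 2 kb CGI
  flanks; enhancers of 200–1000 bp inside large intergenic gaps;
  intergenic as the complement of promoter ∪ exon ∪ intron. All
  coordinates 1-based closed.
* **Methylation.** Site mean methylation from a three-component beta
  mixture — LM ~ Beta(0.5, 8), IM ~ Beta(5, 5), HM ~ Beta(8, 0.5) — with
  genome-wide control weights (0.02, 0.46, 0.52) and element-specific
  weights for CGIs, shores, promoters, enhancers and exons taken from
  published non-NEC gut-epithelium element profiles (CGIs ≈ 46 % LM,
  promoters ≈ 21 % LM). NEC hypermethylation is a logit-scale shift
  (default +0.5) applied to a seeded-shuffle fraction of CpGs (default
  30 %), giving a broad, moderate genome-wide shift of the kind seen in
  NEC colon. Per-sample rates are Beta(κm, κ(1−m)) with κ = 30; coverage
  is negative binomial with mean 15 and size 5 (WGBS-typical); methylated
  counts are binomial.
* **Expression.** Baseline log2 means ~ N(5, 2); ceil(de_frac·n) genes
  (deterministic count, seeded shuffle) receive a fold change of constant
  magnitude (default 1) and random sign. A coupling fraction of the DE
  set, restricted to genes whose promoters actually received the
  methylation shift, is forced negative and additionally tied to the
  group-centred per-sample promoter methylation (−4 log2 units per unit
  rate), so methylation and expression are anti-correlated within as well
  as between groups — the structure the integration stage is designed to
  detect (≈ 0.2 of DE genes by default, mirroring the minority of DE
  genes with methylation links). Library-size factors are uniform on
  [0.5, 1.5]; counts are negative binomial with dispersion 0.05.

What the generator does **not** emulate: read-level artefacts (bisulfite
conversion errors, mapping bias, SNPs under CpGs), spatially correlated
methylation along the genome, patient-level covariates (age, sex, batch),
isoform structure, and compositional RNA-seq effects beyond library size.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the stated generative assumptions, not
robustness to those real-data complications.

## Numerical and degenerate-input conventions

Logit clipping ε = 0.01; DE pseudocount 0.5; BH excludes NaN p-values
and reports their count; chi-square tables with a zero row or column are
reported undefined with a reason instead of raising; ties in DMS sorting
are broken stably by (q, p); nearest-feature ties on |distance| break
lexicographically on feature id; all simulation randomness flows through
`numpy.random.default_rng` seeded from the config, so identical configs
give byte-identical datasets.

## Problem sizes

The test suite and acceptance script use 10,000–100,000-CpG and
500–2,000-gene configurations: large enough for stable empirical rates
(binomial standard error ≈ 0.0015 on a 20,000-site type-I estimate),
small enough that the whole suite runs in about a minute on one CPU.
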