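# Methods

This note documents the models, parameter choices and numerical conventions
behind `cfepiscan`, and what the synthetic benchmark does and does not
establish about real data.

## Window grid and filters

Each autosome is tiled with windows of width w = 500 bp and step s = 250 bp;
windows are [k·s, k·s + w) and a partial terminal window is dropped so all
windows share one width (keeping count statistics comparable; the
alternative of retaining a short terminal window changes nothing else).
"Coverage" is fragment-overlap counting — a fragment increments every
window it overlaps by ≥ 1 bp, matching the semantics of interval-overlap
counting tools — not base-level depth. Window filters: base-weighted mean
mappability < 0.9 (bases absent from the track score 1), any overlap with a
dark region, and the low-coverage rule *keep iff more than 3 counts in at
least 10 samples*, evaluated on HC and SCZ pooled, each modality filtered
independently.

## Negative-binomial differential engine

Counts are modelled as K<sub>ij</sub> ~ NB(μ<sub>ij</sub>, α<sub>i</sub>)
with log link, offset log s<sub>j</sub> and variance μ + αμ².

* **Size factors** are the median over all-positive windows of
  K<sub>ij</sub>/geomean<sub>i</sub> (median-of-ratios). They are not
  rescaled; only ratios matter downstream.
* **Dispersion** per window is method-of-moments on normalized counts,
  α̂ = max((var − mean)/mean², 10⁻⁸), blended geometrically with a robust
  (Huber) regression trend α(μ) = a₀ + a₁/μ. This is a deliberate
  simplification of a full empirical-Bayes MAP shrinkage: the engine is
  validated by calibration and recovery rather than numeric identity with
  any particular implementation, and on 143-sample designs the MoM point
  estimate is already stable (the trend blend mainly protects low-mean
  windows). Below 20 windows the trend is skipped with a warning.
* **Fitting** is batched iteratively-reweighted least squares across all
  windows simultaneously (per-window 5×5 normal equations solved with
  batched linear algebra; 20,000 windows × 143 samples fit in a few
  seconds). Standard errors come from the expected Fisher information at
  the optimum. Coefficients are reported on the log₂ scale. Windows not
  converged after 100 iterations are flagged and excluded from calling.
* **Design**: intercept, group (SCZ = 1), age standardized to mean 0/SD 1,
  gender (M = 1), and treatment-coded batch indicators for 5mC only
  (reference = lexicographically first batch). The batch term is omitted
  for 5hmC because that assay shows no batch structure.
* **Calling**: two-sided Wald p = 2(1 − Φ(|β/SE|)); hyper if p < 5·10⁻⁴
  and log₂FC > 0.5, hypo if p < 5·10⁻⁴ and log₂FC < −0.5. The p-threshold
  default is 5·10⁻⁴ (the value consistent with the reported region counts
  and figure gates); it is configurable, as is an optional BH adjustment
  which is off by default — calling operates on raw p with a fold-change
  gate.
* **Power** per region uses the two-sample two-sided t-test formula with
  noncentrality d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2, at d = |log₂FC|/lfcSE and
  α = 0.005. At d = 0 this returns exactly α. d is a Wald-statistic-scaled
  quantity, not Cohen's d; it is used as defined without re-interpretation.
  The printed powers for the fragment metrics (0.27/0.68/0.51 at effect
  sizes 0.23/0.43/0.35) are not jointly consistent with one sample-size
  convention; this package always uses (n₁, n₂) as given, which reproduces
  the first value and brackets the others. scipy's noncentral-t CDF loses
  accuracy at large noncentrality; NaNs there are replaced by the
  asymptotic normal form.
* **VST** is log₂(K/s + 1). It feeds only clustering, the severity model
  and the brain screen, where any monotone variance-flattening transform
  serves; the full parametric variance-stabilizing integral is intentionally
  not reproduced.
* **Clustering** of samples at called regions uses average linkage on
  1 − Pearson correlation between sample profiles, cut at k = 2.

## Fragment QC

Fragments of insert size 20–1000 bp (inclusive) on autosomes are retained.
Length classes: short < 166 bp, medial 166–332 bp inclusive on both ends,
long > 332 bp — 166 bp is the mono-nucleosome + linker length, 332 bp the
di-nucleosome length. Capture efficiency = modality-matched spike-in reads
/ total spike-in reads. Group comparisons use the rank-sum test (exact for
small tie-free samples, tie-corrected normal approximation otherwise) with
Cohen's d on the pooled SD as the standardized effect (the effect-size
estimator is an assumption; the source analyses report signed effects with
rank-sum p-values without naming one).

## Annotation and enrichment

CpG rings: a region overlapping an island is "island"; otherwise its
midpoint distance to the nearest island edge assigns "shore" (< 2 kb),
"shelf" (2–4 kb) or "interCGI" (midpoint classification is our choice for
boundary-spanning regions; island overlap takes precedence). Promoters are
the strand-aware 1 kb upstream of the TSS. A region may carry several genic
classes (promoter/exon/intron); summaries use precedence promoter > exon >
intron. Enrichment reports the upper-tail hypergeometric P(X ≥ k) and a
two-sided p defined as the doubled smaller tail capped at 1 (the convention
chosen where "two-sided" is otherwise undefined); tissue panels use the 2×2
Fisher exact test with sample odds ratio. BH adjustment is applied across
sets or tissues.

## Colocalization

A region colocalizes with a GWAS locus on ≥ 1 bp interval overlap
(half-open coordinates). The proximity null re-places the lead-SNP count
uniformly over unmasked bases (complement of the dark regions) for `reps`
rounds (default 1000) and records each simulated SNP's distance to its
nearest region; all rounds are pooled into one null sample. The observed
statistic uses the same direction — each lead SNP to its nearest region
(region-to-nearest-SNP is also implemented) — and the comparison is a
one-sided rank-sum test (observed stochastically smaller). Distance between
a half-open region [a, b) and position p is max(a − p, p − (b−1), 0).
SCZ-specific variants require qual > 30 and depth > 30 (strict), exact
(chrom, pos, ref, alt) identity with a lead SNP (no strand flipping), and
absence of the same call from the HC cohort.

## Brain-structure association

Measures are residualized by ordinary least squares with the raw median
added back: cortical thickness (CT) against age + gender; cortical volume,
surface area and subcortical volume (CV/SA/SV) additionally against
intracranial volume; region values (VST at called windows) against age +
gender. Group differences use per-measure rank-sum tests with BH across
measures at FDR 0.05. Note that with ~22 strong true positives among 305
measures, BH at 0.05 *expects* about one false flag — exact recovery of an
affected set is not a property FDR control provides.

The screen computes all region × measure Spearman correlations (rank
transform + matrix product; p from the t approximation), applies BH jointly
over all pairs of one modality (the conservative scope), and retains
measures with ≥ 5 significant regions for 5mC or ≥ 10 for 5hmC.

Sparse CCA follows the penalized matrix decomposition: on M = XᵀZ (columns
standardized), each component maximizes uᵀMv subject to ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1,
‖u‖₁ ≤ c₁, ‖v‖₁ ≤ c₂, by alternating soft-thresholded updates with the
threshold set by bisection, initialized from the leading singular vector,
deflating M by d·uvᵀ between the K = 3 components. With penalties at their
maxima the components equal the truncated SVD (tested to 10⁻⁶). Sign
convention: first nonzero element of u positive.

Penalty tuning: candidate penalties are fractions {0.15, 0.3, 0.45, 0.6}
of √dim. For each grid point the Fisher-transformed first-component
correlation is compared against its distribution over row-permutations of
X. Two numerical choices matter here and are deliberate:
(i) z-scores use the null SD *pooled across grid points*, because
permutation nulls concentrate as penalties tighten and per-point scaling
would always select the sparsest setting; (ii) the final penalty is the
sparsest within one pooled SD of the best z (the one-standard-error rule).
The reported z and the no-signal flag (z < 2) are recomputed on fresh
permutations, removing the max-over-grid selection bias. "Contributing"
variables are those whose weight exceeds 10% of the largest magnitude in
any component — coefficients below that are numerically nonzero but
negligible.

Reliable measures = screen-retained ∩ sCCA-contributing; reported pairs are
the significant screen pairs restricted to reliable measures, annotated
with membership in the atrophy (group-difference) set. The imaging subset
is handled by explicit sample intersection.

## Severity model

A gradient-boosting classifier on VST values at called regions returns a
per-sample SCZ probability. Hyperparameters (trees ∈ {50, 100, 200}, depth
∈ {1, 2, 3}, learning rate 0.1) are selected by mean log-loss over repeated
stratified 3-fold cross-validation (10 rounds by default); reported scores
are out-of-fold predictions from a final stratified 3-fold split, so no
sample is scored by a model that saw its label. Whether the original
analysis cross-validated its scores is unstated; out-of-fold is chosen to
avoid leakage, at the cost that in-sample score magnitudes elsewhere are
not directly comparable. Scores are correlated (Spearman) with the
PANSS-like and BACS-like scales.

## Synthetic-data generator

The generator reproduces the *statistical structure* the analysis assumes,
with ground truth recorded for recovery testing:

* cohort of 77 HC / 66 SCZ (imaging subset 68/59), ages ~ N(32.1, 10.4²)
  truncated at 17, ~62/67% female, PANSS-like ~ 31.8 (2.8) in HC vs
  49.2 (15.7) in SCZ and BACS-like −0.22 (0.93) vs −1.82 (1.46), generated
  as monotone noisy functions of a latent severity so severity-score
  correlations have known sign; cfDNA concentration log-normal with a
  standardized SCZ shift of 0.4;
* NB window counts with baseline log-mean ~ N(log 8, 1), dispersion 0.1,
  covariate effects age 0.005/yr, gender 0.05, batch 0.1 (5mC only) on the
  natural-log mean, per-sample depth factors log-normal (SD 0.2); injected
  differential windows with |log₂FC| = 1 (half hyper). Baseline depth and
  dispersion of the real assays are unpublished; these values are chosen
  once for testability (counts comfortably above the low-coverage filter,
  overdispersion clearly non-Poisson), not as estimates of the real data;
* co-methylated latent blocks: a per-sample factor added to the log-mean
  of a block of 8 truth windows with loading 0.5 (natural log), factors
  across blocks sharing a common component (50% variance). The brain
  generator links measures to these factors with strength 1.2 (in noise-SD
  units). Both values are set so a linked measure correlates at ρ ≈ 0.45
  with each block region — strong co-regulation, chosen so recovery is
  identifiable rather than borderline;
* fragment lengths from a 3-component normal mixture: sub-nucleosomal
  (120 ± 25), mono-nucleosomal (166 ± 20), di-nucleosomal (332 ± 40), HC
  weights (0.25, 0.60, 0.15) vs SCZ (0.22, 0.60, 0.18) — the direction of
  the reported case-control difference (short fraction lower, long higher
  in SCZ); 1% deliberately out-of-range lengths and 0.5% sex-chromosome
  fragments exercise the QC filter;
* brain measures split CT/CV/SA (68 each) + SV (101) with age/gender/ICV
  loadings (CT without ICV), a −2·SD group effect on 22 affected measures,
  and N(0,1) noise;
* GWAS-style loci (20 kb, lead SNP inside) with a configurable fraction of
  lead SNPs planted inside supplied regions, and variant-call tables with
  injected SCZ-exclusive, shared, and low-quality decoy calls.

Everything is deterministic per seed (`numpy.random.default_rng`); the
pipeline derives stage seeds from one master seed via `SeedSequence`.

**What passing tests show — and don't.** The benchmark establishes that the
implementation is correct and calibrated under its own model: NB counts
with log-linear covariates, independent windows (beyond the planted
blocks), Gaussian measures, uniform SNP placement. Real cfDNA data add
GC/fragment-length bias, spatially correlated windows, immunoprecipitation
efficiency variation, population structure and LD among SNPs — none of
which are simulated, and no claim about performance under those features is
made. Headline region counts of any particular cohort are functions of its
data and are not reproduction targets here.

## Problem sizes used in validation

The automated checks run at the study's sample sizes (143 samples; 127 in
the imaging subset) with genome/window counts scaled to the toy genome:
20,000 windows for null calibration, 5,000 for recovery and normalization
accuracy, 5,000 Monte-Carlo draws for the power comparison, 200–500
re-placement rounds × 20 seeds for the colocalization null, and two full
pipeline runs for determinism. These sizes give the tails and rates being
tested a few percent of Monte-Carlo error, matching the tolerances asserted.

## Known limitations

* The dispersion estimator is a trend-blend, not MAP shrinkage; for a
  handful of samples (≪ 50) it will be noticeably noisier than
  empirical-Bayes engines.
* The sCCA tuner evaluates a small penalty grid; very asymmetric sparsity
  between the two views may fall between grid points.
* Region annotation is O(regions × genes) — fine for hundreds of called
  regions against toy gene models; annotating millions of windows against
  a full gene set would need an interval index.
* The colocalization null places SNPs uniformly over unmasked bases; it
  does not model SNP density or LD structure.
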