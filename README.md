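# cfepiscan

Analysis toolkit for genome-wide 5-methylcytosine (5mC) and
5-hydroxymethylcytosine (5hmC) profiles of plasma cell-free DNA (cfDNA) in
case-control studies of schizophrenia (SCZ) versus healthy controls (HC).
It is written for computational biologists who receive enrichment-sequencing
fragment files (cfMeDIP-seq for 5mC, hMe-Seal for 5hmC) plus clinical and
structural-MRI tables, and want a tested, reproducible path from fragments to
differentially modified regions and their downstream interpretation.

## What it computes

**Differential modification.** The genome is tiled with 500 bp windows
advancing in 250 bp steps; windows with low mappability (base-weighted mean
score < 0.9), any dark-region overlap, or low coverage (not more than three
fragments in at least ten samples) are removed. Window counts
K<sub>ij</sub> follow a negative-binomial model

&nbsp;&nbsp;&nbsp;&nbsp;K<sub>ij</sub> ~ NB(μ<sub>ij</sub>, α<sub>i</sub>),&nbsp;&nbsp;
log μ<sub>ij</sub> = x<sub>j</sub><sup>T</sup>β<sub>i</sub> + log s<sub>j</sub>,&nbsp;&nbsp;
Var = μ + α μ²,

with median-of-ratios size factors s<sub>j</sub>, a trend-blended
method-of-moments dispersion α<sub>i</sub>, and a design containing
intercept, group (SCZ = 1), standardized age, gender and (for 5mC only)
batch. The group coefficient is tested with a Wald z-test; windows with
p < 5·10⁻⁴ and |log₂FC| > 0.5 are called hyper- or hypo-modified regions
(DMRs for 5mC, DhMRs for 5hmC). Per-region power uses the noncentral-t
two-sample formula at effect size |log₂FC|/lfcSE and α = 0.005.

**Around the core:** cfDNA fragment QC (20–1000 bp autosomal filter,
short/medial/long fractions split at the 166 bp mono- and 332 bp
di-nucleosome lengths, spike-in capture efficiency, rank-sum group
comparisons with Cohen's d and power); CpG island/shore/shelf and
promoter/exon/intron annotation with hypergeometric and Fisher set
enrichment (BH-adjusted); colocalization of called regions with GWAS loci
and a proximity test against 1000 rounds of uniformly re-placed SNPs;
SCZ-specific variant filtering (qual > 30, depth > 30, exact lead-SNP
allele match, absent from HC calls); association of regions with 305 brain
structural measures by a joint BH-corrected Spearman screen plus sparse CCA
via penalized matrix decomposition (three components, permutation-tuned L1
penalties), intersecting both routes into a "reliable" measure set; and a
cross-validated gradient-boosting disease-probability score correlated with
PANSS/BACS clinical scales.

A synthetic-data generator (`cfepiscan.simulate`) emulates the full study
design — 77 HC / 66 SCZ, a 68/59 matched-imaging subset, NB counts with
injected differential windows and co-methylated latent blocks,
nucleosome-peaked fragment lengths, spike-ins, GWAS-style loci and clinical
scores with known ground truth — so every stage is testable end to end.

## Worked example

Run the full synthetic benchmark from the shell:

```bash
cfepiscan all --out demo_out --seed 0
```

which executes simulate → qc → windows → diff → annotate → coloc → brain →
severity and prints the per-stage manifest:

```json
{
 "simulate": {"samples": 143, "windows": 7198, "fragments": 572000},
 "qc":       {"samples": 143},
 "windows":  {"kept_5mC": 6406, "kept_5hmC": 6431,
              "pct_genome_5mC": 92.67, "pct_genome_5hmC": 92.67},
 "diff":     {"dmrs": 38, "dhmrs": 33, "hypo_5mC": 20, "hyper_5mC": 18},
 "annotate": {"regions": 38, "genes_5mC": 30, "genes_5hmC": 21, "shared_genes": 10},
 "coloc":    {"pairs": 28, "proximity_p": 2e-06, "specific_variants": 3},
 "brain":    {"n_pairs": 11590, "retained": 29, "scca_measures": 19,
              "reliable": 19, "atrophic": 23},
 "severity": {"samples": 143, "rho_panss": 0.6553, "rho_bacs": -0.4959}
}
```

Reading the numbers: the generator injected 40 differential windows per
modality into a two-chromosome 1.8 Mb toy genome; after the
mappability/dark/coverage filters (6406 of 7198 windows kept) the NB Wald
engine calls 38 DMRs and 33 DhMRs, nearly all of them truth windows. The
called DhMRs sit significantly closer to the planted GWAS lead SNPs than
re-placed random SNPs (proximity p = 2·10⁻⁶), exactly 3 injected
SCZ-exclusive variants survive the quality filter, the Spearman + sparse-CCA
intersection reports 19 reliable brain measures, and the out-of-fold disease
score correlates positively with the PANSS-like symptom scale (ρ = 0.66)
and negatively with the BACS-like cognition score (ρ = −0.50), the signs
the severity model is designed to recover.

The same stages are available as library calls; the estimator-shaped cores
follow scikit-learn conventions:

```python
from cfepiscan import NBWaldDifferential, simulate

cohort = simulate.generate_cohort(seed=0)
counts, truth = simulate.generate_counts(None, cohort, seed=1,
                                         n_windows=5000, n_true=60)
model = NBWaldDifferential(p_thresh=5e-4, lfc_thresh=0.5).fit(counts, cohort)
print(model.results_["call"].value_counts())
```

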