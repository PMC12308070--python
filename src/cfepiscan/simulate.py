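"""Synthetic cohort, genome and data generation.

Every downstream stage of the pipeline (fragment QC, window counting,
differential calling, enrichment, colocalization, brain association,
severity scoring) is exercised on data produced here.  The generator
emulates the statistical structure of a plasma cfDNA 5mC/5hmC case-control
study: a 77 HC / 66 SCZ cohort, negative-binomial window counts with
injected differential regions and covariate effects, nucleosome-peaked
fragment lengths, spike-in control counts, 305 brain structural measures
with a matched-imaging subset, and GWAS-style SNP loci with per-cohort
variant calls.  Ground truth of everything injected is recorded in a
:class:`TruthTable` so recovery can be measured.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "TruthTable",
    "generate_genome",
    "generate_cohort",
    "generate_counts",
    "generate_fragments",
    "generate_brain_measures",
    "generate_snp_loci",
    "write_bed",
    "write_truth",
]

MEASURE_CLASSES = ("CT", "CV", "SA", "SV")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """A toy genome: chromosome sizes plus the tracks the filters consume.

    Intervals are 0-based half-open and lie within chromosome bounds.
    ``low_mappability`` intervals carry a per-base score in [0, 1); bases not
    covered by any interval have mappability 1.  ``dark_regions`` model
    centromere/telomere-like excluded intervals.
    """

    chromosomes: list  # [(name, length)]
    cpg_islands: pd.DataFrame  # chrom, start, end
    low_mappability: pd.DataFrame  # chrom, start, end, score
    dark_regions: pd.DataFrame  # chrom, start, end
    genes: pd.DataFrame  # gene_id, chrom, strand, tss, start, end, exons, gene_type

    @property
    def chrom_sizes(self) -> dict:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return int(sum(l for _, l in self.chromosomes))

    def autosomes(self) -> list:
        return [name for name, _ in self.chromosomes]


@dataclass
class TruthTable:
    """Ground truth of injected signal, the acceptance surface for recovery.

    ``diff_windows`` maps window index -> signed log2 fold change;
    ``links`` lists (region_index, measure_index, strength) triples;
    ``affected_measures`` are the indices given a (negative) group effect;
    ``planted_snps`` flags lead SNPs placed near a supplied region.
    """

    diff_windows: dict = field(default_factory=dict)  # int -> float lfc
    links: list = field(default_factory=list)  # (region_idx, measure_idx, strength)
    affected_measures: list = field(default_factory=list)
    planted_snps: list = field(default_factory=list)  # bool per lead SNP
    latent_blocks: list = field(default_factory=list)  # [[window idx, ...] per factor]

    def validate_against(self, n_windows=None, n_measures=None, n_regions=None):
        if n_windows is not None and self.diff_windows:
            if max(self.diff_windows) >= n_windows:
                raise ValueError("truth window index outside generated windows")
        if n_measures is not None:
            for m in self.affected_measures:
                if m >= n_measures:
                    raise ValueError("truth measure index outside measures")
            for _, m, _ in self.links:
                if m >= n_measures:
                    raise ValueError("link measure index outside measures")
        if n_regions is not None:
            for r, _, _ in self.links:
                if r >= n_regions:
                    raise ValueError("link region index outside regions")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _place_intervals(rng, length, target_fraction, mean_len, min_len=200):
    """Place non-overlapping intervals covering ~target_fraction of [0, length)."""
    if target_fraction <= 0:
        return []
    target = int(length * target_fraction)
    placed = []
    covered = 0
    occupied = np.zeros(0, dtype=np.int64)  # flattened sorted edges
    attempts = 0
    while covered < target and attempts < 10000:
        attempts += 1
        span = max(min_len, int(rng.exponential(mean_len)))
        span = min(span, max(min_len, target - covered + min_len))
        if span >= length:
            break
        start = int(rng.integers(0, length - span))
        end = start + span
        # reject overlaps with already placed intervals
        idx = np.searchsorted(occupied, [start, end])
        if idx[0] != idx[1] or idx[0] % 2 == 1:
            continue
        placed.append((start, end))
        covered += span
        occupied = np.sort(np.concatenate([occupied, [start, end]]))
    placed.sort()
    return placed


def generate_genome(
    seed,
    n_chrom=2,
    lengths=(1_000_000, 800_000),
    island_rate=1e-5,
    low_map_fraction=0.05,
    dark_fraction=0.02,
    n_genes=60,
):
    """Generate a :class:`GenomeSpec` with CpG-island, mappability and dark tracks.

    ``island_rate`` is islands per bp; ``low_map_fraction``/``dark_fraction``
    are the genome fractions covered by low-mappability (score < 0.9) and
    dark intervals; achieved coverage is within ±20% of the request.
    """
    lengths = list(lengths)[:n_chrom]
    if len(lengths) < n_chrom:
        lengths = lengths + [lengths[-1]] * (n_chrom - len(lengths))
    for l in lengths:
        if l < 10_000:
            raise ValueError("chromosome length must be >= 10 kb")
    if not (0 <= low_map_fraction < 1 and 0 <= dark_fraction < 1):
        raise ValueError("fractions must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", int(l)) for i, l in enumerate(lengths)]

    islands, lowmap, dark, genes = [], [], [], []
    gene_counter = 0
    for name, length in chroms:
        n_isl = rng.poisson(island_rate * length)
        starts = np.sort(rng.integers(0, max(1, length - 3000), size=n_isl))
        prev_end = -1
        for s in starts:
            w = int(rng.integers(300, 2000))
            if s <= prev_end:  # keep islands non-overlapping
                s = prev_end + 100
            if s + w >= length:
                continue
            islands.append((name, int(s), int(s + w)))
            prev_end = s + w
        for s, e in _place_intervals(rng, length, low_map_fraction, 5000):
            score = float(rng.uniform(0.0, 0.85))
            lowmap.append((name, s, e, score))
        for s, e in _place_intervals(rng, length, dark_fraction, 8000):
            dark.append((name, s, e))
        # gene models: span with 2-6 exons inside
        n_g = max(1, int(round(n_genes * length / sum(lengths))))
        for _ in range(n_g):
            span = int(rng.integers(5_000, 50_000))
            start = int(rng.integers(0, max(1, length - span)))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            n_ex = int(rng.integers(2, 7))
            edges = np.sort(rng.choice(np.arange(start, end), size=2 * n_ex, replace=False))
            exons = [(int(edges[2 * k]), int(edges[2 * k + 1]) + 1) for k in range(n_ex)]
            gtype = "protein_coding" if rng.random() < 0.8 else "lncRNA"
            genes.append((f"G{gene_counter:04d}", name, strand, int(tss), start, end, exons, gtype))
            gene_counter += 1

    return GenomeSpec(
        chromosomes=chroms,
        cpg_islands=pd.DataFrame(islands, columns=["chrom", "start", "end"]),
        low_mappability=pd.DataFrame(lowmap, columns=["chrom", "start", "end", "score"]),
        dark_regions=pd.DataFrame(dark, columns=["chrom", "start", "end"]),
        genes=pd.DataFrame(
            genes,
            columns=["gene_id", "chrom", "strand", "tss", "start", "end", "exons", "gene_type"],
        ),
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    seed,
    n_hc=77,
    n_scz=66,
    n_imaging_hc=68,
    n_imaging_scz=59,
    n_batches=2,
    conc_effect=0.4,
):
    """Generate the sample table: demographics, batch, ICV, imaging subset,
    cfDNA concentration and severity-driven clinical scores.

    Ages ~ N(32, 10.4) truncated at 17; ~62/67% female per group.  Each
    sample carries a latent disease severity (higher in SCZ); the PANSS-like
    total increases and the BACS-like composite decreases monotonically (with
    noise) in that severity, so severity-score correlations have known sign.
    cfDNA concentration is log-normal with a standardized group shift of
    ``conc_effect`` (SCZ higher).
    """
    rng = np.random.default_rng(seed)
    n = n_hc + n_scz
    group = np.array(["HC"] * n_hc + ["SCZ"] * n_scz)
    age = np.clip(rng.normal(32.1, 10.4, size=n), 17, 75)
    p_female = np.where(group == "HC", 0.623, 0.667)
    gender = np.where(rng.random(n) < p_female, "F", "M")
    batch = np.array([f"B{rng.integers(1, n_batches + 1)}" for _ in range(n)])
    icv = rng.normal(1.45e6, 1.4e5, size=n)

    severity = np.where(group == "SCZ", rng.normal(1.5, 0.8, n), rng.normal(0.0, 0.5, n))
    panss = np.where(
        group == "SCZ",
        np.clip(30 + 12 * np.clip(severity, 0, None) + rng.normal(0, 4, n), 30, 120),
        np.clip(rng.normal(31.8, 2.8, n), 30, 50),
    )
    bacs = np.where(
        group == "SCZ",
        -0.2 - 1.0 * severity + rng.normal(0, 0.6, n),
        rng.normal(-0.22, 0.93, n),
    )
    conc = np.exp(rng.normal(np.log(10.0) + conc_effect * 0.35 * (group == "SCZ"), 0.35))

    has_imaging = np.zeros(n, dtype=bool)
    hc_idx = np.where(group == "HC")[0]
    scz_idx = np.where(group == "SCZ")[0]
    has_imaging[rng.choice(hc_idx, min(n_imaging_hc, len(hc_idx)), replace=False)] = True
    has_imaging[rng.choice(scz_idx, min(n_imaging_scz, len(scz_idx)), replace=False)] = True

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "group": group,
            "age": np.round(age, 1),
            "gender": gender,
            "batch": batch,
            "icv": np.round(icv, 0),
            "has_imaging": has_imaging,
            "cfdna_conc": np.round(conc, 3),
            "panss_total": np.round(panss, 1),
            "bacs_z": np.round(bacs, 3),
            "severity": severity,
        }
    )


# ---------------------------------------------------------------------------
# window counts
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_EFFECTS = {"age": 0.005, "gender": 0.05, "batch": 0.1}


def generate_counts(
    genome,
    cohort,
    seed,
    window=500,
    step=250,
    baseline_logmean=(np.log(8), 1.0),
    dispersion=0.1,
    n_true=0,
    lfc_magnitude=1.0,
    frac_hyper=0.5,
    covariate_effects=None,
    depth_factors=None,
    modality="5mC",
    n_windows=None,
    n_latent_blocks=0,
    latent_block_size=8,
    latent_loading=0.5,
    latent_shared=0.5,
):
    """Draw a windows x samples NB count matrix with injected differential windows.

    log mean = baseline_i + lfc_i*[group==SCZ] + age/gender/batch effects
    + log depth_j; variance = mu + dispersion * mu^2.  ``n_true`` windows get a
    signed log2 fold change of ``lfc_magnitude`` (fraction ``frac_hyper`` up in
    SCZ).  ``n_windows`` overrides the genome grid size (windows then get
    synthetic coordinates on chr1) for large calibration runs.

    ``n_latent_blocks`` plants co-methylated clusters: each block of
    ``latent_block_size`` truth windows shares a per-sample latent factor
    added to the log-mean with weight ``latent_loading`` (natural-log scale).
    Factors are correlated across blocks through a common component with
    variance share ``latent_shared``, so one multivariate axis can span all
    blocks.  Block membership is recorded in ``truth.latent_blocks`` and the
    factor matrix (blocks x samples) in ``counts.attrs["latent_factors"]`` —
    the hook the brain-measure generator links to.

    Returns ``(counts, truth)`` where ``counts`` is a DataFrame indexed by
    window id with chrom/start/end columns followed by one column per sample.
    """
    from .windows import make_grid  # local import to avoid cycles

    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if n_windows is None:
        grid = make_grid(genome.chromosomes, window, step)
        if len(grid) == 0:
            raise ValueError("window grid yields zero windows")
    else:
        starts = np.arange(n_windows, dtype=np.int64) * step
        grid = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + window})
    W = len(grid)
    if n_true >= W:
        raise ValueError("n_true must be < number of windows")
    n = len(cohort)

    cov = dict(DEFAULT_COVARIATE_EFFECTS if covariate_effects is None else covariate_effects)
    if modality != "5mC":
        cov["batch"] = 0.0  # batch effect only present in the 5mC assay
    if depth_factors is None:
        depth_factors = np.exp(rng.normal(0, 0.2, size=n))
    depth_factors = np.asarray(depth_factors, dtype=float)

    base = rng.normal(baseline_logmean[0], baseline_logmean[1], size=W)
    lfc = np.zeros(W)
    truth = TruthTable()
    if n_true > 0:
        idx = rng.choice(W, size=n_true, replace=False)
        n_up = int(round(frac_hyper * n_true))
        signs = np.array([1.0] * n_up + [-1.0] * (n_true - n_up))
        rng.shuffle(signs)
        lfc[idx] = signs * lfc_magnitude
        truth.diff_windows = {int(i): float(l) for i, l in zip(idx, lfc[idx])}

    is_scz = (cohort["group"].to_numpy() == "SCZ").astype(float)
    age_c = cohort["age"].to_numpy() - cohort["age"].to_numpy().mean()
    is_m = (cohort["gender"].to_numpy() == "M").astype(float)
    batches = pd.Categorical(cohort["batch"]).codes.astype(float)

    sample_eta = (
        cov.get("age", 0.0) * age_c
        + cov.get("gender", 0.0) * is_m
        + cov.get("batch", 0.0) * batches
        + np.log(depth_factors)
    )
    log_mu = base[:, None] + np.log(2.0) * lfc[:, None] * is_scz[None, :] + sample_eta[None, :]

    factors = None
    if n_latent_blocks > 0:
        need = n_latent_blocks * latent_block_size
        if n_true < need:
            raise ValueError(
                f"latent blocks need {need} truth windows, only {n_true} injected")
        common = rng.normal(size=n)
        factors = (np.sqrt(latent_shared) * common[None, :]
                   + np.sqrt(1.0 - latent_shared)
                   * rng.normal(size=(n_latent_blocks, n)))
        for b in range(n_latent_blocks):
            block = idx[b * latent_block_size:(b + 1) * latent_block_size]
            log_mu[block, :] += latent_loading * factors[b][None, :]
            truth.latent_blocks.append([int(w) for w in block])
    mu = np.exp(log_mu)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    out = pd.concat(
        [grid.reset_index(drop=True),
         pd.DataFrame(counts, columns=list(cohort["sample_id"]))],
        axis=1,
    )
    out.index = [f"w{i:06d}" for i in range(W)]
    out.index.name = "window"
    out.attrs["modality"] = modality
    out.attrs["depth_factors"] = depth_factors
    out.attrs["latent_factors"] = factors
    truth.validate_against(n_windows=W)
    return out, truth


# ---------------------------------------------------------------------------
# fragments & spike-ins
# ---------------------------------------------------------------------------

DEFAULT_MIXTURE = {
    "centers": (120.0, 166.0, 332.0),
    "sds": (25.0, 20.0, 40.0),
    "weights_hc": (0.25, 0.60, 0.15),
    "weights_scz": (0.22, 0.60, 0.18),
}


def generate_fragments(
    cohort,
    genome,
    seed,
    depth=5000,
    mixture_params=None,
    out_of_range_fraction=0.01,
    sex_chrom_fraction=0.005,
    spike_in_design=None,
):
    """Draw per-sample cfDNA fragments and spike-in control counts.

    Lengths come from a 3-component normal mixture (sub-nucleosomal,
    mono-nucleosomal at 166 bp, di-nucleosomal at 332 bp) with group-specific
    weights; by default the SCZ short-fragment weight is lower and the long
    weight higher, matching the direction of the observed case-control
    difference.  A small fraction of fragments is made deliberately
    out-of-range (<20 or >1000 bp) or placed on a sex chromosome so the
    20-1000 bp autosome filter has something to remove.

    Returns ``(fragments, spike_ins)``: a dict sample_id -> DataFrame
    (chrom, start, end) and a DataFrame of spike-in read counts.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    mp = dict(DEFAULT_MIXTURE)
    if mixture_params:
        mp.update(mixture_params)
    for key in ("weights_hc", "weights_scz"):
        if abs(sum(mp[key]) - 1.0) > 1e-9:
            raise ValueError(f"{key} must sum to 1")
    if spike_in_design is None:
        spike_in_design = {"total": 2000, "efficiency": 0.88}

    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_lens = np.array([l for _, l in genome.chromosomes], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    centers = np.asarray(mp["centers"], float)
    sds = np.asarray(mp["sds"], float)

    fragments = {}
    spikes = []
    for _, row in cohort.iterrows():
        w = np.asarray(mp["weights_scz" if row["group"] == "SCZ" else "weights_hc"], float)
        comp = rng.choice(3, size=depth, p=w)
        lengths = rng.normal(centers[comp], np.maximum(sds[comp], 1e-12))
        lengths = np.clip(np.round(lengths), 20, 1000).astype(np.int64)
        # deliberately broken fragments for the QC filter to catch
        n_bad = rng.binomial(depth, out_of_range_fraction)
        if n_bad:
            bad_idx = rng.choice(depth, size=n_bad, replace=False)
            short = rng.random(n_bad) < 0.5
            lengths[bad_idx] = np.where(
                short, rng.integers(1, 20, n_bad), rng.integers(1001, 2000, n_bad)
            )
        ci = rng.choice(len(chrom_names), size=depth, p=chrom_p)
        starts = (rng.random(depth) * (chrom_lens[ci] - lengths)).astype(np.int64)
        chroms = np.array(chrom_names, dtype=object)[ci]
        n_x = rng.binomial(depth, sex_chrom_fraction)
        if n_x:
            chroms[rng.choice(depth, size=n_x, replace=False)] = "chrX"
        fragments[row["sample_id"]] = pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": starts + lengths}
        )
        total = spike_in_design["total"]
        eff = spike_in_design["efficiency"]
        matched = rng.binomial(total, eff)
        other = total - matched
        unmod = rng.binomial(other, 0.6)
        spikes.append((row["sample_id"], matched, unmod, other - unmod))

    spike_df = pd.DataFrame(spikes, columns=["sample_id", "matched", "unmodified", "other_mod"])
    return fragments, spike_df


def spike_counts_for_modality(spike_df, modality):
    """Reshape generated spike-in counts into (unmodified, 5mC, 5hmC) columns."""
    out = pd.DataFrame({"sample_id": spike_df["sample_id"]})
    out["reads_unmodified"] = spike_df["unmodified"]
    if modality == "5mC":
        out["reads_5mC"] = spike_df["matched"]
        out["reads_5hmC"] = spike_df["other_mod"]
    elif modality == "5hmC":
        out["reads_5hmC"] = spike_df["matched"]
        out["reads_5mC"] = spike_df["other_mod"]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return out


# ---------------------------------------------------------------------------
# brain measures
# ---------------------------------------------------------------------------

def generate_brain_measures(
    cohort,
    seed,
    n_measures=305,
    n_affected=22,
    effect_size=2.0,
    link_map=None,
    region_matrix=None,
    icv_loading=0.3,
    age_loading=-0.2,
    gender_loading=0.3,
    noise_sd=1.0,
    exclude_from_affected=None,
):
    """Generate samples x measures brain-structure data with known truth.

    Measures split into CT/CV/SA (68 each) and SV (remainder) classes. Each
    measure = covariate part (age, gender, ICV loadings; CT gets no ICV
    loading) + a negative group effect of ``effect_size`` (in units of
    ``noise_sd``) on ``n_affected`` measures + optional latent links to region
    values + N(0, noise_sd) noise.

    ``link_map`` is a list of (region_index, measure_index, strength); the
    standardized column ``region_index`` of ``region_matrix`` (samples x
    regions, aligned to ``cohort``) is added with weight ``strength``.

    Returns ``(measures, classes, truth)``.
    """
    if n_affected > n_measures:
        raise ValueError("n_affected must be <= n_measures")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_ct = min(68, n_measures)
    n_cv = min(68, max(0, n_measures - n_ct))
    n_sa = min(68, max(0, n_measures - n_ct - n_cv))
    n_sv = n_measures - n_ct - n_cv - n_sa
    classes = np.array(
        ["CT"] * n_ct + ["CV"] * n_cv + ["SA"] * n_sa + ["SV"] * n_sv, dtype=object
    )

    age_z = (cohort["age"].to_numpy() - cohort["age"].mean()) / cohort["age"].std()
    is_m = (cohort["gender"].to_numpy() == "M").astype(float)
    icv_z = (cohort["icv"].to_numpy() - cohort["icv"].mean()) / cohort["icv"].std()
    is_scz = (cohort["group"].to_numpy() == "SCZ").astype(float)

    X = np.zeros((n, n_measures))
    for j in range(n_measures):
        X[:, j] = age_loading * age_z + gender_loading * is_m
        if classes[j] != "CT":  # thickness does not scale with head size
            X[:, j] += icv_loading * icv_z

    allowed = np.arange(n_measures)
    if exclude_from_affected is not None:
        allowed = np.setdiff1d(allowed, np.asarray(list(exclude_from_affected)))
    if len(allowed) < n_affected:
        raise ValueError("too few measures left to choose the affected set")
    affected = rng.choice(allowed, size=n_affected, replace=False)
    X[:, affected] -= effect_size * noise_sd * is_scz[:, None]

    truth = TruthTable(affected_measures=sorted(int(a) for a in affected))
    if link_map:
        if region_matrix is None:
            raise ValueError("link_map requires region_matrix")
        R = np.asarray(region_matrix, dtype=float)
        if R.shape[0] != n:
            raise ValueError("region_matrix rows must align with cohort")
        for r_idx, m_idx, strength in link_map:
            if r_idx >= R.shape[1]:
                raise ValueError(f"link_map region {r_idx} not in region_matrix")
            if m_idx >= n_measures:
                raise ValueError(f"link_map measure {m_idx} out of range")
            col = R[:, r_idx]
            sd = col.std()
            z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
            X[:, m_idx] += strength * noise_sd * z
            truth.links.append((int(r_idx), int(m_idx), float(strength)))

    X += rng.normal(0, noise_sd, size=X.shape)
    measures = pd.DataFrame(
        X, index=cohort["sample_id"], columns=[f"{classes[j]}_{j:03d}" for j in range(n_measures)]
    )
    return measures, pd.Series(classes, index=measures.columns, name="class"), truth


# ---------------------------------------------------------------------------
# SNP loci & variant calls
# ---------------------------------------------------------------------------

def generate_snp_loci(
    genome,
    seed,
    n_loci=30,
    locus_width=20_000,
    planted_fraction=0.0,
    regions=None,
    n_specific=3,
    qual=50.0,
    depth=40,
):
    """Generate GWAS-style loci with lead SNPs plus per-cohort variant calls.

    A ``planted_fraction`` of lead SNPs is placed inside a supplied region
    (distance 0); the rest are placed uniformly.  Variant-call tables carry
    QUAL and depth; ``n_specific`` SCZ-exclusive calls exactly matching lead
    SNP position/alleles are injected, alongside shared calls and low-quality
    decoys, to exercise the specificity filter.

    Returns ``(loci, calls_scz, calls_hc, truth)``.
    """
    if not (0 <= planted_fraction <= 1):
        raise ValueError("planted_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in genome.chromosomes]
    sizes = genome.chrom_sizes
    alleles = np.array(list("ACGT"))

    region_list = []
    if regions is not None:
        region_list = list(regions[["chrom", "start", "end"]].itertuples(index=False, name=None))
    n_planted = int(round(planted_fraction * n_loci))
    if n_planted > 0 and not region_list:
        raise ValueError("planted_fraction > 0 requires regions")

    rows, planted_flags = [], []
    for i in range(n_loci):
        if i < n_planted:
            chrom, rs, re_ = region_list[int(rng.integers(0, len(region_list)))]
            lead = int(rng.integers(rs, re_))
            planted_flags.append(True)
        else:
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            lead = int(rng.integers(0, sizes[chrom]))
            planted_flags.append(False)
        start = max(0, lead - locus_width // 2)
        end = min(sizes[chrom], lead + locus_width // 2)
        ref, alt = rng.choice(alleles, size=2, replace=False)
        rows.append((chrom, start, end, lead, ref, alt, f"locus{i:03d}"))
    loci = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "lead_pos", "ref", "alt", "label"]
    )

    calls_scz, calls_hc = [], []
    # SCZ-exclusive calls matching lead SNPs, passing qual/depth filters
    spec_idx = rng.choice(n_loci, size=min(n_specific, n_loci), replace=False)
    for i in spec_idx:
        r = loci.iloc[i]
        calls_scz.append((r["chrom"], r["lead_pos"], r["ref"], r["alt"], qual, depth))
    # shared calls (present in both cohorts -> excluded by specificity)
    other = [i for i in range(n_loci) if i not in set(spec_idx)]
    for i in other[: max(0, len(other) // 2)]:
        r = loci.iloc[i]
        rec = (r["chrom"], r["lead_pos"], r["ref"], r["alt"], qual, depth)
        calls_scz.append(rec)
        calls_hc.append(rec)
    # low-quality decoys matching lead SNPs
    for i in other[len(other) // 2:]:
        r = loci.iloc[i]
        calls_scz.append((r["chrom"], r["lead_pos"], r["ref"], r["alt"], 20.0, 20))
    cols = ["chrom", "pos", "ref", "alt", "qual", "depth"]
    truth = TruthTable(planted_snps=planted_flags)
    return (
        loci,
        pd.DataFrame(calls_scz, columns=cols),
        pd.DataFrame(calls_hc, columns=cols),
        truth,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(df, path):
    df[["chrom", "start", "end"] + [c for c in df.columns if c not in ("chrom", "start", "end")]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_truth(truth, path):
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1, default=int)
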