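"""End-to-end orchestration of the synthetic benchmark and analysis stages.

``run_pipeline`` executes the stages in dependency order on a synthetic
bundle — simulate, fragment QC, window filtering, differential calling (5mC
and 5hmC), annotation/enrichment, colocalization, brain association and
severity scoring — writing per-stage TSV/JSON outputs and a manifest with
seeds and per-stage row counts.  All randomness derives from one master
seed through ``numpy.random.SeedSequence``, so identical configs give
byte-identical bundles.

Stage toggles: ``simulate`` always runs; disabling ``windows`` or ``diff``
ends the run after the preceding stage (everything downstream depends on
them); ``qc``, ``annotate``, ``coloc``, ``brain`` and ``severity`` can be
skipped individually.  The brain stage degrades gracefully (skip + log)
when no sample has imaging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, brain, colocalization, differential, fragments, severity, simulate, windows

log = logging.getLogger("cfepiscan")

STAGES = ["simulate", "qc", "windows", "diff", "annotate", "coloc", "brain", "severity"]


@dataclass
class PipelineConfig:
    """Declarative configuration; every threshold the stages consume."""

    out_dir: str = "cfepiscan_out"
    seed: int = 0
    # genome / cohort scale
    chrom_lengths: tuple = (1_000_000, 800_000)
    n_hc: int = 77
    n_scz: int = 66
    n_imaging_hc: int = None  # None -> min(68, n_hc)
    n_imaging_scz: int = None  # None -> min(59, n_scz)
    fragment_depth: int = 4000
    # injected signal
    n_true: int = 40
    lfc_magnitude: float = 1.0
    dispersion: float = 0.1
    # thresholds
    p_thresh: float = 5e-4
    lfc_thresh: float = 0.5
    map_threshold: float = 0.9
    fdr: float = 0.05
    power_alpha: float = 0.005
    # brain
    n_measures: int = 305
    n_affected: int = 22
    brain_effect: float = 2.0
    n_links: int = 5
    link_block_size: int = 8
    link_strength: float = 1.2
    # colocalization
    n_loci: int = 30
    planted_fraction: float = 0.5
    coloc_reps: int = 200
    # severity (reduced grid keeps the default bundle quick)
    severity_grid: tuple = (
        {"n_estimators": 50, "max_depth": 1, "learning_rate": 0.1},
        {"n_estimators": 100, "max_depth": 2, "learning_rate": 0.1},
    )
    severity_repeats: int = 2
    stages: tuple = tuple(STAGES)

    def validate(self):
        if not (0 < self.p_thresh < 1 and 0 < self.fdr < 1):
            raise ValueError("thresholds must be in (0, 1)")
        if self.lfc_thresh < 0 or self.dispersion <= 0:
            raise ValueError("invalid lfc threshold or dispersion")
        return self


def _seeds(master, n=16):
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _finish(out, manifest, bundle):
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle


def run_pipeline(config: PipelineConfig):
    """Run the configured stages; returns a dict of in-memory results and
    writes the report bundle (TSVs, JSONs, manifest) under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    manifest = {"seed": config.seed, "stages": {}, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items() if not isinstance(v, dict)
    }}
    bundle = {}

    def record(stage, **counts):
        manifest["stages"][stage] = counts
        log.info("stage %s done: %s", stage, counts)

    # ---------------- simulate ----------------
    genome = simulate.generate_genome(seeds[0], n_chrom=len(config.chrom_lengths),
                                      lengths=config.chrom_lengths)
    n_img_hc = min(68, config.n_hc) if config.n_imaging_hc is None else config.n_imaging_hc
    n_img_scz = min(59, config.n_scz) if config.n_imaging_scz is None else config.n_imaging_scz
    cohort = simulate.generate_cohort(seeds[1], n_hc=config.n_hc, n_scz=config.n_scz,
                                      n_imaging_hc=n_img_hc, n_imaging_scz=n_img_scz)
    frags, spikes = simulate.generate_fragments(cohort, genome, seeds[2],
                                                depth=config.fragment_depth)
    counts = {}
    truths = {}
    for mi, modality in enumerate(("5mC", "5hmC")):
        # the 5mC counts carry the co-methylated latent blocks that the
        # brain stage links measures to
        n_blocks = config.n_links if modality == "5mC" else 0
        counts[modality], truths[modality] = simulate.generate_counts(
            genome, cohort, seeds[3 + mi], dispersion=config.dispersion,
            n_true=config.n_true, lfc_magnitude=config.lfc_magnitude, modality=modality,
            n_latent_blocks=n_blocks, latent_block_size=config.link_block_size,
        )
    bundle.update(genome=genome, cohort=cohort, fragments=frags, spikes=spikes,
                  counts=counts, truths=truths)
    cohort.drop(columns=["severity"]).to_csv(out / "metadata.tsv", sep="\t", index=False)
    record("simulate", samples=len(cohort), windows=len(counts["5mC"]),
           fragments=sum(len(f) for f in frags.values()))

    # ---------------- qc ----------------
    if "qc" in config.stages:
        spike_5mc = simulate.spike_counts_for_modality(spikes, "5mC")
        qc = fragments.qc_table(frags, spike_5mc, "5mC", genome.autosomes())
        is_scz = cohort["group"] == "SCZ"
        qc_cmp = {}
        for col in ("f_short", "f_long"):
            cmp = fragments.compare_groups(qc.loc[~is_scz.values, col],
                                           qc.loc[is_scz.values, col])
            qc_cmp[col] = {"p": cmp.pvalue, "d": cmp.d, "power": cmp.power}
        conc = fragments.compare_groups(cohort.loc[~is_scz, "cfdna_conc"],
                                        cohort.loc[is_scz, "cfdna_conc"])
        qc_cmp["cfdna_conc"] = {"p": conc.pvalue, "d": conc.d, "power": conc.power}
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        (out / "qc_comparisons.json").write_text(json.dumps(qc_cmp, indent=1))
        bundle["qc"] = qc
        bundle["qc_comparisons"] = qc_cmp
        record("qc", samples=len(qc))
    else:
        record("qc", skipped="disabled")

    if "windows" not in config.stages:
        record("windows", skipped="disabled")
        return _finish(out, manifest, bundle)

    # ---------------- windows ----------------
    grid = counts["5mC"][["chrom", "start", "end"]].reset_index(drop=True)
    track_mask = windows.filter_windows(grid, genome.low_mappability, genome.dark_regions,
                                        config.map_threshold, genome.chrom_sizes)
    masks = {}
    for modality in ("5mC", "5hmC"):
        K = counts[modality].drop(columns=["chrom", "start", "end"])
        cov_mask = windows.low_coverage_filter(K.to_numpy())
        masks[modality] = track_mask & cov_mask
    frac = {m: windows.genome_fraction(grid, masks[m], genome.total_length)
            for m in ("5mC", "5hmC")}
    per_sample_rho, rho_summary = windows.modality_correlation(
        counts["5mC"].loc[masks["5mC"]], counts["5hmC"].loc[masks["5hmC"]],
        groups=cohort["group"].to_numpy(),
    )
    bundle["masks"] = masks
    bundle["genome_fraction"] = frac
    bundle["modality_rho"] = rho_summary
    pd.DataFrame({m: masks[m] for m in masks}).to_csv(out / "window_masks.tsv", sep="\t")
    record("windows", kept_5mC=int(masks["5mC"].sum()), kept_5hmC=int(masks["5hmC"].sum()),
           pct_genome_5mC=round(frac["5mC"], 2), pct_genome_5hmC=round(frac["5hmC"], 2))

    if "diff" not in config.stages:
        record("diff", skipped="disabled")
        return _finish(out, manifest, bundle)

    # ---------------- differential ----------------
    models, calls, vsts = {}, {}, {}
    for modality in ("5mC", "5hmC"):
        sub = counts[modality].loc[masks[modality]]
        model = differential.NBWaldDifferential(
            p_thresh=config.p_thresh, lfc_thresh=config.lfc_thresh,
            power_alpha=config.power_alpha,
        ).fit(sub, cohort, modality=modality)
        models[modality] = model
        res = model.results_
        res.to_csv(out / f"diff_{modality}.tsv", sep="\t")
        calls[modality] = res[res["call"] != "none"]
        vsts[modality] = model.transform(sub)
    bundle["models"] = models
    bundle["calls"] = calls
    bundle["vst"] = vsts
    record("diff", dmrs=len(calls["5mC"]), dhmrs=len(calls["5hmC"]),
           hypo_5mC=int((calls["5mC"]["call"] == "hypo").sum()),
           hyper_5mC=int((calls["5mC"]["call"] == "hyper").sum()))

    # ---------------- annotation / enrichment ----------------
    if "annotate" in config.stages:
        called_regions = calls["5mC"][["chrom", "start", "end"]]
        ann = annotation.annotate_regions(called_regions, genome)
        genes_5mc = annotation.regions_to_genes(called_regions, genome)
        genes_5hmc = annotation.regions_to_genes(calls["5hmC"][["chrom", "start", "end"]], genome)
        shared = annotation.shared_gene_summary(genes_5mc, genes_5hmc)
        rng = np.random.default_rng(seeds[6])
        all_genes = list(genome.genes["gene_id"])
        gene_sets = {f"set{i}": list(rng.choice(all_genes, size=min(10, len(all_genes)),
                                                replace=False)) for i in range(5)}
        if genes_5mc:
            gene_sets["hit_like"] = genes_5mc[: max(3, len(genes_5mc) // 2)]
        enr = annotation.hypergeom_enrich(genes_5mc, gene_sets, len(all_genes))
        ann.to_csv(out / "annotation.tsv", sep="\t")
        annotation.enrichment_table(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        bundle["annotation"] = ann
        bundle["gene_overlap"] = shared
        bundle["enrichment"] = enr
        record("annotate", regions=len(ann), genes_5mC=len(genes_5mc),
               genes_5hmC=len(genes_5hmc), shared_genes=shared["n_shared"])
    else:
        record("annotate", skipped="disabled")

    # ---------------- colocalization ----------------
    if "coloc" in config.stages:
        region_df = calls["5hmC"][["chrom", "start", "end"]].reset_index(drop=True)
        if len(region_df) == 0:
            region_df = grid.head(5)
        loci, calls_scz, calls_hc, snp_truth = simulate.generate_snp_loci(
            genome, seeds[7], n_loci=config.n_loci,
            planted_fraction=config.planted_fraction, regions=region_df,
        )
        pairs, coloc_summary = colocalization.colocalize(region_df, loci)
        obs = colocalization.observed_distances(region_df, loci)
        null, _ = colocalization.simulate_null(genome, len(loci), region_df,
                                               reps=config.coloc_reps, seed=seeds[8])
        prox_p = colocalization.test_proximity(obs, null)
        spec = colocalization.specific_variants(calls_scz, calls_hc, loci)
        pairs.to_csv(out / "colocalization.tsv", sep="\t", index=False)
        (out / "proximity.json").write_text(json.dumps(
            {"p": prox_p, "reps": config.coloc_reps, "seed": seeds[8],
             "n_specific_variants": len(spec)}, indent=1))
        bundle.update(loci=loci, coloc_pairs=pairs, proximity_p=prox_p,
                      specific_variants=spec, snp_truth=snp_truth)
        record("coloc", pairs=coloc_summary["n_pairs"], proximity_p=round(prox_p, 6),
               specific_variants=len(spec))
    else:
        record("coloc", skipped="disabled")

    # ---------------- brain association ----------------
    imaging = cohort[cohort["has_imaging"]].reset_index(drop=True)
    if "brain" not in config.stages:
        record("brain", skipped="disabled")
        bundle["brain"] = None
    elif len(imaging) == 0:
        log.warning("brain stage skipped: no imaging samples")
        record("brain", skipped="no imaging samples")
        bundle["brain"] = None
    else:
        vst_5mc = vsts["5mC"]
        # linked "blocks": measure m shares the latent factor of the m-th
        # co-methylated block planted in the 5mC counts
        factors = counts["5mC"].attrs.get("latent_factors")
        if factors is not None and config.n_links > 0:
            link_map = [(b, b, config.link_strength) for b in range(config.n_links)]
            link_region_mat = np.asarray(factors).T  # samples x blocks
        else:
            link_map, link_region_mat = None, None
        measures, classes, brain_truth = simulate.generate_brain_measures(
            cohort, seeds[9], n_measures=config.n_measures, n_affected=config.n_affected,
            effect_size=config.brain_effect,
            link_map=link_map,
            region_matrix=link_region_mat,
            exclude_from_affected=range(config.n_links),
        )
        brain_truth.latent_blocks = truths["5mC"].latent_blocks
        meas_img = measures.loc[imaging["sample_id"]]
        resid = brain.Residualizer().fit_transform(meas_img, imaging, classes)
        gdiff = brain.group_difference(resid, imaging["group"].to_numpy(), alpha=config.fdr)
        atrophy = sorted(gdiff.index[gdiff["significant"] & (gdiff["direction"] < 0)])
        # called 5mC regions on the imaging subset, residualized for age+gender
        called_windows = calls["5mC"].index
        reg_img = vst_5mc.loc[called_windows, imaging["sample_id"].tolist()].T
        reg_resid = pd.DataFrame(
            {c: brain.residualize(reg_img[c].to_numpy(),
                                  brain.covariates_for_class(imaging, "CT"))
             for c in reg_img.columns}, index=reg_img.index)
        screen = brain.spearman_screen(reg_resid, resid, brain.COUNT_THRESHOLDS["5mC"],
                                       fdr=config.fdr)
        p_dim, q_dim = reg_resid.shape[1], resid.shape[1]
        grid_pen = brain.default_penalty_grid(p_dim, q_dim)
        c1, c2, zscore, no_signal = brain.scca_tune(reg_resid, resid, grid_pen,
                                                    n_perm=10, seed=seeds[10])
        scca = brain.SparseCCA(c1=c1, c2=c2, n_components=3, random_state=seeds[10])
        scca.fit(reg_resid.to_numpy(), resid.to_numpy())
        _, active_v = scca.active_sets()
        scca_measures = [resid.columns[i] for i in active_v]
        report = brain.intersect_findings(screen["retained"], scca_measures, atrophy,
                                          screen["significant"])
        gdiff.to_csv(out / "brain_group_diff.tsv", sep="\t")
        screen["significant"].to_csv(out / "brain_screen.tsv", sep="\t", index=False)
        (out / "scca.json").write_text(json.dumps(
            {"c1": c1, "c2": c2, "z": zscore, "no_signal": bool(no_signal),
             "d": scca.d_.tolist(), "correlations": scca.correlations_.tolist(),
             "reliable": report["reliable"], "atrophy_flagged": report["atrophy_flagged"]},
            indent=1))
        bundle["brain"] = {"measures": measures, "classes": classes, "truth": brain_truth,
                           "group_diff": gdiff, "screen": screen, "scca": scca,
                           "report": report, "atrophy": atrophy}
        record("brain", n_pairs=screen["n_pairs"], retained=len(screen["retained"]),
               scca_measures=len(scca_measures), reliable=len(report["reliable"]),
               atrophic=len(atrophy))

    # ---------------- severity ----------------
    if "severity" not in config.stages:
        record("severity", skipped="disabled")
        bundle["severity"] = None
        return _finish(out, manifest, bundle)
    feat_idx = calls["5mC"].index
    if len(feat_idx) >= 2:
        feats = vsts["5mC"].loc[feat_idx].T  # samples x regions
        scores, scorer = severity.fit_boosted_score(
            feats, cohort["group"].to_numpy(), repeats=config.severity_repeats,
            grid=config.severity_grid, seed=seeds[11])
        clinical = cohort.set_index("sample_id")[["panss_total", "bacs_z"]]
        corr = severity.correlate_severity(scores["score"], clinical)
        scores.to_csv(out / "severity_scores.tsv", sep="\t")
        (out / "severity_correlations.json").write_text(json.dumps(corr, indent=1))
        bundle["severity"] = {"scores": scores, "scorer": scorer, "correlations": corr}
        record("severity", samples=len(scores),
               rho_panss=round(corr["panss_total"]["rho"], 4),
               rho_bacs=round(corr["bacs_z"]["rho"], 4))
    else:
        record("severity", skipped="fewer than 2 called regions")
        bundle["severity"] = None

    return _finish(out, manifest, bundle)
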