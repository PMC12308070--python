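"""Generator contracts: determinism, injected-signal calibration, truth plumbing."""

import numpy as np
import pandas as pd
import pytest

from cfepiscan import simulate


class TestGenome:
    def test_same_seed_gives_identical_tracks(self):
        a = simulate.generate_genome(7, n_chrom=2, lengths=(200_000, 150_000))
        b = simulate.generate_genome(7, n_chrom=2, lengths=(200_000, 150_000))
        for attr in ("cpg_islands", "low_mappability", "dark_regions", "genes"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))

    def test_zero_dark_fraction_yields_no_dark_intervals(self):
        g = simulate.generate_genome(1, n_chrom=1, lengths=(1_000_000,), dark_fraction=0.0)
        assert len(g.dark_regions) == 0

    def test_low_mappability_fraction_is_respected(self):
        g = simulate.generate_genome(3, n_chrom=1, lengths=(5_000_000,),
                                     low_map_fraction=0.1, dark_fraction=0.0)
        masked = (g.low_mappability["end"] - g.low_mappability["start"]).sum()
        assert 0.08 <= masked / 5_000_000 <= 0.12

    def test_islands_do_not_overlap(self, genome):
        for _, sub in genome.cpg_islands.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_rejects_tiny_chromosome(self):
        with pytest.raises(ValueError, match="10 kb"):
            simulate.generate_genome(1, n_chrom=1, lengths=(5_000,))


class TestCohort:
    def test_default_design_sizes(self, cohort_full):
        assert (cohort_full["group"] == "HC").sum() == 77
        assert (cohort_full["group"] == "SCZ").sum() == 66
        img = cohort_full[cohort_full["has_imaging"]]
        assert (img["group"] == "HC").sum() == 68
        assert (img["group"] == "SCZ").sum() == 59
        assert (cohort_full["age"] > 0).all()

    def test_clinical_scores_track_latent_severity(self, cohort_full):
        scz = cohort_full[cohort_full["group"] == "SCZ"]
        from scipy.stats import spearmanr
        assert spearmanr(scz["severity"], scz["panss_total"]).statistic > 0.5
        assert spearmanr(scz["severity"], scz["bacs_z"]).statistic < -0.5


class TestCounts:
    def test_null_group_ratio_near_one(self, cohort_full):
        counts, _ = simulate.generate_counts(None, cohort_full, 5, n_true=0,
                                             n_windows=400, lfc_magnitude=0.0)
        K = counts.drop(columns=["chrom", "start", "end"])
        depth = counts.attrs["depth_factors"]
        norm = K.to_numpy() / depth[None, :]
        scz = cohort_full["group"].to_numpy() == "SCZ"
        ratio = norm[:, scz].mean(axis=1) / norm[:, ~scz].mean(axis=1)
        assert 0.95 <= np.median(ratio) <= 1.05

    def test_injected_lfc_reproduces_group_ratio(self, cohort_full):
        # one truth window, 200 replicate draws of the generator
        ratios = []
        for rep in range(200):
            counts, truth = simulate.generate_counts(
                None, cohort_full, 1000 + rep, n_true=1, n_windows=2,
                lfc_magnitude=1.0, frac_hyper=1.0, covariate_effects={},
                depth_factors=np.ones(143),
            )
            (widx, lfc), = truth.diff_windows.items()
            assert lfc == 1.0
            row = counts.drop(columns=["chrom", "start", "end"]).to_numpy()[widx]
            scz = cohort_full["group"].to_numpy() == "SCZ"
            ratios.append(row[scz].mean() / row[~scz].mean())
        assert 1.7 <= np.mean(ratios) <= 2.3

    def test_dispersion_matches_method_of_moments(self, cohort_full):
        counts, _ = simulate.generate_counts(None, cohort_full, 6, n_true=0,
                                             n_windows=2000, dispersion=0.2,
                                             covariate_effects={},
                                             depth_factors=np.ones(143))
        K = counts.drop(columns=["chrom", "start", "end"]).to_numpy().astype(float)
        mean = K.mean(axis=1)
        var = K.var(axis=1, ddof=1)
        mom = (var - mean) / mean**2
        assert 0.15 <= np.median(mom) <= 0.25

    def test_counts_are_nonnegative_integers(self, counts_small):
        K = counts_small[0].drop(columns=["chrom", "start", "end"]).to_numpy()
        assert (K >= 0).all() and np.issubdtype(K.dtype, np.integer)

    def test_truth_indices_exist(self, counts_small):
        counts, truth = counts_small
        assert max(truth.diff_windows) < len(counts)

    def test_rejects_bad_parameters(self, genome, cohort_small):
        with pytest.raises(ValueError, match="dispersion"):
            simulate.generate_counts(genome, cohort_small, 1, dispersion=0.0)
        with pytest.raises(ValueError, match="n_true"):
            simulate.generate_counts(None, cohort_small, 1, n_true=10, n_windows=5)


class TestFragments:
    def test_degenerate_mixture_gives_constant_length(self, genome, cohort_small):
        frags, _ = simulate.generate_fragments(
            cohort_small, genome, 8, depth=200,
            mixture_params={"weights_hc": (0, 1, 0), "weights_scz": (0, 1, 0),
                            "sds": (0.0, 0.0, 0.0)},
            out_of_range_fraction=0.0, sex_chrom_fraction=0.0,
        )
        for df in frags.values():
            assert ((df["end"] - df["start"]) == 166).all()

    def test_modal_length_is_mononucleosomal(self, genome, cohort_small):
        frags, _ = simulate.generate_fragments(cohort_small, genome, 9, depth=3000,
                                               out_of_range_fraction=0.0)
        lengths = np.concatenate([(df["end"] - df["start"]).to_numpy()
                                  for df in frags.values()])
        # discretization noise moves the argmax by a base or two around the
        # mono-nucleosomal peak
        assert abs(np.bincount(lengths).argmax() - 166) <= 2

    def test_group_short_fraction_difference_sign(self, genome, cohort_small):
        frags, _ = simulate.generate_fragments(
            cohort_small, genome, 10, depth=3000,
            mixture_params={"weights_hc": (0.25, 0.6, 0.15),
                            "weights_scz": (0.20, 0.6, 0.20)},
            out_of_range_fraction=0.0,
        )
        short = {}
        for sid, df in frags.items():
            lengths = (df["end"] - df["start"]).to_numpy()
            short[sid] = (lengths < 166).mean()
        groups = cohort_small.set_index("sample_id")["group"]
        f = pd.Series(short)
        assert f[groups == "SCZ"].mean() - f[groups == "HC"].mean() < 0

    def test_per_sample_depth_is_exact(self, genome, cohort_small):
        frags, _ = simulate.generate_fragments(cohort_small, genome, 11, depth=500)
        assert all(len(df) == 500 for df in frags.values())

    def test_negative_depth_rejected(self, genome, cohort_small):
        with pytest.raises(ValueError, match="depth"):
            simulate.generate_fragments(cohort_small, genome, 1, depth=-1)

    def test_bad_mixture_weights_rejected(self, genome, cohort_small):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate.generate_fragments(cohort_small, genome, 1,
                                        mixture_params={"weights_hc": (0.5, 0.1, 0.1)})


class TestBrainMeasures:
    def test_zero_effect_is_indistinguishable(self, cohort_full):
        from cfepiscan.brain import group_difference, Residualizer
        meas, classes, truth = simulate.generate_brain_measures(
            cohort_full, 12, n_measures=100, n_affected=20, effect_size=0.0)
        res = Residualizer().fit_transform(meas, cohort_full, classes)
        gd = group_difference(res, cohort_full["group"].to_numpy())
        assert (gd["pvalue"] < 0.05).mean() <= 0.08  # ~raw alpha
        assert gd["significant"].sum() <= 2

    def test_zero_link_strength_gives_no_correlation(self, cohort_full, rng):
        R = rng.normal(size=(143, 5))
        meas, _, _ = simulate.generate_brain_measures(
            cohort_full, 13, n_measures=30, n_affected=0, effect_size=0.0,
            link_map=[(i, i, 0.0) for i in range(5)], region_matrix=R)
        from scipy.stats import spearmanr
        rhos = [abs(spearmanr(R[:, i], meas.iloc[:, i]).statistic) for i in range(5)]
        assert np.median(rhos) < 0.1

    def test_icv_loading_removed_by_residualization(self, cohort_full):
        from cfepiscan.brain import residualize, covariates_for_class
        meas, _, _ = simulate.generate_brain_measures(
            cohort_full, 14, n_measures=80, n_affected=0, effect_size=0.0,
            icv_loading=1.0, age_loading=0.0, gender_loading=0.0, noise_sd=0.05)
        y = meas.iloc[:, 70].to_numpy()  # a CV-class measure scales with ICV
        C = covariates_for_class(cohort_full, "CV")
        resid = residualize(y, C, add_back_median=False)
        assert 1 - resid.var() / y.var() >= 0.95

    def test_link_map_validation(self, cohort_full, rng):
        with pytest.raises(ValueError, match="region"):
            simulate.generate_brain_measures(
                cohort_full, 1, n_measures=10, n_affected=0,
                link_map=[(99, 0, 1.0)], region_matrix=rng.normal(size=(143, 3)))
        with pytest.raises(ValueError, match="n_affected"):
            simulate.generate_brain_measures(cohort_full, 1, n_measures=5, n_affected=6)


class TestSnpLoci:
    def test_fully_planted_leads_fall_inside_regions(self, genome):
        regions = pd.DataFrame(
            [("chr1", 10_000, 10_500), ("chr2", 50_000, 50_500)],
            columns=["chrom", "start", "end"])
        loci, _, _, truth = simulate.generate_snp_loci(
            genome, 15, n_loci=10, planted_fraction=1.0, regions=regions)
        assert all(truth.planted_snps)
        for _, l in loci.iterrows():
            inside = ((regions["chrom"] == l["chrom"])
                      & (regions["start"] <= l["lead_pos"])
                      & (l["lead_pos"] < regions["end"]))
            assert inside.any()

    def test_injected_specific_calls_survive_filter(self, genome):
        from cfepiscan.colocalization import specific_variants
        loci, calls_scz, calls_hc, _ = simulate.generate_snp_loci(
            genome, 16, n_loci=12, n_specific=3, qual=50.0, depth=40)
        kept = specific_variants(calls_scz, calls_hc, loci)
        assert len(kept) == 3

    def test_planted_fraction_out_of_range(self, genome):
        with pytest.raises(ValueError, match="planted_fraction"):
            simulate.generate_snp_loci(genome, 1, planted_fraction=1.5)

    def test_lead_inside_locus(self, genome):
        loci, *_ = simulate.generate_snp_loci(genome, 17, n_loci=20)
        assert ((loci["start"] <= loci["lead_pos"]) & (loci["lead_pos"] < loci["end"])).all()


class TestLatentBlocks:
    def test_block_windows_are_co_methylated(self, cohort_full):
        counts, truth = simulate.generate_counts(
            None, cohort_full, 55, n_true=16, n_windows=500,
            n_latent_blocks=2, latent_block_size=8, covariate_effects={},
            depth_factors=np.ones(143))
        assert len(truth.latent_blocks) == 2
        K = counts.drop(columns=["chrom", "start", "end"]).to_numpy(float)
        factors = counts.attrs["latent_factors"]
        for b, block in enumerate(truth.latent_blocks):
            assert len(block) == 8
            # each block window's log-counts track the block factor
            for w in block[:3]:
                rho = np.corrcoef(np.log1p(K[w]), factors[b])[0, 1]
                assert rho > 0.3

    def test_block_factors_deterministic(self, cohort_full):
        a, ta = simulate.generate_counts(None, cohort_full, 56, n_true=16,
                                         n_windows=300, n_latent_blocks=2)
        b, tb = simulate.generate_counts(None, cohort_full, 56, n_true=16,
                                         n_windows=300, n_latent_blocks=2)
        np.testing.assert_array_equal(a.attrs["latent_factors"],
                                      b.attrs["latent_factors"])
        assert ta.latent_blocks == tb.latent_blocks

    def test_too_few_truth_windows_for_blocks(self, cohort_full):
        with pytest.raises(ValueError, match="latent blocks"):
            simulate.generate_counts(None, cohort_full, 1, n_true=5,
                                     n_windows=100, n_latent_blocks=2,
                                     latent_block_size=8)
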