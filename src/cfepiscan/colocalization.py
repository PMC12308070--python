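"""Colocalization of differential regions with GWAS loci and the
randomized-SNP proximity null.

A region colocalizes with a locus when the two intervals overlap by at
least one base.  To ask whether regions sit closer to risk SNPs than
chance allows, SNPs are re-placed uniformly over the unmasked genome many
times; each simulated SNP's distance to its nearest region forms the null
sample against which the observed distances are compared with a one-sided
rank-sum test.  SCZ-specific variants are calls passing quality/depth
gates that match a lead SNP's position and alleles exactly and appear in
the SCZ cohort but not the HC cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "colocalize",
    "region_snp_distance",
    "simulate_null",
    "observed_distances",
    "test_proximity",
    "specific_variants",
]


def colocalize(regions, loci):
    """(region, locus) pairs overlapping by >= 1 bp, plus summary counts."""
    pairs = []
    for rid, r in regions.iterrows():
        hits = loci[
            (loci["chrom"] == r["chrom"]) & (loci["start"] < r["end"]) & (loci["end"] > r["start"])
        ]
        for lid, l in hits.iterrows():
            pairs.append({"region": rid, "locus": l["label"], "lead_pos": l["lead_pos"]})
    pairs = pd.DataFrame(pairs, columns=["region", "locus", "lead_pos"])
    summary = {
        "n_pairs": len(pairs),
        "n_regions": pairs["region"].nunique(),
        "n_lead_snps": pairs[["locus", "lead_pos"]].drop_duplicates().shape[0],
    }
    return pairs, summary


def region_snp_distance(start, end, pos):
    """bp distance between a half-open region [start, end) and a 0-based SNP
    position; 0 when the SNP lies inside the region."""
    return int(max(start - pos, pos - (end - 1), 0))


def _nearest_region_distance(positions, chroms, regions):
    """Distance of each SNP to its nearest region (inf when none share the chrom)."""
    out = np.full(len(positions), np.inf)
    for chrom in np.unique(chroms):
        sub = regions[regions["chrom"] == chrom]
        sel = np.flatnonzero(np.asarray(chroms) == chrom)
        if len(sub) == 0 or len(sel) == 0:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        pos = np.asarray(positions)[sel]
        # distance to nearest region on a sorted grid of region edges
        i = np.searchsorted(starts, pos, side="right")
        d_left = np.where(i > 0, pos - (ends[np.maximum(i - 1, 0)] - 1), np.inf)
        d_right = np.where(i < len(starts), starts[np.minimum(i, len(starts) - 1)] - pos, np.inf)
        out[sel] = np.maximum(np.minimum(d_left, d_right), 0)
    return out


def observed_distances(regions, loci, direction="snp_to_region"):
    """Observed distances between lead SNPs and regions.

    ``snp_to_region`` (default): each lead SNP to its nearest region —
    matching the direction used for the simulated null.  ``region_to_snp``:
    each region to its nearest lead SNP.
    """
    if direction == "snp_to_region":
        return _nearest_region_distance(
            loci["lead_pos"].to_numpy(), loci["chrom"].to_numpy(), regions
        )
    if direction == "region_to_snp":
        dists = np.full(len(regions), np.inf)
        for i, (_, r) in enumerate(regions.iterrows()):
            same = loci[loci["chrom"] == r["chrom"]]
            if len(same) == 0:
                continue
            dists[i] = min(
                region_snp_distance(r["start"], r["end"], p) for p in same["lead_pos"]
            )
        return dists
    raise ValueError(f"unknown direction {direction!r}")


def _unmasked_segments(genome):
    """Per-chromosome unmasked segments (complement of the dark regions)."""
    segments = []
    for chrom, length in genome.chromosomes:
        dark = genome.dark_regions[genome.dark_regions["chrom"] == chrom].sort_values("start")
        cur = 0
        for _, d in dark.iterrows():
            if d["start"] > cur:
                segments.append((chrom, cur, int(d["start"])))
            cur = max(cur, int(d["end"]))
        if cur < length:
            segments.append((chrom, cur, length))
    return segments


def simulate_null(genome, n_snps, regions, reps=1000, seed=0):
    """Null distances: place ``n_snps`` uniformly over unmasked bases per rep
    and record each simulated SNP's distance to its nearest region.

    Returns an array of shape (reps, n_snps); deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    segs = _unmasked_segments(genome)
    if not segs:
        raise ValueError("genome has no unmasked bases")
    seg_len = np.array([e - s for _, s, e in segs], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    total = cum[-1]
    draws = rng.integers(0, total, size=reps * n_snps)
    seg_idx = np.searchsorted(cum, draws, side="right") - 1
    offs = draws - cum[seg_idx]
    seg_starts = np.array([s for _, s, _ in segs], dtype=np.int64)
    seg_chroms = np.array([c for c, _, _ in segs], dtype=object)
    positions = seg_starts[seg_idx] + offs
    chroms = seg_chroms[seg_idx]
    d = _nearest_region_distance(positions, chroms, regions)
    out = d.reshape(reps, n_snps)
    out_meta = {"positions": positions.reshape(reps, n_snps), "chroms": chroms.reshape(reps, n_snps)}
    return out, out_meta


def test_proximity(observed, null, alternative="less"):
    """One-sided rank-sum p that observed distances are stochastically smaller
    than the pooled null (tie-corrected normal approximation)."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float).ravel()
    observed = observed[np.isfinite(observed)]
    null = null[np.isfinite(null)]
    if observed.size == 0 or null.size == 0:
        raise ValueError("both distance samples must be non-empty")
    res = stats.mannwhitneyu(observed, null, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def specific_variants(calls_scz, calls_hc, lead_snps, qual_min=30, depth_min=30):
    """SCZ-exclusive variants matching lead SNPs.

    Keeps SCZ-cohort calls with qual > qual_min and depth > depth_min whose
    (chrom, pos, ref, alt) exactly matches a lead SNP and which have no HC
    call at the same (chrom, pos, ref, alt).
    """
    for df, name in ((calls_scz, "SCZ"), (calls_hc, "HC")):
        if len(df) and (df["ref"].astype(str).str.len().eq(0).any()
                        or df["alt"].astype(str).str.len().eq(0).any()):
            raise ValueError(f"malformed alleles in {name} calls")
    key = ["chrom", "pos", "ref", "alt"]
    lead_keys = set(map(tuple, lead_snps[["chrom", "lead_pos", "ref", "alt"]].to_numpy()))
    hc_keys = set(map(tuple, calls_hc[key].to_numpy())) if len(calls_hc) else set()
    keep = []
    for _, c in calls_scz.iterrows():
        if c["qual"] <= qual_min or c["depth"] <= depth_min:
            continue
        tup = (c["chrom"], c["pos"], c["ref"], c["alt"])
        if tup in lead_keys and tup not in hc_keys:
            keep.append(c)
    return pd.DataFrame(keep, columns=calls_scz.columns).reset_index(drop=True)
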