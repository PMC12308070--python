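"""Genome-wide sliding-window grid, window filters and fragment counting.

The grid tiles each autosome with 500 bp windows advancing in 250 bp steps
(partial terminal windows are dropped so all windows share one width).
Windows overlapping low-mappability sequence (base-weighted mean score
< 0.9) or any dark region are removed, and windows without more than three
fragments in at least ten samples are treated as low-coverage.  "Coverage"
is fragment-overlap counting: a fragment increments every window it
overlaps by at least one base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "make_windows",
    "make_grid",
    "filter_windows",
    "count_fragments",
    "counts_matrix",
    "low_coverage_filter",
    "modality_correlation",
    "genome_fraction",
]

WINDOW = 500
STEP = 250
MAP_THRESHOLD = 0.9
MIN_COUNT_EXCLUSIVE = 3
MIN_SAMPLES = 10


def make_windows(chrom_length, w=WINDOW, s=STEP):
    """Window start positions [k*s, k*s+w) with k*s+w <= chrom_length."""
    if w <= 0 or s <= 0:
        raise ValueError("window and step must be positive")
    if s > w:
        raise ValueError("step must not exceed window width")
    n = (chrom_length - w) // s + 1 if chrom_length >= w else 0
    starts = np.arange(n, dtype=np.int64) * s
    return starts


def make_grid(chromosomes, w=WINDOW, s=STEP):
    """Full-genome window grid as a DataFrame (chrom, start, end)."""
    frames = []
    for name, length in chromosomes:
        starts = make_windows(length, w, s)
        frames.append(pd.DataFrame({"chrom": name, "start": starts, "end": starts + w}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _interval_overlap_per_window(starts, w, track_starts, track_ends, values=None):
    """Base-weighted sum of ``values`` (or overlap bp) over each window [s, s+w)."""
    out = np.zeros(len(starts), dtype=float)
    for ts, te, v in zip(
        track_starts, track_ends, values if values is not None else np.ones(len(track_starts))
    ):
        ov = np.minimum(starts + w, te) - np.maximum(starts, ts)
        np.maximum(ov, 0, out=ov)
        out += ov * v
    return out


def filter_windows(grid, mappability_track, dark_regions, map_threshold=MAP_THRESHOLD, chrom_sizes=None):
    """Boolean keep-mask: drop windows with mean mappability < threshold or
    any (>=1 bp) dark-region overlap.

    ``mappability_track`` lists intervals with score in [0, 1]; bases not
    covered score 1.  The window mean is base-weighted.
    """
    if chrom_sizes is not None:
        for df in (mappability_track, dark_regions):
            if len(df) == 0:
                continue
            limits = df["chrom"].map(chrom_sizes)
            if limits.isna().any() or (df["end"] > limits).any() or (df["start"] < 0).any():
                raise ValueError("track interval outside chromosome bounds")
    keep = np.ones(len(grid), dtype=bool)
    for chrom, sub in grid.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        w = int((sub["end"] - sub["start"]).iloc[0])
        mt = mappability_track[mappability_track["chrom"] == chrom]
        if len(mt):
            # penalty relative to the default score of 1 per base
            deficit = _interval_overlap_per_window(
                starts, w, mt["start"].to_numpy(), mt["end"].to_numpy(),
                1.0 - mt["score"].to_numpy(),
            )
            mean_map = 1.0 - deficit / w
            keep[idx] &= mean_map >= map_threshold
        dk = dark_regions[dark_regions["chrom"] == chrom]
        if len(dk):
            ov = _interval_overlap_per_window(
                starts, w, dk["start"].to_numpy(), dk["end"].to_numpy()
            )
            keep[idx] &= ov == 0
    return keep


def count_fragments(grid, fragments, w=None, s=None):
    """Fragment-overlap counts per window (a fragment may hit several windows).

    Exploits the regular grid: fragment [f0, f1) overlaps window k iff
    k*s < f1 and k*s + w > f0.  Raises on fragments from chromosomes absent
    from the grid.
    """
    counts = np.zeros(len(grid), dtype=np.int64)
    grid_chroms = {}
    for chrom, sub in grid.groupby("chrom", sort=False):
        ww = int((sub["end"] - sub["start"]).iloc[0]) if w is None else w
        ss = int(np.diff(sub["start"].to_numpy()).min()) if s is None and len(sub) > 1 else (s or ww)
        grid_chroms[chrom] = (sub.index.to_numpy(), sub["start"].to_numpy(), ww, ss)
    unknown = set(fragments["chrom"]) - set(grid_chroms)
    if unknown:
        raise ValueError(f"fragment chromosome(s) not in grid: {sorted(unknown)}")
    for chrom, sub in fragments.groupby("chrom", sort=False):
        idx, starts, ww, ss = grid_chroms[chrom]
        n_win = len(starts)
        f0 = sub["start"].to_numpy()
        f1 = sub["end"].to_numpy()
        k_min = np.maximum(0, (f0 - ww) // ss + 1)
        k_max = np.minimum(n_win - 1, (f1 - 1) // ss)
        valid = k_min <= k_max
        # range-increment via difference array
        diff = np.zeros(n_win + 1, dtype=np.int64)
        np.add.at(diff, k_min[valid], 1)
        np.add.at(diff, k_max[valid] + 1, -1)
        counts[idx] += np.cumsum(diff[:-1])
    return counts


def counts_matrix(grid, fragments_by_sample, modality="5mC"):
    """Assemble the windows x samples counts DataFrame over filtered fragments."""
    out = grid.reset_index(drop=True).copy()
    out.index = [f"w{i:06d}" for i in range(len(out))]
    out.index.name = "window"
    for sid, frag in fragments_by_sample.items():
        out[sid] = count_fragments(grid.reset_index(drop=True), frag)
    out.attrs["modality"] = modality
    return out


def low_coverage_filter(K, min_count_exclusive=MIN_COUNT_EXCLUSIVE, min_samples=MIN_SAMPLES):
    """Keep windows with more than ``min_count_exclusive`` counts in at least
    ``min_samples`` samples (pooled over both groups)."""
    K = np.asarray(K)
    if K.shape[1] < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples for the low-coverage filter, got {K.shape[1]}"
        )
    return (K > min_count_exclusive).sum(axis=1) >= min_samples


def modality_correlation(K_5mC, K_5hmC, groups=None, min_windows=10):
    """Per-sample Spearman correlation of 5mC vs 5hmC counts over shared windows.

    Matrices are intersected on their window index and sample columns first.
    Returns ``(per_sample, summary)`` where summary holds the median rho per
    group (or overall when no groups are given).
    """
    shared_w = K_5mC.index.intersection(K_5hmC.index)
    meta = {"chrom", "start", "end"}
    samples = [c for c in K_5mC.columns if c in set(K_5hmC.columns) and c not in meta]
    if len(shared_w) < min_windows:
        raise ValueError(f"fewer than {min_windows} shared windows")
    a = K_5mC.loc[shared_w, samples].to_numpy(float)
    b = K_5hmC.loc[shared_w, samples].to_numpy(float)
    rho = np.array([stats.spearmanr(a[:, j], b[:, j]).statistic for j in range(len(samples))])
    per_sample = pd.Series(rho, index=samples, name="rho")
    if groups is not None:
        g = pd.Series(np.asarray(groups), index=samples)
        summary = per_sample.groupby(g).median().to_dict()
    else:
        summary = {"all": float(per_sample.median())}
    return per_sample, summary


def genome_fraction(grid, mask, genome_length):
    """Percentage of the genome covered by the union of retained windows."""
    kept = grid.loc[np.asarray(mask)]
    total = 0
    for _, sub in kept.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        starts = s["start"].to_numpy()
        ends = s["end"].to_numpy()
        # union of sorted, possibly overlapping windows
        run_end = -1
        for st, en in zip(starts, ends):
            if st >= run_end:
                total += en - st
                run_end = en
            elif en > run_end:
                total += en - run_end
                run_end = en
    return 100.0 * total / genome_length
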