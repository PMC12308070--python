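"""Fragment filtering, length profiling, spike-in capture efficiency and
group comparisons of fragment-level statistics.

cfDNA fragments arrive as BED-like interval tables (chrom, start, end;
0-based half-open).  Analysis keeps properly sized fragments (20-1000 bp
insert) on autosomes, profiles lengths against the nucleosomal structure of
cfDNA (mono-nucleosome peak at 166 bp, di-nucleosome at 332 bp) and compares
per-sample summary statistics between groups with rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LengthProfile",
    "GroupComparison",
    "read_fragment_bed",
    "filter_fragments",
    "length_fractions",
    "capture_efficiency",
    "compare_groups",
    "qc_table",
]

MIN_LEN = 20
MAX_LEN = 1000
SHORT_BOUND = 166  # short: < 166 bp
LONG_BOUND = 332  # long: > 332 bp; medial is inclusive [166, 332]


@dataclass
class LengthProfile:
    """Per-sample fragment-length summary on filtered fragments."""

    n_fragments: int
    modal_length: int
    f_short: float
    f_medial: float
    f_long: float


@dataclass
class GroupComparison:
    """Two-group rank-sum comparison with standardized effect size.

    ``d`` is Cohen's d with pooled SD, signed SCZ - HC; ``power`` is the
    two-sample t-test power at that d and the given group sizes.
    """

    statistic: float
    pvalue: float
    d: float
    power: float


def read_fragment_bed(path):
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    return df


def filter_fragments(records, autosomes, min_len=MIN_LEN, max_len=MAX_LEN):
    """Keep fragments with min_len <= length <= max_len on an autosome.

    Returns ``(kept, removed)`` where ``removed`` counts exclusions per
    reason.  Raises on malformed records (start >= end), naming the row.
    """
    records = records.reset_index(drop=True)
    if len(records) == 0:
        return records.copy(), {"too_short": 0, "too_long": 0, "non_autosome": 0}
    bad = records["start"] >= records["end"]
    if bad.any():
        raise ValueError(f"malformed fragment at row {int(np.flatnonzero(bad)[0])}: start >= end")
    length = records["end"] - records["start"]
    auto = records["chrom"].isin(set(autosomes))
    too_short = length < min_len
    too_long = length > max_len
    keep = auto & ~too_short & ~too_long
    removed = {
        "too_short": int((too_short & auto).sum()),
        "too_long": int((too_long & auto).sum()),
        "non_autosome": int((~auto).sum()),
    }
    return records.loc[keep].reset_index(drop=True), removed


def length_fractions(lengths):
    """Fractions of short (<166), medial (166-332 inclusive) and long (>332) fragments."""
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("cannot compute length fractions of an empty fragment set")
    n = lengths.size
    f_short = np.count_nonzero(lengths < SHORT_BOUND) / n
    f_long = np.count_nonzero(lengths > LONG_BOUND) / n
    return f_short, 1.0 - f_short - f_long, f_long


def length_profile(records):
    lengths = (records["end"] - records["start"]).to_numpy()
    f_s, f_m, f_l = length_fractions(lengths)
    modal = int(np.bincount(lengths).argmax())
    return LengthProfile(len(lengths), modal, f_s, f_m, f_l)


def capture_efficiency(reads_unmodified, reads_5mC, reads_5hmC, modality):
    """Ratio of reads from the modality-matched spike-in species to all spike-in reads."""
    total = reads_unmodified + reads_5mC + reads_5hmC
    if total <= 0:
        raise ZeroDivisionError("no spike-in reads: capture efficiency undefined")
    if modality == "5mC":
        return reads_5mC / total
    if modality == "5hmC":
        return reads_5hmC / total
    raise ValueError(f"unknown modality {modality!r}")


def compare_groups(values_hc, values_scz, alpha=0.05):
    """Two-sided rank-sum comparison (SCZ vs HC) with Cohen's d and power.

    Uses the exact rank-sum null for small samples without ties and the
    tie-corrected normal approximation otherwise.  ``d`` uses the pooled SD
    and is undefined (error) when the pooled values are constant.
    """
    from .differential import region_power

    x = np.asarray(values_hc, dtype=float)
    y = np.asarray(values_scz, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
    if sp2 == 0:
        if np.array_equal(x, y[: x.size]) and x.size == y.size:
            return GroupComparison(float(x.size * y.size / 2), 1.0, 0.0, alpha)
        raise ValueError("pooled values are constant: effect size undefined")
    res = stats.mannwhitneyu(y, x, alternative="two-sided", method="auto")
    d = (y.mean() - x.mean()) / np.sqrt(sp2)
    power = region_power(abs(d), y.size, x.size, alpha)
    return GroupComparison(float(res.statistic), float(res.pvalue), float(d), float(power))


def qc_table(fragments_by_sample, spike_df, modality, autosomes):
    """Per-sample QC summary: fragment counts, modal length, fractions, capture efficiency."""
    rows = []
    for sid, frag in fragments_by_sample.items():
        kept, removed = filter_fragments(frag, autosomes)
        prof = length_profile(kept)
        sp = spike_df.loc[spike_df["sample_id"] == sid].iloc[0]
        eff = capture_efficiency(
            int(sp["reads_unmodified"]), int(sp["reads_5mC"]), int(sp["reads_5hmC"]), modality
        )
        rows.append(
            {
                "sample_id": sid,
                "n_fragments": prof.n_fragments,
                "n_removed": sum(removed.values()),
                "modal_length": prof.modal_length,
                "f_short": prof.f_short,
                "f_medial": prof.f_medial,
                "f_long": prof.f_long,
                "capture_efficiency": eff,
            }
        )
    return pd.DataFrame(rows)
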