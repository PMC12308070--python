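"""Region annotation (CpG rings, genic features) and set enrichment.

CpG classes follow the island/shore/shelf ring convention: a region
overlapping an island is "island"; otherwise its midpoint distance to the
nearest island edge places it in "shore" (< 2 kb), "shelf" (2-4 kb) or
"interCGI".  Promoters are the 1 kb strand-aware upstream flank of the TSS.
Enrichment uses upper-tail hypergeometric tests (two-sided reported as the
doubled smaller tail, capped at 1) and 2x2 Fisher exact tests, both with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "cpg_annotate",
    "genic_annotate",
    "annotate_regions",
    "regions_to_genes",
    "hypergeom_enrich",
    "fisher_tissue_enrich",
    "overlap_test",
]

SHORE_BP = 2000
SHELF_BP = 4000
PROMOTER_LEN = 1000
GENIC_PRECEDENCE = ("promoter", "exon", "intron", "intergenic")


@dataclass
class EnrichmentResult:
    name: str
    k: int
    query_size: int
    set_size: int
    universe_size: int
    odds_ratio: float
    p_upper: float
    pvalue: float
    padj: float = np.nan


def _overlaps(start, end, istarts, iends):
    return np.any((istarts < end) & (iends > start))


def cpg_annotate(region, islands):
    """CpG class of a (chrom, start, end) region against non-overlapping islands."""
    chrom, start, end = region[0], int(region[1]), int(region[2])
    isl = islands[islands["chrom"] == chrom]
    if len(isl) == 0:
        return "interCGI"
    istarts = isl["start"].to_numpy()
    iends = isl["end"].to_numpy()
    if _overlaps(start, end, istarts, iends):
        return "island"
    mid = (start + end) // 2
    dist = np.minimum(np.abs(mid - istarts), np.abs(mid - iends)).min()
    if dist < SHORE_BP:
        return "shore"
    if dist < SHELF_BP:
        return "shelf"
    return "interCGI"


def promoter_interval(tss, strand, promoter_len=PROMOTER_LEN):
    """Strand-aware promoter: [TSS-len, TSS) for +, (TSS, TSS+len] for -."""
    tss = int(tss)
    if strand == "+":
        return max(0, tss - promoter_len), tss
    return tss + 1, tss + 1 + promoter_len


def genic_annotate(region, genes, promoter_len=PROMOTER_LEN):
    """Genic classes of a region and the gene ids it touches.

    A region may carry several classes (promoter/exon/intron); it is
    "intergenic" only when it overlaps no gene body or promoter.
    """
    chrom, start, end = region[0], int(region[1]), int(region[2])
    classes, gene_ids = set(), []
    sub = genes[genes["chrom"] == chrom]
    for _, g in sub.iterrows():
        hit = False
        ps, pe = promoter_interval(g["tss"], g["strand"], promoter_len)
        if ps < end and pe > start:
            classes.add("promoter")
            hit = True
        if g["start"] < end and g["end"] > start:
            hit = True
            in_exon = any(es < end and ee > start for es, ee in g["exons"])
            classes.add("exon" if in_exon else "intron")
        if hit:
            gene_ids.append(g["gene_id"])
    if not classes:
        classes = {"intergenic"}
    return sorted(classes), gene_ids


def annotate_regions(regions, genome, promoter_len=PROMOTER_LEN):
    """Annotation table for a regions DataFrame (chrom, start, end)."""
    sizes = genome.chrom_sizes
    bad = genome.genes[
        (genome.genes["tss"] < 0)
        | (genome.genes["tss"] >= genome.genes["chrom"].map(sizes).fillna(-1))
    ]
    if len(bad):
        raise ValueError(f"gene TSS outside chromosome: {bad['gene_id'].tolist()}")
    rows = []
    for rid, r in regions.iterrows():
        reg = (r["chrom"], r["start"], r["end"])
        cpg = cpg_annotate(reg, genome.cpg_islands)
        classes, gids = genic_annotate(reg, genome.genes, promoter_len)
        primary = next(c for c in GENIC_PRECEDENCE if c in classes)
        gene_types = sorted(
            set(genome.genes.set_index("gene_id").loc[gids, "gene_type"]) if gids else []
        )
        rows.append(
            {
                "region": rid,
                "cpg_class": cpg,
                "genic_classes": ",".join(classes),
                "genic_primary": primary,
                "genes": ",".join(gids),
                "gene_types": ",".join(gene_types),
            }
        )
    return pd.DataFrame(rows).set_index("region")


def regions_to_genes(regions, genome, promoter_len=PROMOTER_LEN):
    """Unique gene ids whose body or promoter overlaps >= 1 region."""
    hit = set()
    for _, r in regions.iterrows():
        _, gids = genic_annotate((r["chrom"], r["start"], r["end"]), genome.genes, promoter_len)
        hit.update(gids)
    return sorted(hit)


def shared_gene_summary(genes_a, genes_b):
    """Genes carrying both region types, with percentages of each gene set."""
    a, b = set(genes_a), set(genes_b)
    shared = a & b
    return {
        "shared": sorted(shared),
        "n_shared": len(shared),
        "pct_of_a": 100.0 * len(shared) / len(a) if a else 0.0,
        "pct_of_b": 100.0 * len(shared) / len(b) if b else 0.0,
    }


def _hypergeom_tails(k, N, K_set, n_query):
    upper = stats.hypergeom.sf(k - 1, N, K_set, n_query)
    lower = stats.hypergeom.cdf(k, N, K_set, n_query)
    two = min(1.0, 2.0 * min(upper, lower))
    return float(upper), float(two)


def hypergeom_enrich(query_genes, gene_sets, universe_size):
    """Hypergeometric over-representation of the query in each gene set.

    ``gene_sets`` maps set name -> gene list.  Reports the upper tail
    P(X >= k) and the two-sided p (doubled smaller tail), with BH over sets
    applied to the two-sided p.
    """
    query = set(query_genes)
    if len(query) > universe_size:
        raise ValueError("query larger than universe")
    results = []
    for name, members in gene_sets.items():
        members = set(members)
        if len(members) > universe_size:
            raise ValueError(f"gene set {name!r} larger than universe")
        k = len(query & members)
        upper, two = _hypergeom_tails(k, universe_size, len(members), len(query))
        results.append(
            EnrichmentResult(name, k, len(query), len(members), universe_size, np.nan, upper, two)
        )
    if results:
        padj = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, pa in zip(results, padj):
            r.padj = float(pa)
    return results


def fisher_tissue_enrich(query_genes, tissue_panels, universe_size):
    """Per-tissue 2x2 Fisher exact enrichment with odds ratios and BH."""
    query = set(query_genes)
    results = []
    for name, panel in tissue_panels.items():
        panel = set(panel)
        if not panel:
            warnings.warn(f"empty tissue panel {name!r} skipped", stacklevel=2)
            continue
        k = len(query & panel)
        table = [
            [k, len(query) - k],
            [len(panel) - k, universe_size - len(query) - len(panel) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        upper, two = _hypergeom_tails(k, universe_size, len(panel), len(query))
        results.append(
            EnrichmentResult(
                name, k, len(query), len(panel), universe_size, float(odds), float(p), float(p)
            )
        )
    if results:
        padj = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, pa in zip(results, padj):
            r.padj = float(pa)
    return results


def overlap_test(genes_a, genes_b, universe_size):
    """Upper-tail hypergeometric p for the intersection of two gene lists."""
    a, b = set(genes_a), set(genes_b)
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def enrichment_table(results):
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "k": r.k,
                "query_size": r.query_size,
                "set_size": r.set_size,
                "universe_size": r.universe_size,
                "odds_ratio": r.odds_ratio,
                "p_upper": r.p_upper,
                "pvalue": r.pvalue,
                "padj": r.padj,
            }
            for r in results
        ]
    )
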