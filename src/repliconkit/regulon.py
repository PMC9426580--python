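"""Cross-strain differential-expression structure.

Given per-strain DE tables (gene, log2 fold change, p-value) against a common
reference, this module computes the pieces used to compare plasmid-response
regulons across strains: significant gene sets, the disjoint Venn partition
of up to four sets, whole-transcriptome fold-change correlation, upper-tail
hypergeometric category enrichment with Benjamini-Hochberg adjustment, and
RPKM expression summaries per replicon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

from .io import DETable

__all__ = [
    "SignificantSet",
    "significant_set",
    "VennPartition",
    "venn",
    "fc_correlation",
    "EnrichmentResult",
    "enrichment",
    "rpkm_summary",
]


@dataclass
class SignificantSet:
    strain: str
    genes: frozenset[str]
    alpha: float
    fc_threshold: float
    adjusted: bool


def significant_set(
    table: DETable,
    alpha: float = 0.05,
    fc_threshold: float = 0.0,
    adjust: bool = False,
    replicon_id: str | None = None,
) -> SignificantSet:
    """Genes with p <= alpha and |log2FC| >= fc_threshold.

    With ``adjust=True`` p-values are Benjamini-Hochberg corrected before
    thresholding.  ``replicon_id`` restricts the table to one replicon (e.g.
    chromosomal genes only) before selection.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = table.data
    if replicon_id is not None:
        df = df[df["replicon_id"] == replicon_id]
    pvals = df["pvalue"].to_numpy()
    if adjust and len(pvals):
        pvals = multipletests(pvals, method="fdr_bh")[1]
    keep = (pvals <= alpha) & (df["log2fc"].abs().to_numpy() >= fc_threshold)
    return SignificantSet(
        strain=table.strain,
        genes=frozenset(df["gene_id"].to_numpy()[keep]),
        alpha=alpha,
        fc_threshold=fc_threshold,
        adjusted=adjust,
    )


@dataclass
class VennPartition:
    """Disjoint region counts for k sets, keyed by membership mask.

    Mask "101" counts elements in the first and third set but not the second
    (set order as supplied).
    """

    set_labels: list[str]
    regions: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def count(self, mask: str) -> int:
        return self.regions.get(mask, 0)


def venn(sets: dict[str, "frozenset[str] | set[str]"]) -> VennPartition:
    """Disjoint Venn regions of 2 to 4 labelled sets."""
    labels = list(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn supports 2 to 4 sets")
    universe = set().union(*sets.values())
    regions = {
        "".join(m): 0 for m in product("01", repeat=len(labels)) if "1" in m
    }
    for element in universe:
        mask = "".join("1" if element in sets[lab] else "0" for lab in labels)
        regions[mask] += 1
    return VennPartition(set_labels=labels, regions=regions)


def fc_correlation(x: DETable, y: DETable) -> dict:
    """Pearson correlation of log2 fold changes over shared genes.

    Returns r, the two-sided p-value, the number of shared genes, and how
    many genes of each table had no partner.  Zero variance in either vector
    makes r undefined (reported as NaN).
    """
    merged = x.data.merge(y.data, on="gene_id", suffixes=("_x", "_y"))
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need at least 3")
    vx = merged["log2fc_x"].to_numpy()
    vy = merged["log2fc_y"].to_numpy()
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        warnings.warn("zero variance in a fold-change vector; correlation undefined")
        r, p = float("nan"), float("nan")
    else:
        r, p = pearsonr(vx, vy)
    return {
        "r": float(r),
        "pvalue": float(p),
        "n_shared": n,
        "only_in_x": len(x.data) - n,
        "only_in_y": len(y.data) - n,
    }


@dataclass
class EnrichmentResult:
    category: str
    population_size: int
    category_size: int
    draw_size: int
    overlap: int
    pvalue: float
    qvalue: float


def enrichment(
    significant: SignificantSet,
    categories: dict[str, "set[str] | frozenset[str]"],
    population: "set[str] | frozenset[str]",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of categories in a gene set.

    For each category with K members in a population of N genes and a
    significant set of n genes overlapping it in k, the p-value is
    P(X >= k) for X ~ Hypergeom(N, K, n); q-values are Benjamini-Hochberg
    across the tested categories.
    """
    population = set(population)
    if not set(significant.genes) <= population:
        raise ValueError("significant set must be a subset of the population")
    N, n = len(population), len(significant.genes)
    rows = []
    for cat in sorted(categories):
        members = set(categories[cat]) & population
        K = len(members)
        if K == 0:
            warnings.warn(f"category {cat!r} has no members in the population; skipped")
            continue
        k = len(members & significant.genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, N, K, n, k, p))
    if not rows:
        return []
    qvals = multipletests([r[5] for r in rows], method="fdr_bh")[1]
    return [
        EnrichmentResult(
            category=cat, population_size=N, category_size=K, draw_size=n,
            overlap=k, pvalue=p, qvalue=float(q),
        )
        for (cat, N, K, n, k, p), q in zip(rows, qvals)
    ]


def rpkm_summary(
    counts: pd.DataFrame,
    chromosome_id: str | None = None,
    library_size: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene RPKM and per-replicon medians from a read-count table.

    ``counts`` needs columns gene_id, replicon_id, reads, length_bp.  RPKM is
    reads * 1e9 / (length_bp * total mapped reads); the library size defaults
    to the column total but may be supplied (e.g. total mapped reads
    including features outside the table).  The replicon summary reports the
    median RPKM per replicon and, when ``chromosome_id`` is given, each
    replicon's median relative to the chromosome's.
    """
    required = {"gene_id", "replicon_id", "reads", "length_bp"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    if (counts["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be positive")
    total = counts["reads"].sum() if library_size is None else library_size
    if total <= 0:
        raise ValueError("library size (total mapped reads) must be positive")
    per_gene = counts.copy()
    per_gene["rpkm"] = per_gene["reads"] * 1e9 / (per_gene["length_bp"] * total)
    summary = (
        per_gene.groupby("replicon_id")["rpkm"].median().rename("median_rpkm").reset_index()
    )
    if chromosome_id is not None:
        if chromosome_id not in summary["replicon_id"].values:
            raise ValueError(f"chromosome id {chromosome_id!r} not in counts table")
        chrom_med = float(
            summary.loc[summary["replicon_id"] == chromosome_id, "median_rpkm"].iloc[0]
        )
        summary["ratio_to_chromosome"] = summary["median_rpkm"] / chrom_med
    return per_gene, summary
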