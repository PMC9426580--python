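"""Copy number and population prevalence from sequencing depth.

Low-copy replicons leave a simple signature in whole-genome sequencing of a
population: the depth ratio r of a replicon to the chromosome satisfies
r = c * p, where c is the per-cell copy number in carrier cells and p the
fraction of cells carrying the replicon.  A tightly controlled single-copy
replicon present in every cell gives r = 1; the same replicon carried by only
half the population gives r = 0.5.  Decomposing r into (c, p) is ambiguous in
general, so the decomposition below is rule-based and flags the ambiguous
cases instead of hiding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .assays import AssayCounts

__all__ = ["CoverageEstimate", "coverage_ratio", "decompose_ratio", "consistency_test"]


@dataclass
class CoverageEstimate:
    """Depth ratio of a replicon to the chromosome, decomposed as r = c * p."""

    replicon_id: str
    r: float
    ci_low: float
    ci_high: float
    c: int
    p: float
    mode: str  # integer_copy | single_copy_partial | ambiguous

    MODES = ("integer_copy", "single_copy_partial", "ambiguous")


def coverage_ratio(
    depth: pd.DataFrame,
    chromosome_id: str,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict[str, tuple[float, tuple[float, float]]]:
    """Median-depth ratio of every replicon to the chromosome, with a
    percentile-bootstrap 95% CI over windows.

    The median (not the mean) of window depths is used so that local pileups
    over repeats do not inflate the ratio.  The chromosome's own entry is 1 by
    construction.
    """
    required = {"replicon_id", "depth"}
    if not required <= set(depth.columns):
        raise ValueError(f"depth table must have columns {sorted(required)}")
    groups = {rid: sub["depth"].to_numpy(float) for rid, sub in depth.groupby("replicon_id")}
    if chromosome_id not in groups:
        raise ValueError(f"chromosome id {chromosome_id!r} not in depth table")
    chrom = groups[chromosome_id]
    if len(chrom) < 20:
        raise ValueError(
            f"chromosome {chromosome_id} has only {len(chrom)} windows; need >= 20"
        )
    chrom_med = float(np.median(chrom))
    if chrom_med == 0:
        raise ValueError("chromosome median depth is zero")
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[float, tuple[float, float]]] = {
        chromosome_id: (1.0, (1.0, 1.0))
    }
    for rid in sorted(groups):
        if rid == chromosome_id:
            continue
        win = groups[rid]
        if len(win) < 5:
            warnings.warn(f"replicon {rid} has only {len(win)} windows; CI will be wide")
        r = float(np.median(win)) / chrom_med
        ridx = rng.integers(0, len(win), size=(n_boot, len(win)))
        cidx = rng.integers(0, len(chrom), size=(n_boot, len(chrom)))
        boot = np.median(win[ridx], axis=1) / np.median(chrom[cidx], axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        out[rid] = (r, (float(lo), float(hi)))
    return out


def decompose_ratio(
    r: float,
    ci: tuple[float, float] = (np.nan, np.nan),
    replicon_id: str = "",
    single_copy_constraint: bool = False,
    tol: float = 0.1,
) -> CoverageEstimate:
    """Decompose a depth ratio into copy number and prevalence.

    Rules, in order:

    1. r within ``tol`` of an integer >= 1  ->  that copy number, full
       prevalence (``integer_copy``);
    2. otherwise, if the replicon is known to be single-copy (e.g. a RepABC
       replicon) and r < 1  ->  c = 1, p = r (``single_copy_partial``);
    3. otherwise c = max(1, round(r)) and p = r / c, flagged ``ambiguous``.
    """
    if r <= 0:
        raise ValueError(f"ratio must be positive, got {r}")
    if not 0 < tol < 0.5:
        raise ValueError(f"tol must lie in (0, 0.5), got {tol}")
    nearest = int(np.floor(r + 0.5))  # round half up, not banker's
    if abs(r - nearest) <= tol and nearest >= 1:
        c, p, mode = nearest, 1.0, "integer_copy"
    elif single_copy_constraint and r < 1:
        c, p, mode = 1, min(r, 1.0), "single_copy_partial"
    else:
        c = max(1, nearest)
        p, mode = r / c, "ambiguous"
    return CoverageEstimate(
        replicon_id=replicon_id, r=r, ci_low=ci[0], ci_high=ci[1], c=c, p=p, mode=mode
    )


def consistency_test(estimate: CoverageEstimate, assay: AssayCounts) -> float:
    """Exact two-sided binomial test of a colony assay against the
    coverage-predicted prevalence.

    Two-sided by minimum-likelihood summation: the p-value sums the
    probabilities of all outcomes no more likely than the observed count.
    Returns the p-value; a value near 1 means the assay is fully consistent
    with the sequencing-based prevalence.
    """
    p = estimate.p
    if p in (0.0, 1.0):
        concordant = assay.n_positive == (0 if p == 0.0 else assay.n_tested)
        if concordant:
            return 1.0
        warnings.warn(
            f"prevalence {p} cannot produce {assay.n_positive}/{assay.n_tested}; p-value 0"
        )
        return 0.0
    return float(binomtest(assay.n_positive, assay.n_tested, p, alternative="two-sided").pvalue)
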