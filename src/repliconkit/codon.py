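"""Relative synonymous codon usage (RSCU) profiling and replicon classification.

For a codon ``c`` in a synonymous family of size ``n_aa`` with observed counts
``x``, RSCU_c = x_c * n_aa / sum(x over the family): 1 means no bias, values
above/below 1 mark over/under-used codons.  Replicon-level profiles pool codon
counts over all CDSs before normalizing, so gene length does not weight the
profile beyond its codon contribution.

Chromids carry a chromosome-like codon-usage imprint while genuine plasmids,
typically of xenologous origin, do not; clustering replicon RSCU vectors and
measuring each replicon's cophenetic distance to the chromosome turns that
qualitative contrast into a reproducible chromid/plasmid call.

The bacterial codon table (translation table 11) is used throughout.  The two
single-codon families (ATG/Met, TGG/Trp) carry no synonymous signal and are
excluded, as are stop codons, leaving 59 informative sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.spatial.distance import pdist, squareform

from .hierarchy import Dendrogram, agglomerate
from .io import Replicon

__all__ = [
    "SENSE_CODONS",
    "INFORMATIVE_CODONS",
    "FAMILIES",
    "RSCUProfile",
    "count_codons",
    "rscu_of_counts",
    "replicon_rscu",
    "RepliconDendrogram",
    "cluster_replicons",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid for the 61 sense codons of table 11
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS: list[str] = sorted(CODON_TO_AA)

#: amino acid -> synonymous codons (all sense families)
FAMILIES: dict[str, list[str]] = {}
for _c, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, []).append(_c)

#: the 59 codons in families of size >= 2 (drops ATG and TGG)
INFORMATIVE_CODONS: list[str] = sorted(
    c for aa, fam in FAMILIES.items() if len(fam) > 1 for c in fam
)


@dataclass
class RSCUProfile:
    """RSCU values and raw codon counts for one gene or replicon.

    Families with no observed codon have no defined RSCU; their codons are
    recorded as NaN (missing), never as 0, so downstream imputation stays an
    explicit choice.
    """

    owner_id: str
    counts: dict[str, int] = field(default_factory=dict)
    values: dict[str, float] = field(default_factory=dict)

    def vector(self, impute: float | None = 1.0) -> np.ndarray:
        """RSCU over INFORMATIVE_CODONS in fixed order; missing families are
        imputed as family-uniform (1.0) unless ``impute`` is None."""
        v = np.array([self.values.get(c, nan) for c in INFORMATIVE_CODONS])
        if impute is not None:
            v = np.where(np.isnan(v), impute, v)
        return v


def count_codons(cds_seq: str) -> dict[str, int]:
    """Count sense codons in an in-frame coding sequence.

    Trailing incomplete codons, stop codons, and codons containing non-ACGT
    (ambiguous) bases are skipped rather than guessed at.
    """
    counts: dict[str, int] = {}
    seq = cds_seq.upper()
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in CODON_TO_AA:
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu_of_counts(counts: Mapping[str, int], owner_id: str = "counts") -> RSCUProfile:
    """Normalize codon counts to RSCU, family by family."""
    clean: dict[str, int] = {}
    for codon, x in counts.items():
        if x < 0:
            raise ValueError(f"negative count for codon {codon}: {x}")
        if codon in CODON_TO_AA:
            clean[codon] = int(x)
    values: dict[str, float] = {}
    for fam in FAMILIES.values():
        if len(fam) < 2:
            continue
        total = sum(clean.get(c, 0) for c in fam)
        for c in fam:
            values[c] = clean.get(c, 0) * len(fam) / total if total else nan
    return RSCUProfile(owner_id=owner_id, counts=clean, values=values)


def replicon_rscu(replicon: Replicon, min_codons: int = 6) -> RSCUProfile:
    """Pooled RSCU over all CDSs of a replicon.

    Counts are summed across genes before normalization (a long gene
    contributes proportionally more codons than a short one).
    """
    pooled: dict[str, int] = {}
    usable = 0
    for cds in replicon.cds_list:
        seq = replicon.cds_sequence(cds)
        if len(seq) < 3 * min_codons:
            continue
        usable += 1
        for codon, x in count_codons(seq).items():
            pooled[codon] = pooled.get(codon, 0) + x
    if not usable:
        raise ValueError(
            f"replicon {replicon.id} has no CDS of at least {min_codons} codons"
        )
    return rscu_of_counts(pooled, owner_id=replicon.id)


@dataclass
class RepliconDendrogram:
    """Clustering of replicon RSCU profiles with the chromid/plasmid call."""

    dendrogram: Dendrogram
    classification: dict[str, str]
    chromosome_id: str | None
    tau: float

    @property
    def newick(self) -> str:
        return self.dendrogram.newick

    @property
    def heights(self) -> list[float]:
        return self.dendrogram.heights


def cluster_replicons(
    profiles: list[RSCUProfile],
    metric: str = "euclidean",
    linkage: str = "average",
    chromosome_id: str | None = None,
    tau: float = 0.5,
) -> RepliconDendrogram:
    """Cluster replicon RSCU vectors and classify ECRs as chromid or plasmid.

    A replicon is called "chromid" when its cophenetic distance to the
    chromosome is at most ``tau`` times the maximum cophenetic distance in the
    dendrogram, "plasmid" otherwise.  With no ``chromosome_id`` only the
    dendrogram is produced.  Missing RSCU values (unobserved families) are
    imputed as the no-bias value 1.0 before distances are computed.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    profiles = sorted(profiles, key=lambda p: p.owner_id)
    ids = [p.owner_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate profile owner ids")
    mat = np.vstack([p.vector(impute=1.0) for p in profiles])
    try:
        condensed = pdist(mat, metric=metric)
    except ValueError as exc:
        raise ValueError(f"unknown metric {metric!r}") from exc
    dist = pd.DataFrame(squareform(condensed), index=ids, columns=ids)
    dend = agglomerate(dist, linkage=linkage)

    classification: dict[str, str] = {}
    if chromosome_id is not None:
        if chromosome_id not in ids:
            raise ValueError(f"chromosome id {chromosome_id!r} not among profiles")
        hmax = max(dend.heights) if dend.heights else 0.0
        for rid in ids:
            if rid == chromosome_id:
                classification[rid] = "chromosome"
            else:
                dc = float(dend.cophenetic.loc[rid, chromosome_id])
                classification[rid] = "chromid" if hmax > 0 and dc <= tau * hmax else (
                    "chromid" if hmax == 0 else "plasmid"
                )
    return RepliconDendrogram(
        dendrogram=dend, classification=classification, chromosome_id=chromosome_id, tau=tau
    )
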