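"""RepABC compatibility-group typing.

RepABC modules of alphaproteobacterial low-copy replicons combine two
partitioning proteins (RepA, RepB) with a replicase (RepC).  Compatibility —
whether two replicons can coexist in one cell — is carried by the
partitioning system, and RepA/RepB evolve synchronously while repC is swapped
between modules; typing therefore rests on the partitioning proteins alone.
This module provides the pieces of that analysis:

* p-distances between family members (with pairwise global alignment for
  unaligned input),
* neighbor-joining trees per family,
* Robinson-Foulds distances to quantify RepA/RepB congruence versus
  RepAB/RepC incongruence,
* group assignment by cutting an average-linkage clustering of the averaged
  RepA/RepB distances,
* detection of the diagnostic palindromes (inverted repeats) that act as
  cis-acting RepB partitioning anchors, with a per-group consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from Bio import Align

from .assays import reverse_complement
from .hierarchy import agglomerate

__all__ = [
    "ProteinFamily",
    "pairwise_distances",
    "nj_tree",
    "tree_bipartitions",
    "rf_distance",
    "CompatibilityReport",
    "compatibility_groups",
    "PalindromeHit",
    "find_palindromes",
    "palindrome_consensus",
]


@dataclass
class ProteinFamily:
    """A named protein family (RepA, RepB or RepC) keyed by taxon."""

    name: str
    sequences: dict[str, str]
    aligned: bool = False

    def __post_init__(self) -> None:
        for taxon, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"{self.name}: empty sequence for taxon {taxon!r}")
        if self.aligned:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise ValueError(f"{self.name}: aligned=True but lengths differ: {lengths}")


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _p_distance_aligned(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(x != y for x, y in pairs) / len(pairs)


def pairwise_distances(
    family: ProteinFamily,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> pd.DataFrame:
    """Symmetric matrix of p-distances between all family members.

    Pre-aligned families are compared column-wise over columns where neither
    sequence has a gap.  Unaligned families are globally aligned pairwise
    first (affine gap penalties; a gap of length L costs open + (L-1)*extend).
    """
    taxa = sorted(family.sequences)
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    aligner = None if family.aligned else _make_aligner(match, mismatch, gap_open, gap_extend)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            sa, sb = family.sequences[a], family.sequences[b]
            if family.aligned:
                pij = _p_distance_aligned(sa, sb)
            else:
                aln = aligner.align(sa, sb)[0]
                ga, gb = str(aln[0]), str(aln[1])
                pij = _p_distance_aligned(ga, gb)
            d.loc[a, b] = d.loc[b, a] = pij
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dist: pd.DataFrame) -> skbio.TreeNode:
    """Neighbor-joining tree from a symmetric labelled distance matrix.

    Additive matrices are recovered exactly (topology and branch lengths).
    Ties in the Q criterion are broken by the lexicographically smallest
    sorted label pair, where a cluster is labelled by its smallest member, so
    the result is independent of input order.  Negative branch-length
    estimates are clamped to zero with a warning.  The returned tree is
    unrooted, represented with a trifurcating root.
    """
    labels = sorted(dist.index.astype(str))
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns must match")
    if len(labels) < 4:
        raise ValueError("neighbor joining needs at least 4 taxa")
    mat = dist.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: dict[str, skbio.TreeNode] = {lab: skbio.TreeNode(name=lab) for lab in labels}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d[(a, labels[j])] = mat[i, j]

    def dd(a: str, b: str) -> float:
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = list(labels)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(dd(a, b) for b in active if b != a) for a in active}
        best = min(
            (
                ((n - 2) * dd(a, b) - r[a] - r[b], tuple(sorted((a, b))))
                for i, a in enumerate(active)
                for b in active[i + 1 :]
            ),
            key=lambda t: (t[0], t[1]),
        )
        a, b = best[1]
        la = dd(a, b) / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dd(a, b) - la
        la, lb = _clamp(la, a), _clamp(lb, b)
        parent = skbio.TreeNode()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        parent.extend([na, nb])
        new = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[tuple(sorted((new, c)))] = (dd(a, c) + dd(b, c) - dd(a, b)) / 2
        nodes[new] = parent
        active = sorted(set(active) - {a, b} | {new})

    a, b, c = active
    la = _clamp((dd(a, b) + dd(a, c) - dd(b, c)) / 2, a)
    lb = _clamp((dd(a, b) + dd(b, c) - dd(a, c)) / 2, b)
    lc = _clamp((dd(a, c) + dd(b, c) - dd(a, b)) / 2, c)
    root = skbio.TreeNode()
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(lab)
        node.length = ln
        root.append(node)
    return root


def _clamp(length: float, label: str) -> float:
    if length < 0:
        warnings.warn(f"negative branch length {length:.4g} at {label}; clamped to 0")
        return 0.0
    return length


# ---------------------------------------------------------------------------
# Robinson-Foulds


def tree_bipartitions(tree: skbio.TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as a
    frozenset of the two leaf-name frozensets (root-placement invariant)."""
    leaves = frozenset(t.name for t in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({side, leaves - side}))
    return splits


def rf_distance(t1: skbio.TreeNode, t2: skbio.TreeNode) -> tuple[int, float]:
    """Robinson-Foulds distance and its normalized value in [0, 1].

    The distance is the size of the symmetric difference between the
    non-trivial bipartition sets; the maximum on n shared leaves is 2(n-3).
    """
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, only in second {sorted(l2 - l1)}"
        )
    rf = len(tree_bipartitions(t1) ^ tree_bipartitions(t2))
    maxrf = 2 * (len(l1) - 3)
    return rf, rf / maxrf if maxrf > 0 else 0.0


# ---------------------------------------------------------------------------
# compatibility groups


@dataclass
class CompatibilityReport:
    groups: dict[str, int]
    cut_height: float
    rf_repa_repb: int
    rf_repab_repc: int | None
    rf_repab_repc_norm: float | None
    trees: dict[str, skbio.TreeNode] = field(repr=False, default_factory=dict)


def compatibility_groups(
    repa: ProteinFamily,
    repb: ProteinFamily,
    cut_height: float,
    repc: ProteinFamily | None = None,
    **align_kwargs,
) -> CompatibilityReport:
    """Assign taxa to compatibility groups from their partitioning proteins.

    The RepA and RepB p-distance matrices (restricted to shared taxa) are
    averaged, clustered by average linkage, and cut at ``cut_height``; the
    resulting flat clusters are the groups.  RF(RepA, RepB) is reported as a
    congruence check (should be 0 for synchronously evolving partitioning
    proteins) and, when RepC is supplied, RF(RepAB, RepC) as the incongruence
    score that exposes replicase swapping.
    """
    shared = sorted(set(repa.sequences) & set(repb.sequences))
    if len(shared) < 4:
        raise ValueError(f"RepA and RepB share only {len(shared)} taxa; need >= 4")
    da = pairwise_distances(repa, **align_kwargs).loc[shared, shared]
    db = pairwise_distances(repb, **align_kwargs).loc[shared, shared]
    dab = (da + db) / 2

    dend = agglomerate(dab, linkage="average")
    if dend.heights and not (min(dend.heights) <= cut_height <= max(dend.heights)):
        warnings.warn(
            f"cut height {cut_height} outside merge-height range "
            f"[{min(dend.heights):.4g}, {max(dend.heights):.4g}]; "
            "grouping is all-singleton or a single group"
        )
    groups = dend.cut(cut_height)

    trees = {"RepA": nj_tree(da), "RepB": nj_tree(db), "RepAB": nj_tree(dab)}
    rf_ab, _ = rf_distance(trees["RepA"], trees["RepB"])
    rf_abc = rf_abc_norm = None
    if repc is not None:
        shared_c = sorted(set(shared) & set(repc.sequences))
        if len(shared_c) < 4:
            raise ValueError(f"RepC shares only {len(shared_c)} taxa with RepA/RepB; need >= 4")
        dc = pairwise_distances(repc, **align_kwargs).loc[shared_c, shared_c]
        trees["RepC"] = nj_tree(dc)
        ab_shared = nj_tree(dab.loc[shared_c, shared_c]) if shared_c != shared else trees["RepAB"]
        rf_abc, rf_abc_norm = rf_distance(ab_shared, trees["RepC"])
    return CompatibilityReport(
        groups=groups,
        cut_height=cut_height,
        rf_repa_repb=rf_ab,
        rf_repab_repc=rf_abc,
        rf_repab_repc_norm=rf_abc_norm,
        trees=trees,
    )


# ---------------------------------------------------------------------------
# palindromes (inverted repeats)

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class PalindromeHit:
    """A maximal inverted repeat: left arm, loop, right arm."""

    position: int  # 0-based start of the left arm
    arm_length: int
    loop_length: int
    mismatches: int
    arm: str  # left-arm sequence

    @property
    def end(self) -> int:
        return self.position + 2 * self.arm_length + self.loop_length

    def site(self, sequence: str) -> str:
        return sequence[self.position : self.end]


def _arm_mismatches(seq: str, i: int, a: int, loop: int) -> int:
    left = seq[i : i + a]
    right = seq[i + a + loop : i + 2 * a + loop]
    return sum(x != y for x, y in zip(left, reverse_complement(right)))


def find_palindromes(
    seq: str,
    min_arm: int = 5,
    max_loop: int = 10,
    max_mismatch: int = 1,
) -> list[PalindromeHit]:
    """All maximal inverted repeats with arms of at least ``min_arm``.

    A hit (position i, arm a, loop l) requires the left arm to equal the
    reverse complement of the right arm up to ``max_mismatch`` substitutions.
    Maximality means the arms cannot be extended outward by one base without
    either leaving the sequence or exceeding the mismatch budget.  Inverted
    repeats are strand-symmetric, so one scan of the given strand covers both.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    seq = seq.upper()
    n = len(seq)
    hits = []
    for loop in range(max_loop + 1):
        # center = start of the loop
        for center in range(1, n):
            i_max = min(center, n - center - loop)  # widest possible arm
            if i_max < min_arm:
                continue
            mism = 0
            best = 0
            for a in range(1, i_max + 1):
                left_base = seq[center - a]
                right_base = seq[center + loop + a - 1]
                if left_base != reverse_complement(right_base):
                    mism += 1
                    if mism > max_mismatch:
                        break
                best = a
            if best >= min_arm:
                # the greedy scan stops at the mismatch budget or the sequence
                # edge, so `best` is already the maximal arm for this center
                i = center - best
                hits.append(
                    PalindromeHit(
                        position=i,
                        arm_length=best,
                        loop_length=loop,
                        mismatches=_arm_mismatches(seq, i, best, loop),
                        arm=seq[i : i + best],
                    )
                )
    return sorted(hits, key=lambda h: (h.position, h.loop_length, -h.arm_length))


def palindrome_consensus(sites: list[str]) -> str:
    """Per-column majority consensus of palindromic sites aligned by center.

    Sites of unequal length are center-aligned; columns with a tie report the
    IUPAC ambiguity code of the tied bases; positions covered by no site are
    skipped.
    """
    if not sites:
        raise ValueError("no sites to build a consensus from")
    width = max(len(s) for s in sites)
    cols: list[list[str]] = [[] for _ in range(width)]
    for s in sites:
        offset = (width - len(s)) // 2
        for j, base in enumerate(s.upper()):
            cols[offset + j].append(base)
    out = []
    for col in cols:
        if not col:
            continue
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, k in counts.items() if k == top)
        out.append(_IUPAC.get(winners, "N"))
    return "".join(out)
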