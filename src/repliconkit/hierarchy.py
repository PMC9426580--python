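"""Deterministic agglomerative clustering on a labelled distance matrix.

A small, explicit implementation is used instead of delegating to
:func:`scipy.cluster.hierarchy.linkage` because downstream classification
rules need (a) a documented tie-break — merge the pair whose sorted label
pair is lexicographically smallest among all minimum-distance pairs — so
results are invariant to input order, and (b) cophenetic distances keyed by
label.  On tie-free inputs the merge heights agree with scipy's, which is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LINKAGES = ("average", "single", "complete")


@dataclass
class Dendrogram:
    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]  # (left members, right members, height)
    newick: str
    cophenetic: pd.DataFrame

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cut(self, height: float) -> dict[str, int]:
        """Flat clusters obtained by cutting all merges above ``height``.

        Group ids are assigned in order of each group's lexicographically
        smallest member, starting at 0.
        """
        clusters: list[set[str]] = [{lab} for lab in self.labels]
        for left, right, h in self.merges:
            if h > height:
                continue
            li = next(i for i, c in enumerate(clusters) if left <= c)
            ri = next(i for i, c in enumerate(clusters) if right <= c)
            if li != ri:
                clusters[li] = clusters[li] | clusters[ri]
                del clusters[ri]
        clusters.sort(key=lambda c: min(c))
        return {lab: i for i, c in enumerate(clusters) for lab in c}


def agglomerate(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Cluster a symmetric labelled distance matrix bottom-up.

    Heights are the inter-cluster distances at merge time; with the supported
    linkages on a metric input they are non-decreasing.  The newick output is
    ultrametric: each leaf sits at depth height/2 below its merge point.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    labels = sorted(dist.index.astype(str))
    if list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix index and columns must match")
    if len(labels) < 2:
        raise ValueError("need at least two items to cluster")
    d = dist.loc[labels, labels].to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    # active clusters: key = sorted member tuple
    members: dict[str, frozenset] = {lab: frozenset([lab]) for lab in labels}
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    key_of = {lab: lab for lab in labels}  # cluster key = smallest member label
    dmat: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dmat[(a, labels[j])] = d[i, j]

    newick_of = {lab: lab for lab in labels}
    depth_of = {lab: 0.0 for lab in labels}  # current leaf-to-top distance
    merges: list[tuple[frozenset, frozenset, float]] = []
    coph = pd.DataFrame(0.0, index=labels, columns=labels)

    active = sorted(key_of)
    while len(active) > 1:
        best = min(
            ((dmat[(a, b)], (a, b)) for i, a in enumerate(active) for b in active[i + 1 :]),
            key=lambda t: (t[0], t[1]),
        )
        h, (a, b) = best
        for x in members[a]:
            for y in members[b]:
                coph.loc[x, y] = coph.loc[y, x] = h
        merges.append((members[a], members[b], h))
        new = min(a, b)
        bla, blb = h / 2 - depth_of[a], h / 2 - depth_of[b]
        newick_new = f"({newick_of[a]}:{bla:.6g},{newick_of[b]}:{blb:.6g})"
        # Lance-Williams style distance update
        for c in active:
            if c in (a, b):
                continue
            da = dmat[tuple(sorted((a, c)))]
            db = dmat[tuple(sorted((b, c)))]
            if linkage == "single":
                dn = min(da, db)
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = (sizes[a] * da + sizes[b] * db) / (sizes[a] + sizes[b])
            dmat[tuple(sorted((new, c)))] = dn
        members[new] = members[a] | members[b]
        sizes[new] = sizes[a] + sizes[b]
        newick_of[new] = newick_new
        depth_of[new] = h / 2
        active = sorted(set(active) - {a, b} | {new})

    root = active[0]
    return Dendrogram(
        labels=labels,
        merges=merges,
        newick=newick_of[root] + ";",
        cophenetic=coph,
    )
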