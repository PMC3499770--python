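"""Condition clustering on 1 - RV distances with average linkage (UPGMA).

The pairwise RV coefficients between the per-condition cross-product
matrices define a similarity in [0, 1]; conditions are clustered
agglomeratively on the dissimilarity D = 1 - RV with size-weighted average
linkage. The merge loop is written out explicitly (K is the number of
conditions, typically single digits) so the tie-break is fully specified:
among equally close pairs the one with the lexicographically smallest
cluster indices (in creation order) merges first. Average linkage is
reducible, so merge heights are non-decreasing and the dendrogram is
ultrametric; the Newick export places every leaf at distance height/2 from
each internal node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering of K condition labels.

    ``merges[k] = (a, b)`` joins clusters a and b (indices 0..K-1 are leaves
    in input order; K+k is the cluster created by merge k) at height
    ``heights[k]``.
    """

    condition_ids: list[str]
    merges: list[tuple[int, int]]
    heights: list[float]
    sizes: list[int]  # size of the cluster created by each merge

    @property
    def K(self) -> int:
        return len(self.condition_ids)

    def leaf_order(self) -> list[str]:
        """Leaves in dendrogram (left-to-right traversal) order."""
        order: list[int] = []

        def walk(node: int) -> None:
            if node < self.K:
                order.append(node)
            else:
                a, b = self.merges[node - self.K]
                walk(a)
                walk(b)

        walk(self.K + len(self.merges) - 1) if self.merges else order.append(0)
        return [self.condition_ids[i] for i in order]

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (K-1) x 4 linkage matrix for plotting/cophenet."""
        Z = np.zeros((len(self.merges), 4))
        for k, ((a, b), h, s) in enumerate(zip(self.merges, self.heights, self.sizes)):
            Z[k] = [a, b, h, s]
        return Z


def cluster_conditions(rv_matrix: np.ndarray, condition_ids: list[str]) -> Dendrogram:
    """UPGMA clustering of conditions on D = 1 - RV."""
    rv = np.asarray(rv_matrix, dtype=float)
    K = len(condition_ids)
    if K < 2:
        raise ValueError("need at least 2 conditions to cluster")
    if rv.shape != (K, K):
        raise ValueError("rv_matrix shape does not match condition_ids")
    if np.max(np.abs(rv - rv.T)) > 1e-10 or np.max(np.abs(np.diag(rv) - 1)) > 1e-10:
        raise ValueError("rv_matrix must be symmetric with unit diagonal")
    D = 1.0 - rv

    # active clusters: id -> (distance row key), sizes
    dist: dict[tuple[int, int], float] = {}
    active = list(range(K))
    sizes = {i: 1 for i in range(K)}
    for i in range(K):
        for j in range(i + 1, K):
            dist[(i, j)] = float(D[i, j])

    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    out_sizes: list[int] = []
    next_id = K
    while len(active) > 1:
        # smallest distance; ties -> lexicographically smallest (i, j)
        best = min(
            ((dist[(min(a, b), max(a, b))], (min(a, b), max(a, b)))
             for ii, a in enumerate(active) for b in active[ii + 1:]),
            key=lambda x: (x[0], x[1]),
        )
        h, (a, b) = best
        merges.append((a, b))
        heights.append(h)
        na, nb = sizes[a], sizes[b]
        sizes[next_id] = na + nb
        out_sizes.append(na + nb)
        # size-weighted average linkage update
        for c in active:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            dist[(min(next_id, c), max(next_id, c))] = (na * dac + nb * dbc) / (na + nb)
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(
        condition_ids=list(condition_ids),
        merges=merges,
        heights=heights,
        sizes=out_sizes,
    )


def cophenetic_matrix(d: Dendrogram) -> np.ndarray:
    """K x K matrix of merge heights at which leaf pairs first join."""
    K = d.K
    members: dict[int, list[int]] = {i: [i] for i in range(K)}
    coph = np.zeros((K, K))
    for k, (a, b) in enumerate(d.merges):
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = d.heights[k]
        members[K + k] = members[a] + members[b]
    return coph


def dendrogram_to_newick(d: Dendrogram) -> str:
    """Ultrametric Newick string; root-to-leaf path = final height / 2."""

    def node_repr(node: int) -> tuple[str, float]:
        """Return (newick fragment, height of node above the leaves / 2)."""
        if node < d.K:
            return d.condition_ids[node], 0.0
        a, b = d.merges[node - d.K]
        h = d.heights[node - d.K] / 2.0
        ra, ha = node_repr(a)
        rb, hb = node_repr(b)
        return f"({ra}:{h - ha:.10g},{rb}:{h - hb:.10g})", h

    if not d.merges:
        return f"({d.condition_ids[0]});"
    rep, _ = node_repr(d.K + len(d.merges) - 1)
    return rep + ";"
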