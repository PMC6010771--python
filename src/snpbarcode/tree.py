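"""UPGMA trees from allele-sharing distances between genotyped individuals.

The distance between two individuals is one minus the proportion of
allele copies they share over the SNPs where both have calls:

    d(i, j) = 1 - shared(i, j) / (2 * n_compared)

where each SNP contributes the size of the multiset intersection of the
two diploid genotypes (identical homozygotes share 2 copies, a
homozygote and an overlapping heterozygote share 1, disjoint genotypes
share 0).  Clustering is average-linkage (UPGMA) via scipy; leaves are
pre-sorted lexically so tie-breaking is deterministic.  Branch lengths
place each node at half its merge distance, yielding an ultrametric
tree.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datamodel import GenotypeMatrix


def _shared_copies(call_a, call_b) -> int:
    a1, a2 = call_a
    b = list(call_b)
    shared = 0
    for a in (a1, a2):
        if a in b:
            b.remove(a)
            shared += 1
    return shared


def allele_sharing_distance(G: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Pairwise distance matrix (individuals sorted lexically).

    Raises when a pair of individuals has no SNP with calls in both.
    """
    order = sorted(range(len(G.individuals)), key=lambda i: G.individuals[i])
    ids = [G.individuals[i] for i in order]
    n = len(ids)
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = order[a], order[b]
            shared = compared = 0
            for j in range(len(G.snp_ids)):
                ca, cb = G.calls[ia, j], G.calls[ib, j]
                if ca is None or cb is None:
                    continue
                compared += 1
                shared += _shared_copies(ca, cb)
            if compared == 0:
                raise ValueError(
                    f"individuals {ids[a]} and {ids[b]} share no genotyped SNPs"
                )
            D[a, b] = D[b, a] = 1.0 - shared / (2.0 * compared)
    return D, ids


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (i, j, dist, _) in enumerate(Z):
        i, j = int(i), int(j)
        h = dist / 2.0  # ultrametric node height
        left = f"{newick[i]}:{h - heights[i]:.6g}"
        right = f"{newick[j]}:{h - heights[j]:.6g}"
        node = n + k
        newick[node] = f"({left},{right})"
        heights[node] = h
    return newick[n + len(Z) - 1] + ";"


def upgma_tree(G: GenotypeMatrix) -> str:
    """Newick string of the UPGMA tree over all individuals."""
    if len(G.individuals) < 2:
        raise ValueError("need at least two individuals for a tree")
    D, ids = allele_sharing_distance(G)
    Z = linkage(squareform(D, checks=False), method="average")
    return _linkage_to_newick(Z, ids)


def upgma_from_distance(D: np.ndarray, labels) -> str:
    """UPGMA Newick from a precomputed symmetric distance matrix."""
    labels = list(labels)
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    D = np.asarray(D, dtype=float)[np.ix_(order, order)]
    Z = linkage(squareform(D, checks=False), method="average")
    return _linkage_to_newick(Z, [labels[i] for i in order])
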