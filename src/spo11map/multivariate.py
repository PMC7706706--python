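"""Per-map summary matrix, principal components, hierarchical clustering.

Each Spo11-oligo map is reduced to its vector of per-chromosome RPM
totals; a collection of maps then forms a maps x chromosomes matrix.
PCA is computed on the column-centered matrix without unit-variance
scaling (covariance PCA), so chromosomes with larger absolute
variation carry proportionally more weight.  Clustering is
agglomerative with Euclidean distances under the Ward D2 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genome_io import IntegrityError, SignalMap
from .normalize import per_chromosome_totals

__all__ = ["PCAResult", "build_map_matrix", "pca_maps", "cluster_maps",
           "linkage_to_newick"]


def build_map_matrix(
    maps: Sequence[SignalMap], labels: Sequence[str]
) -> pd.DataFrame:
    """Maps x chromosomes matrix of per-chromosome totals.

    Rows are labeled maps, columns the assembly's chromosomes in order;
    entries are included (rDNA-masked) totals, so each row sums to the
    map's nuclear total.
    """
    if len(maps) != len(labels):
        raise IntegrityError("need one label per map")
    if not maps:
        raise IntegrityError("need at least one map")
    ref = maps[0].assembly
    for m in maps[1:]:
        if m.assembly.chrom_names != ref.chrom_names or (
            m.assembly.chrom_lengths != ref.chrom_lengths
        ):
            raise IntegrityError("all maps must share one assembly")
    rows = {
        label: per_chromosome_totals(m)["total"].to_numpy()
        for label, m in zip(labels, maps)
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ref.chrom_names)
    )


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame             # rows = maps, columns = PC1..PCk
    loadings: pd.DataFrame           # rows = chromosomes, columns = PC1..PCk
    variance_fractions: np.ndarray   # sums to 1


def pca_maps(matrix: pd.DataFrame) -> PCAResult:
    """Covariance PCA of a map matrix (columns centered, not scaled).

    The sign of each component is fixed so that its largest-magnitude
    loading is positive.  Variance fractions sum to 1.
    """
    if len(matrix) < 3:
        raise IntegrityError("need at least 3 maps for PCA")
    X = matrix.to_numpy(dtype=np.float64)
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0.0):
        raise IntegrityError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix sign: largest-magnitude loading of each PC positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s**2
    fractions = var / var.sum()
    k = s.size
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=cols),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=cols),
        variance_fractions=fractions,
    )


def cluster_maps(matrix: pd.DataFrame) -> np.ndarray:
    """Ward-D2 agglomerative clustering of maps on Euclidean distances.

    Returns a SciPy linkage matrix; merge heights are non-decreasing
    (the Ward criterion is reducible) and ties break deterministically
    on the lowest observation index.
    """
    if len(matrix) < 2:
        raise IntegrityError("need at least 2 maps to cluster")
    X = matrix.to_numpy(dtype=np.float64)
    return hierarchy.linkage(X, method="ward")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths
    derived from merge heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
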