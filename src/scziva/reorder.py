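"""Covariance-structure-based gene reordering.

Genes are permuted so that strongly co-expressed genes sit next to each
other, giving the 1-D convolutional encoder meaningful local receptive
fields. The ordering is the leaf order of an average-linkage agglomerative
clustering of genes under the distance ``d(j, j') = 1 - |corr(x_j, x_j')|``
computed on log-transformed expression columns. Constant columns, whose
correlation is undefined, are assigned distance 1 to every other gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import CountMatrix


@dataclass
class GeneOrder:
    """A gene permutation: ``permutation[new_pos] = original column``."""

    permutation: np.ndarray

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=int)
        g = self.permutation.size
        if sorted(self.permutation.tolist()) != list(range(g)):
            raise ValueError("permutation is not a bijection on 0..G-1")

    @property
    def inverse(self) -> np.ndarray:
        inv = np.empty_like(self.permutation)
        inv[self.permutation] = np.arange(self.permutation.size)
        return inv

    @property
    def n_genes(self) -> int:
        return self.permutation.size


def compute_gene_order(m: CountMatrix, use_log: bool = True) -> GeneOrder:
    """Leaf order of hierarchical clustering on gene correlation magnitude.

    ``use_log`` applies log2(1+x) to the columns before correlating
    (raw-count correlations are dominated by a handful of high-expression
    genes); set False to correlate raw values.
    """
    n, g = m.values.shape
    if g < 2:
        raise ValueError("need at least 2 genes to reorder")
    if n < 2:
        raise ValueError("need at least 2 cells to estimate gene correlations")
    x = np.log2(1.0 + m.values) if (use_log and not m.is_transformed) else np.asarray(
        m.values, dtype=float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - np.abs(corr)
    # constant-variance genes: undefined correlation -> maximal distance
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    leaves = sch.leaves_list(linkage)
    return GeneOrder(np.asarray(leaves, dtype=int))


def apply_order(m: CountMatrix, o: GeneOrder) -> CountMatrix:
    """Permute columns (and gene names) into the clustered order."""
    if o.n_genes != m.n_genes:
        raise ValueError(f"order has {o.n_genes} genes, matrix has {m.n_genes}")
    perm = o.permutation
    return CountMatrix(
        m.values[:, perm],
        list(m.cell_ids),
        [m.gene_names[j] for j in perm],
        is_transformed=m.is_transformed,
    )


def restore_order(m: CountMatrix, o: GeneOrder) -> CountMatrix:
    """Inverse of :func:`apply_order`: back to the caller's original order."""
    if o.n_genes != m.n_genes:
        raise ValueError(f"order has {o.n_genes} genes, matrix has {m.n_genes}")
    inv = o.inverse
    return CountMatrix(
        m.values[:, inv],
        list(m.cell_ids),
        [m.gene_names[j] for j in inv],
        is_transformed=m.is_transformed,
    )


def mean_adjacent_abs_correlation(values: np.ndarray, use_log: bool = True) -> float:
    """Mean |correlation| between neighbouring columns; reordering diagnostic."""
    x = np.log2(1.0 + values) if use_log else np.asarray(values, dtype=float)
    g = x.shape[1]
    if g < 2:
        return 0.0
    sd = x.std(axis=0)
    cors = []
    for j in range(g - 1):
        if sd[j] == 0 or sd[j + 1] == 0:
            cors.append(0.0)
        else:
            cors.append(abs(np.corrcoef(x[:, j], x[:, j + 1])[0, 1]))
    return float(np.mean(cors))
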