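"""Reading, writing and preprocessing of cells-by-genes count matrices.

Supported on-disk formats:

* dense CSV/TSV — header row of gene names, first column of cell IDs,
  cells as rows;
* MatrixMarket (``.mtx``) with ``genes.tsv`` / ``barcodes.tsv`` companions,
  stored genes-by-cells as in the 10x / community convention and transposed
  on load;
* a 10x-style triplet directory (``matrix.mtx`` + ``genes.tsv`` +
  ``barcodes.tsv``).

In memory a matrix is always cells-as-rows (:class:`CountMatrix`).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class CountMatrix:
    """A cells × genes expression matrix with axis labels.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` array of non-negative numbers. Raw
        matrices hold integer counts; transformed matrices (see
        :func:`log_normalize`) hold floats and carry ``is_transformed=True``.
    cell_ids, gene_names
        Unique string labels for rows and columns.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_names: list[str] = field(default_factory=list)
    is_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells × genes array")
        n, g = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n)]
        if not self.gene_names:
            self.gene_names = [f"gene{j}" for j in range(g)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_names = [str(g_) for g_ in self.gene_names]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(set(self.cell_ids)) != n or len(set(self.gene_names)) != g:
            raise ValueError("cell ids and gene names must be unique")
        if np.any(self.values < 0):
            raise ValueError("negative count encountered")
        if not self.is_transformed:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("raw count matrix contains non-integer values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CountMatrix":
        return replace(
            self,
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_names=list(self.gene_names),
        )


_FORMATS = ("mtx", "csv", "tenx_dir")


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str, format: str = "csv", transformed: bool = False) -> CountMatrix:
    """Read a count matrix from disk.

    ``mtx`` expects ``<stem>.mtx`` plus ``genes.tsv`` and ``barcodes.tsv``
    next to it; ``tenx_dir`` expects a directory holding ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv``. Both are stored genes × cells on
    disk and transposed to cells × genes on load. No format auto-detection
    is attempted. ``transformed=True`` marks the data as already
    log/normalized (permits non-integer values).
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if format == "csv":
        if not os.path.isfile(path):
            raise FileNotFoundError(path)
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError("negative count in CSV input")
        return CountMatrix(values, list(df.index), list(df.columns),
                           is_transformed=transformed)

    if format == "tenx_dir":
        if not os.path.isdir(path):
            raise FileNotFoundError(path)
        mtx_path = os.path.join(path, "matrix.mtx")
        genes_path = os.path.join(path, "genes.tsv")
        barcodes_path = os.path.join(path, "barcodes.tsv")
    else:  # mtx
        mtx_path = path
        stem_dir = os.path.dirname(os.path.abspath(path))
        genes_path = os.path.join(stem_dir, "genes.tsv")
        barcodes_path = os.path.join(stem_dir, "barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not os.path.isfile(p):
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(mtx_path)  # genes × cells on disk
    dense = np.asarray(scipy.sparse.csr_matrix(mat).todense(), dtype=float).T
    genes = _read_names(genes_path)
    cells = _read_names(barcodes_path)
    if dense.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix is {mat.shape} (genes × cells) but companions list "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    if np.any(dense < 0):
        raise ValueError("negative count in MTX input")
    return CountMatrix(dense, cells, genes, is_transformed=transformed)


def write_counts(m: CountMatrix, path: str, format: str = "csv") -> None:
    """Write ``m`` in the same dialect :func:`read_counts` reads."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if format == "csv":
        df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_names)
        df.to_csv(path)
        return
    if format == "tenx_dir":
        os.makedirs(path, exist_ok=True)
        mtx_path = os.path.join(path, "matrix.mtx")
        out_dir = path
    else:
        mtx_path = path
        out_dir = os.path.dirname(os.path.abspath(path))
        os.makedirs(out_dir, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values.T)  # genes × cells on disk
    scipy.io.mmwrite(mtx_path, sparse)
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("\n".join(m.gene_names) + "\n")
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(m.cell_ids) + "\n")


def filter_zero_genes(m: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Drop genes with zero expression across all cells.

    Returns the filtered matrix and the integer indices of the kept columns
    in the original matrix (original order preserved).
    """
    nonzero = np.asarray((m.values != 0).any(axis=0)).ravel()
    kept = np.flatnonzero(nonzero)
    if kept.size == 0:
        raise ValueError("all genes are zero across all cells; nothing to impute")
    out = CountMatrix(
        m.values[:, kept],
        list(m.cell_ids),
        [m.gene_names[j] for j in kept],
        is_transformed=m.is_transformed,
    )
    return out, kept


def library_scale_factors(values: np.ndarray) -> np.ndarray:
    """Per-cell factors scaling each library to the median library size.

    Cells with zero total count get factor 1 (left unscaled) with a warning.
    """
    lib = np.asarray(values).sum(axis=1)
    zero = lib == 0
    if zero.all():
        warnings.warn("all cells have zero library size; no scaling applied")
        return np.ones_like(lib, dtype=float)
    med = np.median(lib[~zero])
    factors = np.ones_like(lib, dtype=float)
    factors[~zero] = med / lib[~zero]
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total count left unscaled")
    return factors


def log_normalize(m: CountMatrix, scale_factors: np.ndarray | None = None) -> CountMatrix:
    """Median-library-size scaling followed by ``log2(1 + x)``.

    Used for metric reporting and downstream clustering only; the ZINB
    likelihood always consumes raw counts. ``scale_factors`` may be supplied
    to reuse factors computed from a reference matrix.
    """
    if scale_factors is None:
        scale_factors = library_scale_factors(m.values)
    scaled = m.values * np.asarray(scale_factors, dtype=float)[:, None]
    return CountMatrix(
        np.log2(1.0 + scaled),
        list(m.cell_ids),
        list(m.gene_names),
        is_transformed=True,
    )
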