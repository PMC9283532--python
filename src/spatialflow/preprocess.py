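"""Count-matrix preprocessing for spatial transcriptomics data.

Turns a raw spot/cell x gene count matrix into the filtered, depth-normalized,
log-transformed, highly-variable-gene-restricted feature matrix that is
attached as node features to the spatial expression graph.

The pipeline is the standard one for ST/scRNA-seq data:

1. drop genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells,
   then drop cells expressing fewer than ``min_genes_per_cell`` of the
   surviving genes (one pass, genes before cells);
2. scale each cell to a common total count (``scale_factor``, default 10 000)
   and apply ``log(1 + x)``;
3. keep the top highly variable genes ranked by bin-normalized dispersion
   (variance / mean, genes binned into equal-frequency bins of mean
   expression).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "STDataset",
    "FeatureMatrix",
    "filter_counts",
    "normalize_log",
    "select_hvg",
    "preprocess",
    "read_mtx",
    "read_dense",
    "read_coordinates",
    "write_mtx",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class STDataset:
    """A spatial transcriptomics dataset: counts + coordinates + identifiers.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` non-negative integer matrix (dense array or
        scipy sparse). Stored as CSR.
    coords
        ``(n_cells, d)`` spatial coordinates, ``d`` in {2, 3}; arbitrary
        length units.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns of ``counts``.
    """

    counts: sp.csr_matrix
    coords: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords must be (n_cells, 2) or (n_cells, 3)")
        if self.coords.shape[0] != n:
            raise ValueError(
                f"counts has {n} cells but coords has {self.coords.shape[0]} rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match counts rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match counts columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "STDataset":
        """Return a consistent subset along cells and/or genes."""
        cm = np.arange(self.n_cells) if cell_mask is None else np.where(cell_mask)[0]
        gm = np.arange(self.n_genes) if gene_mask is None else np.where(gene_mask)[0]
        return STDataset(
            counts=self.counts[cm][:, gm],
            coords=self.coords[cm],
            cell_ids=self.cell_ids[cm],
            gene_ids=self.gene_ids[gm],
        )


@dataclass
class FeatureMatrix:
    """Log-normalized expression of the selected highly variable genes."""

    X: np.ndarray  # (n_cells, n_selected), log1p of depth-normalized counts
    selected_genes: np.ndarray  # sorted unique indices into the input genes
    scale_factor: float = 10000.0
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.selected_genes = np.asarray(self.selected_genes, dtype=int)
        if self.X.shape[1] != len(self.selected_genes):
            raise ValueError("selected_genes length must match X columns")
        if np.any(np.diff(self.selected_genes) <= 0) and len(self.selected_genes) > 1:
            raise ValueError("selected_genes must be sorted and unique")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_counts(
    data: STDataset,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
) -> STDataset:
    """Remove lowly detected genes, then sparsely covered cells.

    A gene is kept when it has a strictly positive count in at least
    ``min_cells_per_gene`` cells of the *input* matrix; a cell is kept when it
    expresses at least ``min_genes_per_cell`` of the surviving genes. Single
    pass: genes are filtered before cells and the gene filter is not revisited.
    """
    counts = data.counts
    detected = counts.copy()
    detected.data = (detected.data > 0).astype(np.int64)
    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    gene_mask = cells_per_gene >= min_cells_per_gene

    genes_per_cell = np.asarray(detected[:, gene_mask].sum(axis=1)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell

    if gene_mask.sum() == 0 or cell_mask.sum() == 0:
        raise ValueError(
            "empty after filtering: removed "
            f"{int((~gene_mask).sum())}/{data.n_genes} genes and "
            f"{int((~cell_mask).sum())}/{data.n_cells} cells"
        )
    return data.subset(cell_mask=cell_mask, gene_mask=gene_mask)


def normalize_log(data: STDataset, scale_factor: float = 10000.0) -> sp.csr_matrix:
    """Depth-normalize each cell to ``scale_factor`` total counts and log1p.

    Entry ``(i, j)`` of the result is ``log(1 + scale_factor * c_ij / sum_j c_ij)``.
    Before the log transform every row sums to ``scale_factor``.
    """
    counts = sp.csr_matrix(data.counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        bad = int(np.where(totals <= 0)[0][0])
        raise ValueError(f"zero-count cell at row {bad}; filter cells first")
    scaled = sp.diags(scale_factor / totals) @ counts
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return scaled


def _gene_moments(expr) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and (biased, population) variance for dense or sparse."""
    if sp.issparse(expr):
        expr = sp.csr_matrix(expr)
        n = expr.shape[0]
        mean = np.asarray(expr.mean(axis=0)).ravel()
        sq = expr.copy()
        sq.data = sq.data ** 2
        ex2 = np.asarray(sq.mean(axis=0)).ravel()
        var = np.maximum(ex2 - mean ** 2, 0.0)
        return mean, var
    expr = np.asarray(expr, dtype=float)
    return expr.mean(axis=0), expr.var(axis=0)


def select_hvg(expr, n_top: int = 3000, n_bins: int = 20) -> np.ndarray:
    """Rank genes by bin-normalized dispersion; return top-``n_top`` indices.

    Dispersion of a gene is variance / mean (0 where the mean is 0). Genes are
    assigned to ``n_bins`` equal-frequency bins of mean expression; within each
    bin the normalized dispersion is
    ``|dispersion - median(bin dispersions)| / MAD(bin dispersions)``.
    Zero-MAD bins fall back to the bin standard deviation; if that is also 0
    the normalized dispersion is 0. Genes with zero dispersion (constant or
    undetected) are never considered variable: their normalized dispersion is
    fixed at 0. Ties at the cutoff are broken by original gene index, and the
    returned indices are in original (sorted) order.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    mean, var = _gene_moments(expr)
    n_genes = len(mean)
    if n_genes == 0:
        raise ValueError("expression matrix has no genes")
    if n_top >= n_genes:
        return np.arange(n_genes)

    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)

    # equal-frequency binning on mean expression; ties share a bin via qcut
    bins = pd.qcut(
        pd.Series(mean).rank(method="first"),
        q=min(n_bins, n_genes),
        labels=False,
        duplicates="drop",
    ).to_numpy()

    norm_disp = np.zeros(n_genes)
    for b in np.unique(bins):
        idx = np.where(bins == b)[0]
        d = dispersion[idx]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        scale = mad if mad > 0 else d.std()
        if scale > 0:
            norm_disp[idx] = np.abs(d - med) / scale
    # constant genes: variance is 0 up to summation rounding; never variable
    zero_disp = var <= 1e-18 * np.maximum(mean, 1.0) ** 2
    norm_disp[zero_disp] = 0.0

    order = np.lexsort((np.arange(n_genes), -norm_disp))
    return np.sort(order[:n_top])


def preprocess(
    data: STDataset,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 100,
    scale_factor: float = 10000.0,
    n_top_hvg: int = 3000,
    n_bins: int = 20,
) -> tuple[FeatureMatrix, STDataset]:
    """Full preprocessing: filter -> normalize/log -> HVG selection.

    Returns the feature matrix (dense ``X`` restricted to the selected genes)
    together with the filtered dataset whose coordinates and identifiers align
    with the rows of ``X``.
    """
    filtered = filter_counts(data, min_cells_per_gene, min_genes_per_cell)
    lognorm = normalize_log(filtered, scale_factor)
    selected = select_hvg(lognorm, n_top=n_top_hvg, n_bins=n_bins)
    X = np.asarray(lognorm[:, selected].todense())
    fm = FeatureMatrix(
        X=X,
        selected_genes=selected,
        scale_factor=scale_factor,
        gene_ids=filtered.gene_ids[selected],
        cell_ids=filtered.cell_ids,
    )
    return fm, filtered


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def _read_lines(path: str) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([ln.strip().split("\t")[0] for ln in fh if ln.strip()],
                          dtype=object)


def read_coordinates(path: str) -> pd.DataFrame:
    """Coordinate table with columns ``cell_id,x,y[,z]``, indexed by cell id."""
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate file {path} must have columns cell_id,x,y[,z]")
    return df.set_index("cell_id")


def read_mtx(counts: str, genes: str, barcodes: str, coords: str) -> STDataset:
    """Assemble an :class:`STDataset` from MatrixMarket + sidecar text files.

    The matrix is cells x genes; a genes x cells matrix (CellRanger layout) is
    auto-transposed when its row count matches the genes file. Coordinates are
    joined by barcode string, never by row order.
    """
    mat = sp.csr_matrix(mmread(counts))
    gene_ids = _read_lines(genes)
    cell_ids = _read_lines(barcodes)
    if mat.shape != (len(cell_ids), len(gene_ids)):
        if mat.shape == (len(gene_ids), len(cell_ids)):
            mat = sp.csr_matrix(mat.T)
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"(cells={len(cell_ids)}, genes={len(gene_ids)}) nor its transpose"
            )
    coord_df = read_coordinates(coords)
    missing = [c for c in cell_ids if c not in coord_df.index]
    if missing:
        raise ValueError(f"coordinates missing for barcodes: {missing[:5]}")
    cols = ["x", "y", "z"] if "z" in coord_df.columns else ["x", "y"]
    xy = coord_df.loc[list(cell_ids), cols].to_numpy(dtype=float)
    return STDataset(counts=mat, coords=xy, cell_ids=cell_ids, gene_ids=gene_ids)


def read_dense(matrix: str, coords: str) -> STDataset:
    """Dense CSV/TSV matrix (cells in rows, header = gene ids, col 0 = cell id)."""
    sep = "\t" if matrix.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(matrix, sep=sep, index_col=0, comment="#")
    coord_df = read_coordinates(coords)
    missing = [c for c in df.index if c not in coord_df.index]
    if missing:
        raise ValueError(f"coordinates missing for cells: {missing[:5]}")
    cols = ["x", "y", "z"] if "z" in coord_df.columns else ["x", "y"]
    xy = coord_df.loc[list(df.index), cols].to_numpy(dtype=float)
    return STDataset(
        counts=sp.csr_matrix(df.to_numpy()),
        coords=xy,
        cell_ids=df.index.to_numpy(dtype=object),
        gene_ids=df.columns.to_numpy(dtype=object),
    )


def write_mtx(data: STDataset, outdir: str, prefix: str = "matrix") -> dict:
    """Write counts as .mtx with genes/barcodes sidecars and a coordinate CSV."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, f"{prefix}.mtx"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "barcodes": os.path.join(outdir, "barcodes.tsv"),
        "coords": os.path.join(outdir, "coordinates.csv"),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mmwrite(paths["counts"], sp.coo_matrix(data.counts))
    with open(paths["genes"], "w") as fh:
        fh.write("\n".join(map(str, data.gene_ids)) + "\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(map(str, data.cell_ids)) + "\n")
    cols = {"cell_id": data.cell_ids, "x": data.coords[:, 0], "y": data.coords[:, 1]}
    if data.coords.shape[1] == 3:
        cols["z"] = data.coords[:, 2]
    pd.DataFrame(cols).to_csv(paths["coords"], index=False)
    return paths
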