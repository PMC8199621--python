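"""Quality filtering, normalisation, feature selection, embedding, clustering.

The conventional scRNA-seq stack: cells with too few detected genes and
genes detected in too few cells are removed (cells first, then genes);
counts are depth-normalised to a fixed library size and log1p-transformed;
highly variable genes are ranked by variance-stabilised dispersion; PCA
feeds a k-nearest-neighbour graph, a 2-D UMAP embedding, and Leiden
community clustering.  All seeded operations are reproducible for a fixed
seed; PCA components are sign-fixed so that each component's
largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import CountMatrix

DEFAULT_LIBRARY_SIZE = 1e4


@dataclass
class QCThresholds:
    """Cell/gene retention thresholds.

    ``max_fraction_top_gene`` flags degenerate cells dominated by a single
    gene (a stand-in for the mitochondrial-fraction filter when genes carry
    no mitochondrial annotation, as in synthetic data).
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_fraction_top_gene: float = 1.0

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.max_fraction_top_gene <= 1:
            raise ValueError("max_fraction_top_gene must be in (0, 1]")


@dataclass
class EmbeddingResult:
    """Reduced representations of a cell population."""

    hvg_ids: list[str]
    pcs: np.ndarray
    coords_2d: np.ndarray | None = None
    knn_indices: np.ndarray | None = None
    knn_distances: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def qc_filter(matrix: CountMatrix, thresholds: QCThresholds) -> tuple[CountMatrix, dict]:
    """Remove low-quality cells, then rarely detected genes.

    Filter order is cells first, then genes, so the gene filter sees only
    retained cells.  Idempotent: re-applying the same thresholds to the
    output removes nothing.

    Returns the filtered matrix plus a report dict of removed counts.
    """
    counts = matrix.counts.tocsc()
    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    depth = np.asarray(counts.sum(axis=0)).ravel()
    top = np.asarray(counts.max(axis=0).todense()).ravel() if counts.nnz else np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore"):
        top_frac = np.where(depth > 0, top / np.maximum(depth, 1), 1.0)
    keep_cells = (genes_per_cell >= thresholds.min_genes_per_cell) & (
        top_frac <= thresholds.max_fraction_top_gene)

    if not keep_cells.any():
        raise ValueError("QC filter removed every cell")
    filtered = matrix.subset_cells(keep_cells)

    cells_per_gene = np.asarray((filtered.counts > 0).sum(axis=1)).ravel()
    keep_genes = cells_per_gene >= thresholds.min_cells_per_gene
    filtered = filtered.subset_genes(keep_genes)

    report = {
        "cells_removed": int((~keep_cells).sum()),
        "genes_removed": int((~keep_genes).sum()),
        "cells_kept": filtered.n_cells,
        "genes_kept": filtered.n_genes,
    }
    return filtered, report


def normalize_log(
    matrix: CountMatrix,
    library_size: float = DEFAULT_LIBRARY_SIZE,
    scale: bool = False,
) -> np.ndarray:
    """Depth-normalise to ``library_size`` UMIs per cell and log1p.

    Returns a dense genes x cells array.  With ``scale=True`` genes are
    additionally centred and unit-scaled (for PCA input).  Cells with zero
    total counts must be removed by QC first.
    """
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")
    counts = matrix.counts.astype(float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    if (depth == 0).any():
        raise ValueError("matrix contains zero-total cells; run qc_filter first")
    norm = counts.multiply(library_size / depth).toarray()
    expr = np.log1p(norm)
    if scale:
        mu = expr.mean(axis=1, keepdims=True)
        sd = expr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        expr = (expr - mu) / sd
    return expr


def select_hvg(expr: np.ndarray, gene_ids: list[str], n_hvg: int = 2000) -> list[str]:
    """Rank genes by variance-stabilised dispersion and return the top ``n_hvg``.

    Dispersion is var/mean of the log-normalised expression, z-scored within
    20 mean-expression bins (Seurat-style ``mean.var.plot`` flavour).
    """
    if n_hvg > expr.shape[0]:
        raise ValueError("n_hvg exceeds gene count")
    mean = expr.mean(axis=1)
    var = expr.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    # z-score dispersion within mean-expression bins
    order = np.argsort(mean)
    n_bins = min(20, max(1, expr.shape[0] // 10))
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / (sd if sd > 0 else 1.0)
    top = np.argsort(-z, kind="stable")[:n_hvg]
    return [gene_ids[i] for i in sorted(top)]


def run_pca(expr: np.ndarray, k: int = 30) -> np.ndarray:
    """PCA scores (cells x k) of a genes x cells expression table.

    Genes are centred; each component is oriented so its largest-magnitude
    loading is positive, making scores reproducible up to numerical noise.
    """
    n_genes, n_cells = expr.shape
    if k > min(n_genes, n_cells):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(n_genes, n_cells)}")
    x = expr.T  # cells x genes
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest |loading| positive per component
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


def build_knn(pcs: np.ndarray, n_neighbors: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """k-nearest-neighbour indices/distances (self excluded) in PC space."""
    n = pcs.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    return idx[:, 1:], dist[:, 1:]


def embed_2d(pcs: np.ndarray, seed: int = 0, n_neighbors: int = 15,
             min_dist: float = 0.3) -> np.ndarray:
    """Seeded 2-D UMAP of PCA scores."""
    import umap  # deferred: numba compilation is expensive at import

    n_neighbors = min(n_neighbors, pcs.shape[0] - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(pcs)
    return np.asarray(coords, dtype=float)


def cluster_graph(knn_indices: np.ndarray, resolution: float = 0.8,
                  seed: int = 0) -> np.ndarray:
    """Leiden community labels on an undirected kNN graph (no self-loops)."""
    import igraph
    import leidenalg

    n = knn_indices.shape[0]
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in knn_indices[i] if i != j}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)
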