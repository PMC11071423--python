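"""Normalization, dimensionality reduction, joint neighbor graph and
clustering for the paired modalities, plus fragment-derived gene activity.

RNA is depth-normalized as log1p(CP10K) (an analytic Pearson-residual mode is
available); ATAC peaks are TF-IDF normalized and reduced by LSI with the
depth-tracking first component dropped.  The joint graph weights the two
modalities' shared-nearest-neighbor similarities equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from . import io as fio

LOG_CP10K = "LOG_CP10K"
PEARSON = "PEARSON_RESIDUAL"
TFIDF = "TFIDF"


@dataclass
class NormalizedMatrix:
    values: np.ndarray  # features x cells, dense
    feature_ids: np.ndarray
    barcodes: np.ndarray
    method: str


@dataclass
class Embedding:
    coords: np.ndarray  # cells x dims (the retained dims only)
    dims_used: tuple
    modality: str
    singular_values: np.ndarray | None = None
    dropped_first: np.ndarray | None = None  # LSI component-1 scores (depth proxy)


def normalize_rna(counts: fio.CountMatrix, method: str = LOG_CP10K) -> NormalizedMatrix:
    """Depth-normalize RNA counts.

    Default: ``log1p(1e4 * x / cell_total)``.  ``PEARSON_RESIDUAL`` gives
    analytic Pearson residuals under a Poisson depth model, clipped at
    ``sqrt(n_cells)``.
    """
    X = np.asarray(counts.values.todense(), dtype=float)
    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; filter cells first")
    if method == LOG_CP10K:
        vals = np.log1p(1e4 * X / totals)
    elif method == PEARSON:
        n = X.shape[1]
        gene_tot = X.sum(axis=1, keepdims=True)
        mu = gene_tot * totals[None, :] / totals.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (X - mu) / np.sqrt(mu + 1e-12)
        vals = np.clip(np.nan_to_num(vals), -np.sqrt(n), np.sqrt(n))
    else:
        raise ValueError(f"unknown RNA normalization {method!r}")
    return NormalizedMatrix(vals, counts.feature_ids, counts.barcodes, method)


def run_tfidf(peak_counts: fio.CountMatrix) -> NormalizedMatrix:
    """TF-IDF normalize peak counts: ``log1p(1e4 * TF * IDF)`` with
    TF = count / cell total and IDF = n_cells / n_cells detecting the peak.
    Peaks detected nowhere yield all-zero rows."""
    X = sp.csr_matrix(peak_counts.values, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    totals = np.maximum(totals, 1e-12)
    n_cells = X.shape[1]
    det = np.asarray((X > 0).sum(axis=1)).ravel()
    idf = np.zeros(X.shape[0])
    nz = det > 0
    idf[nz] = n_cells / det[nz]
    tf = X.multiply(1.0 / totals[None, :])
    vals = tf.multiply(idf[:, None]).tocsr()
    vals.data = np.log1p(1e4 * vals.data)
    return NormalizedMatrix(
        np.asarray(vals.todense()), peak_counts.feature_ids, peak_counts.barcodes, TFIDF
    )


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Deterministic SVD orientation: the largest-|loading| feature of each
    component gets a positive loading."""
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            scores[:, k] *= -1
    return components, scores


def run_lsi(tfidf: NormalizedMatrix, n_components: int = 25) -> Embedding:
    """Truncated SVD of the TF-IDF matrix; component 1 (depth) is dropped."""
    X = tfidf.values  # features x cells
    if n_components >= min(X.shape):
        raise ValueError("n_components must be < min(matrix dims)")
    # full SVD on the smaller gram; deterministic
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    comps = U[:, :n_components].T  # components x features
    scores = Vt[:n_components].T * s[:n_components]  # cells x components
    comps, scores = _fix_signs(comps, scores)
    dims = tuple(range(2, n_components + 1))
    return Embedding(
        scores[:, 1:n_components],
        dims,
        "ATAC",
        singular_values=s[:n_components],
        dropped_first=scores[:, 0],
    )


def run_pca(norm: NormalizedMatrix, n_components: int = 25, scale: bool = True) -> Embedding:
    """PCA scores of the normalized RNA matrix (features centered, unit-scaled)."""
    X = norm.values
    if X.shape[0] < n_components:
        raise ValueError("fewer features than components")
    Xc = X - X.mean(axis=1, keepdims=True)
    if scale:
        sd = Xc.std(axis=1, keepdims=True)
        Xc = Xc / np.maximum(sd, 1e-12)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = U[:, :n_components].T
    scores = Vt[:n_components].T * s[:n_components]
    comps, scores = _fix_signs(comps, scores)
    return Embedding(scores[:, :n_components], tuple(range(1, n_components + 1)), "RNA",
                     singular_values=s[:n_components])


# ---------------------------------------------------------------------------
# gene activity


def gene_activity(
    fragments: pd.DataFrame,
    gene_model: pd.DataFrame,
    barcodes,
    upstream: int = 2000,
) -> fio.CountMatrix:
    """Count fragments (weighted by their count field) overlapping each gene's
    body extended ``upstream`` bp beyond the TSS, strand-aware.  A fragment
    overlapping several gene windows counts for each of them."""
    barcodes = np.asarray(barcodes, dtype=object)
    bc_index = {b: i for i, b in enumerate(barcodes)}
    genes = fio.validate_gene_model(gene_model)
    n_genes, n_cells = len(genes), len(barcodes)
    out = np.zeros((n_genes, n_cells), dtype=np.int64)

    if len(fragments):
        keep = fragments["barcode"].isin(bc_index).to_numpy()
        frag = fragments.loc[keep]
        cidx = frag["barcode"].map(bc_index).to_numpy()
        win_start = np.where(genes["strand"] == "+", genes["start"] - upstream, genes["start"])
        win_end = np.where(genes["strand"] == "+", genes["end"], genes["end"] + upstream)
        win_start = np.maximum(win_start, 0)
        for chrom, sub_idx in frag.groupby("chrom", sort=False).indices.items():
            g_mask = (genes["chrom"] == chrom).to_numpy()
            if not g_mask.any():
                continue
            starts = frag["start"].to_numpy()[sub_idx]
            ends = frag["end"].to_numpy()[sub_idx]
            counts = frag["count"].to_numpy()[sub_idx]
            cells = cidx[sub_idx]
            order = np.argsort(starts, kind="stable")
            starts, ends, counts, cells = starts[order], ends[order], counts[order], cells[order]
            max_len = int((ends - starts).max())
            for g in np.flatnonzero(g_mask):
                ws, we = win_start[g], win_end[g]
                lo = np.searchsorted(starts, ws - max_len, side="left")
                hi = np.searchsorted(starts, we, side="left")
                if hi <= lo:
                    continue
                sel = ends[lo:hi] > ws
                if sel.any():
                    np.add.at(out[g], cells[lo:hi][sel], counts[lo:hi][sel])
    return fio.CountMatrix(sp.csr_matrix(out), genes["gene"].to_numpy(), barcodes, fio.GENE_ACTIVITY)


# ---------------------------------------------------------------------------
# joint graph and clustering


@dataclass
class NeighborGraph:
    """Undirected weighted SNN graph over cells."""

    adjacency: sp.csr_matrix
    barcodes: np.ndarray


def _snn(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor Jaccard similarity from Euclidean kNN sets
    (each cell's set includes itself)."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be < n_cells")
    if np.allclose(coords.std(axis=0), 0):
        # degenerate constant embedding: every cell shares every neighbor set
        return sp.csr_matrix(np.ones((n, n)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )  # membership matrix, includes self
    inter = (A @ A.T).tocoo()
    set_size = k + 1
    jac = inter.data / (2 * set_size - inter.data)
    S = sp.csr_matrix((jac, (inter.row, inter.col)), shape=(n, n))
    S.setdiag(0)
    S.eliminate_zeros()
    return S


def joint_neighbor_graph(emb_rna: Embedding, emb_atac: Embedding, barcodes, k: int = 20) -> NeighborGraph:
    """Equal-weight joint SNN graph: 0.5 * SNN(RNA) + 0.5 * SNN(ATAC)."""
    if emb_rna.coords.shape[0] != emb_atac.coords.shape[0]:
        raise ValueError("embeddings must cover the same cells")
    S = 0.5 * _snn(emb_rna.coords, k) + 0.5 * _snn(emb_atac.coords, k)
    S = ((S + S.T) / 2).tocsr()  # enforce symmetry
    return NeighborGraph(adjacency=S, barcodes=np.asarray(barcodes, dtype=object))


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # small ints, contiguous from 0, ordered by size
    barcodes: np.ndarray
    resolution: float
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.barcodes, name="cluster")


def cluster_graph(graph: NeighborGraph, resolution: float = 0.1, seed: int = 0) -> ClusterAssignment:
    """Leiden community detection (RB-configuration modularity) on the SNN graph."""
    A = sp.triu(graph.adjacency, k=1).tocoo()
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    g = igraph.Graph(
        n=A.shape[0], edges=list(zip(A.row.tolist(), A.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=A.data.tolist(),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=5,
    )
    labels = np.array(part.membership)
    # relabel by descending cluster size for stable, contiguous ids
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[l] for l in labels])
    return ClusterAssignment(labels, graph.barcodes, resolution, seed)
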