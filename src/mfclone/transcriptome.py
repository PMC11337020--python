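"""Normalization, cell-cycle scoring/regression, HVG selection, PCA, SNN-Louvain
clustering and UMAP — the Seurat-equivalent transcriptomic core.

All numeric contracts are explicit: log-normalization is
``ln(1 + count / cell_total * scale_factor)``; module scores are mean
expression of a gene set minus expression-bin-matched control genes;
covariate removal is per-gene ordinary least squares with the intercept
added back; HVG ranking uses bin-normalized log dispersion; the number of
principal components is the elbow (largest second difference of the
variance curve) clamped to [15, 25].
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, ContractError
from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "Embedding",
    "ClusterLabels",
    "log_normalize",
    "score_gene_module",
    "regress_covariates",
    "select_hvg",
    "run_pca",
    "choose_n_pcs",
    "cluster_snn_louvain",
    "embed_umap",
]


@dataclass
class NormalizedMatrix:
    """Genes x cells matrix of (log-)normalized expression."""

    gene_symbols: list[str]
    gene_ids: list[str]
    cell_barcodes: list[str]
    x: np.ndarray | sp.spmatrix  # genes x cells
    scale_factor: float
    sample_id: str = ""

    @property
    def n_genes(self) -> int:
        return self.x.shape[0]

    @property
    def n_cells(self) -> int:
        return self.x.shape[1]

    def dense(self) -> np.ndarray:
        return self.x.toarray() if sp.issparse(self.x) else np.asarray(self.x)

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        lookup = {}
        for i, s in enumerate(self.gene_symbols):
            lookup.setdefault(s, i)  # first occurrence wins for duplicate symbols
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)

    def subset_cells(self, index) -> "NormalizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return NormalizedMatrix(
            gene_symbols=list(self.gene_symbols),
            gene_ids=list(self.gene_ids),
            cell_barcodes=[self.cell_barcodes[i] for i in index],
            x=self.x[:, index],
            scale_factor=self.scale_factor,
            sample_id=self.sample_id,
        )


@dataclass
class Embedding:
    """Cells x k coordinates; PCA embeddings retain what projection needs."""

    coords: np.ndarray
    kind: str  # "PCA" | "UMAP"
    cell_barcodes: list[str]
    variance_per_dim: Optional[np.ndarray] = None
    loadings: Optional[np.ndarray] = None  # genes x k, over `genes`
    genes: Optional[list[str]] = None
    center: Optional[np.ndarray] = None  # per-gene scaling used before PCA
    scale: Optional[np.ndarray] = None
    clip: float = 10.0

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def transform(self, x_genes_by_cells: np.ndarray) -> np.ndarray:
        """Project gene-space expression (over `genes`, genes x cells) into PC space."""
        if self.loadings is None:
            raise ContractError("embedding has no retained PCA loadings")
        z = (x_genes_by_cells - self.center[:, None]) / self.scale[:, None]
        np.clip(z, -self.clip, self.clip, out=z)
        return z.T @ self.loadings


@dataclass
class ClusterLabels:
    labels: pd.Series  # barcode -> dense integer label
    resolution: float
    n_clusters: int


def log_normalize(
    matrix: CountMatrix,
    scale_factor: Optional[float] = 1e4,
    layer: Optional[str] = None,
    log: bool = True,
) -> NormalizedMatrix:
    """Depth-normalize and log-transform: ``ln(1 + c / total * scale_factor)``.

    Cells with zero total counts map to all-zero columns. With
    ``scale_factor=None`` the median cell depth is used, keeping values on a
    count-like scale. With ``log=False`` the depth-normalized linear values
    are returned (used by the velocity stage, where the steady-state relation
    u = γ·s is linear in expression).
    """
    counts = matrix.layers[layer] if layer else matrix.counts
    counts = sp.csc_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if scale_factor is None:
        positive = totals[totals > 0]
        scale_factor = float(np.median(positive)) if len(positive) else 1.0
    inv = np.where(totals > 0, 1.0 / np.maximum(totals, 1e-300), 0.0)
    x = counts.multiply(inv[None, :] * scale_factor)
    x = sp.csc_matrix(x)
    if log:
        x.data = np.log1p(x.data)
    return NormalizedMatrix(
        gene_symbols=list(matrix.gene_symbols),
        gene_ids=list(matrix.gene_ids),
        cell_barcodes=list(matrix.cell_barcodes),
        x=sp.csr_matrix(x),
        scale_factor=scale_factor,
        sample_id=matrix.sample_id,
    )


def score_gene_module(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Expression-bin-controlled module score per cell.

    Score = mean expression of the module genes minus the mean expression of
    control genes drawn (with a seeded RNG) from the same average-expression
    bins. Deterministic given the seed.
    """
    idx = norm.gene_index(gene_set)
    if idx.size == 0:
        raise ConfigurationError("gene set has empty intersection with the matrix")
    x = norm.x
    gene_means = np.asarray(x.mean(axis=1)).ravel()
    order = np.argsort(gene_means, kind="stable")
    n_genes = len(gene_means)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.arange(n_genes) * n_bins // n_genes  # equal-size rank bins

    rng = np.random.default_rng(seed)
    ctrl_rows: list[int] = []
    by_bin = {b: np.flatnonzero(bins == b) for b in range(n_bins)}
    for g in idx:
        pool = by_bin[bins[g]]
        take = min(n_ctrl, len(pool))
        ctrl_rows.extend(rng.choice(pool, size=take, replace=False))
    ctrl_rows = np.unique(ctrl_rows)

    xc = sp.csr_matrix(x) if sp.issparse(x) else x
    set_mean = np.asarray(xc[idx, :].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(xc[ctrl_rows, :].mean(axis=0)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=norm.cell_barcodes, name="module_score")


def regress_covariates(norm: NormalizedMatrix, covariates: pd.DataFrame) -> NormalizedMatrix:
    """Remove per-cell covariate effects gene-wise by OLS; intercept added back.

    Collinear covariate columns are dropped with a warning.
    """
    cov = covariates.loc[norm.cell_barcodes] if not covariates.index.equals(
        pd.Index(norm.cell_barcodes)
    ) else covariates
    if not np.all(np.isfinite(cov.to_numpy(dtype=float))):
        raise ContractError("covariates must be finite")

    n = norm.n_cells
    X = np.column_stack([np.ones(n)] + [cov[c].to_numpy(dtype=float) for c in cov.columns])
    # drop columns that do not increase rank (constant or collinear)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate {cov.columns[j - 1]!r}", stacklevel=2)
    X = X[:, keep]

    Y = norm.dense()  # genes x cells
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # p x genes
    fitted = X @ beta
    out = Y - fitted.T + beta[0][:, None]  # residuals + intercept
    return NormalizedMatrix(
        gene_symbols=list(norm.gene_symbols),
        gene_ids=list(norm.gene_ids),
        cell_barcodes=list(norm.cell_barcodes),
        x=out,
        scale_factor=norm.scale_factor,
        sample_id=norm.sample_id,
    )


def select_hvg(norm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Top-``n`` genes by trend-corrected dispersion.

    Dispersion = var/mean of the back-transformed expression (expm1),
    log-transformed and z-scored within equal-size mean-expression bins
    (the Seurat-style mean-variance correction). Constant genes are never
    selected; if fewer than ``n`` variable genes exist, all are returned
    with a warning. Deterministic: ties break on gene symbol.
    """
    x = norm.x
    if sp.issparse(x):
        e = x.copy().tocsr()
        e.data = np.expm1(e.data)
        mean = np.asarray(e.mean(axis=1)).ravel()
        sq = e.copy()
        sq.data = sq.data**2
        var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    else:
        e = np.expm1(x)
        mean = e.mean(axis=1)
        var = e.var(axis=1)
    var = var * x.shape[1] / max(x.shape[1] - 1, 1)

    # relative threshold: numerically-constant genes carry no information
    variable = var > 1e-12 * (mean**2 + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(variable, np.log(np.maximum(var, 1e-300) / np.maximum(mean, 1e-300)), -np.inf)

    order = np.argsort(mean, kind="stable")
    n_genes = len(mean)
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.arange(n_genes) * n_bins // n_genes

    z = np.full(n_genes, -np.inf)
    for b in np.unique(bins):
        members = np.flatnonzero((bins == b) & variable)
        if members.size == 0:
            continue
        d = disp[members]
        sd = d.std()
        z[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    symbols = np.asarray(norm.gene_symbols, dtype=object)
    candidates = np.flatnonzero(variable)
    if candidates.size < n:
        warnings.warn(
            f"only {candidates.size} variable genes available (requested {n})", stacklevel=2
        )
    ranking = sorted(candidates, key=lambda i: (-z[i], str(symbols[i])))
    return [str(symbols[i]) for i in ranking[:n]]


def run_pca(
    norm: NormalizedMatrix,
    hvg: Sequence[str],
    n_pcs_max: int = 50,
    clip: float = 10.0,
    seed: int = 0,
) -> Embedding:
    """Scale the HVG submatrix (z-score capped at +/-clip) and run PCA."""
    idx = norm.gene_index(hvg)
    if idx.size == 0:
        raise ConfigurationError("no HVG present in the matrix")
    x = norm.x[idx, :]
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    center = x.mean(axis=1)
    scale = x.std(axis=1, ddof=1)
    scale[scale == 0] = 1.0
    z = (x - center[:, None]) / scale[:, None]
    np.clip(z, -clip, clip, out=z)

    n_comp = min(n_pcs_max, z.shape[1] - 1, z.shape[0])
    if n_comp < n_pcs_max:
        warnings.warn(f"reducing PCs from {n_pcs_max} to {n_comp} (matrix too small)", stacklevel=2)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(z.T)

    # deterministic sign convention: largest-|loading| entry positive per component
    loadings = pca.components_.T  # genes x k
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    coords = coords * flip

    symbols = np.asarray(norm.gene_symbols, dtype=object)[idx]
    return Embedding(
        coords=coords,
        kind="PCA",
        cell_barcodes=list(norm.cell_barcodes),
        variance_per_dim=pca.explained_variance_,
        loadings=loadings,
        genes=[str(s) for s in symbols],
        center=center,
        scale=scale,
        clip=clip,
    )


def choose_n_pcs(variance_per_dim: np.ndarray, lo: int = 15, hi: int = 25) -> int:
    """Elbow rule: the last PC before the curvature maximum of the variance
    curve (largest second difference), clamped to the configured [lo, hi]
    window."""
    v = np.asarray(variance_per_dim, dtype=float)
    if len(v) < 3:
        return int(np.clip(len(v), 1, hi))
    d2 = v[:-2] - 2 * v[1:-1] + v[2:]  # d2[j] is curvature centered on PC j+2
    knee = int(np.argmax(d2)) + 1  # keep everything before the flattening
    return int(np.clip(knee, lo, min(hi, len(v))))


def snn_graph(coords: np.ndarray, n_neighbors: int = 20, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights (pruned)."""
    n = coords.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, ind = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in ind]  # includes self

    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in ind[i]:
            j = int(j)
            if j == i or (min(i, j), max(i, j)) in seen:
                continue
            seen.add((min(i, j), max(i, j)))
            shared = len(neighbor_sets[i] & neighbor_sets[j])
            jac = shared / (2 * (k + 1) - shared)
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_snn_louvain(
    embedding: Embedding,
    n_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterLabels:
    """Louvain modularity clustering on the SNN graph of the PC embedding.

    Deterministic given the seed; labels are re-indexed by decreasing cluster
    size. With too few cells a single cluster is returned with a warning.
    """
    coords = embedding.coords
    n = coords.shape[0]
    if n <= n_neighbors:
        warnings.warn(f"only {n} cells (<= n_neighbors={n_neighbors}); returning one cluster", stacklevel=2)
        labels = pd.Series(np.zeros(n, dtype=int), index=embedding.cell_barcodes, name="cluster")
        return ClusterLabels(labels=labels, resolution=resolution, n_clusters=1)

    g = snn_graph(coords, n_neighbors=n_neighbors)
    random.seed(seed)  # igraph draws from Python's random module
    part = g.community_multilevel(weights=g.es["weight"], resolution=resolution)
    membership = np.asarray(part.membership)

    sizes = pd.Series(membership).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    dense = np.array([remap[m] for m in membership])
    labels = pd.Series(dense, index=embedding.cell_barcodes, name="cluster")
    return ClusterLabels(labels=labels, resolution=resolution, n_clusters=int(dense.max()) + 1)


def embed_umap(embedding: Embedding, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.3) -> Embedding:
    """2-D UMAP of the PC embedding; visualization only, deterministic per seed."""
    import umap

    n = embedding.coords.shape[0]
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, max(2, n - 1)),
        min_dist=min_dist,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        coords = reducer.fit_transform(embedding.coords)
    return Embedding(coords=np.asarray(coords, dtype=float), kind="UMAP", cell_barcodes=list(embedding.cell_barcodes))
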