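"""Steady-state RNA velocity and transition-distance statistics.

Under first-order splicing kinetics at steady state, unspliced abundance is
proportional to spliced abundance, u = γ·s. γ is fitted per gene by a
zero-intercept least-squares regression restricted to cells at the extremes
of the spliced distribution (where the steady-state assumption is most
credible); velocity is the residual v = u − γ·s after k-NN smoothing of both
layers in PC space. Future states x + v·dt are pushed through the retained
PCA loadings, and the transition distance td = √(ΔPC1² + ΔPC2²) is
summarized per sample by its median and inter-quartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, ContractError
from .transcriptome import Embedding

__all__ = [
    "VelocityModel",
    "VelocitySummary",
    "fit_gamma",
    "compute_velocity",
    "project_future",
    "transition_distance",
    "vector_field",
]


@dataclass
class VelocityModel:
    """Per-gene degradation/splicing ratios from the steady-state fit."""

    gamma: np.ndarray  # per gene, >= 0 (NaN for unused genes)
    used: np.ndarray  # per gene flag
    fit_quantile: float


@dataclass
class VelocitySummary:
    """Per-cell transition distances plus per-sample medians and IQRs."""

    per_cell: pd.DataFrame  # barcode, sample, td, td_normalized
    per_sample: pd.DataFrame  # sample, median_td, iqr_td, median_td_raw, iqr_td_raw, n_cells


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)


def fit_gamma(
    spliced,
    unspliced,
    extreme_quantile: float = 0.05,
    min_cells_expressing: int = 20,
) -> VelocityModel:
    """Zero-intercept steady-state fit of unspliced on spliced, per gene.

    Only cells in the bottom/top ``extreme_quantile`` of each gene's spliced
    expression enter the fit. Genes expressed (spliced or unspliced > 0) in
    fewer than ``min_cells_expressing`` cells are flagged unused.
    """
    if spliced is None or unspliced is None:
        raise ConfigurationError("velocity requires spliced/unspliced layers")
    s = _dense(spliced)
    u = _dense(unspliced)
    if s.shape != u.shape:
        raise ConfigurationError(f"layer shapes differ: {s.shape} vs {u.shape}")

    n_genes, n_cells = s.shape
    gamma = np.full(n_genes, np.nan)
    used = np.zeros(n_genes, dtype=bool)

    lo_q, hi_q = extreme_quantile, 1.0 - extreme_quantile
    for g in range(n_genes):
        expressed = int(((s[g] > 0) | (u[g] > 0)).sum())
        if expressed < min_cells_expressing:
            continue
        sg, ug = s[g], u[g]
        lo, hi = np.quantile(sg, [lo_q, hi_q])
        mask = (sg <= lo) | (sg >= hi)
        ss = float(np.sum(sg[mask] ** 2))
        if ss == 0:
            gamma[g] = 0.0
            used[g] = True
            continue
        gamma[g] = max(float(np.sum(ug[mask] * sg[mask]) / ss), 0.0)
        used[g] = True
    return VelocityModel(gamma=gamma, used=used, fit_quantile=extreme_quantile)


def knn_smooth(x: np.ndarray, pc_coords: np.ndarray, k: int = 30) -> np.ndarray:
    """Average each cell's profile with its k nearest neighbors in PC space."""
    n_cells = pc_coords.shape[0]
    k = min(k, n_cells - 1)
    if k < 1:
        return x
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pc_coords)
    _, ind = nn.kneighbors(pc_coords)
    return x[:, ind.ravel()].reshape(x.shape[0], n_cells, k + 1).mean(axis=2)


def compute_velocity(
    spliced,
    unspliced,
    model: VelocityModel,
    pc_coords: Optional[np.ndarray] = None,
    k: int = 30,
) -> np.ndarray:
    """Per-gene, per-cell velocity v = u − γ·s on used genes (NaN-free rows).

    When PC coordinates are given, both layers are k-NN-smoothed first so the
    residual reflects neighborhood expression rather than shot noise.
    """
    s = _dense(spliced)
    u = _dense(unspliced)
    if pc_coords is not None:
        s = knn_smooth(s, pc_coords, k)
        u = knn_smooth(u, pc_coords, k)
    gamma = np.where(model.used, model.gamma, 0.0)
    v = u - gamma[:, None] * s
    v[~model.used, :] = 0.0
    return v


def project_future(
    pc_embedding: Embedding,
    current: np.ndarray,
    velocity: np.ndarray,
    dt: float = 1.0,
) -> np.ndarray:
    """ΔPC from extrapolated expression.

    Future expression = current + v·dt, floored at 0 gene-wise, then pushed
    through the PCA scaling + loadings retained in the embedding; returns
    future − current coordinates (cells x k).
    """
    if pc_embedding.loadings is None:
        raise ContractError("PC embedding lacks loadings; re-run PCA retaining them")
    future = np.maximum(current + velocity * dt, 0.0)
    pc_now = pc_embedding.transform(current)
    pc_future = pc_embedding.transform(future)
    return pc_future - pc_now


def project_future_expression(
    pc_embedding: Embedding,
    s_norm: np.ndarray,
    velocity: np.ndarray,
    dt: float = 1.0,
) -> np.ndarray:
    """ΔPC from a linear-scale extrapolation.

    ``s_norm`` and ``velocity`` live on depth-normalized linear expression;
    the current and extrapolated states are log1p-transformed before being
    pushed through the PCA transform, so the displacement is measured in the
    same space the embedding was built in.
    """
    future = np.maximum(s_norm + velocity * dt, 0.0)
    pc_now = pc_embedding.transform(np.log1p(s_norm))
    pc_future = pc_embedding.transform(np.log1p(future))
    return pc_future - pc_now


def transition_distance(
    delta_pc: np.ndarray,
    cell_barcodes: list[str],
    samples: Optional[pd.Series] = None,
) -> VelocitySummary:
    """Transition distance td = √(ΔPC1² + ΔPC2²) with per-sample summaries.

    Within each sample, td is normalized as (td − min)/max (the study's
    printed convention; see methods for the strict min–max variant), and the
    median and IQR (q75 − q25, linear-interpolation quantiles) are computed
    over the normalized values. Raw-scale summaries are reported alongside.
    """
    td = np.hypot(delta_pc[:, 0], delta_pc[:, 1])
    if samples is None:
        samples = pd.Series(["all"] * len(td), index=cell_barcodes)
    samples = samples.loc[cell_barcodes]

    per_cell = pd.DataFrame(
        {"barcode": cell_barcodes, "sample": samples.to_numpy(), "td": td}
    )
    norm_vals = np.empty_like(td)
    rows = []
    for sample, grp in per_cell.groupby("sample", sort=True):
        t = grp["td"].to_numpy()
        if t.max() == 0:
            warnings.warn(f"sample {sample!r}: all transition distances are 0", stacklevel=2)
            tn = np.zeros_like(t)
        else:
            tn = (t - t.min()) / t.max()
        norm_vals[grp.index.to_numpy()] = tn
        q25n, q50n, q75n = np.quantile(tn, [0.25, 0.5, 0.75])
        q25, q50, q75 = np.quantile(t, [0.25, 0.5, 0.75])
        rows.append(
            {
                "sample": sample,
                "median_td": float(q50n),
                "iqr_td": float(q75n - q25n),
                "median_td_raw": float(q50),
                "iqr_td_raw": float(q75 - q25),
                "n_cells": len(t),
            }
        )
    per_cell["td_normalized"] = norm_vals
    return VelocitySummary(per_cell=per_cell, per_sample=pd.DataFrame(rows))


def transition_distance_minmax(td: np.ndarray) -> np.ndarray:
    """Strict min–max normalization variant, (td − min)/(max − min)."""
    span = td.max() - td.min()
    return (td - td.min()) / span if span > 0 else np.zeros_like(td)


def embedding_displacement(
    embedding_coords: np.ndarray,
    expression: np.ndarray,
    velocity: np.ndarray,
    k: int = 30,
) -> np.ndarray:
    """Correlation-based projection of velocities onto the 2-D embedding.

    For each cell, neighbors whose expression offset correlates positively
    with the cell's velocity vector pull the displacement in their direction;
    the result is the correlation-weighted mean of unit directions to those
    neighbors (velocyto-class embedding projection).
    """
    n = embedding_coords.shape[0]
    k = min(k, n - 1)
    disp = np.zeros((n, 2))
    if k < 1:
        return disp
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding_coords)
    _, ind = nn.kneighbors(embedding_coords)
    X = expression.T  # cells x genes
    V = velocity.T
    for i in range(n):
        v = V[i]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        weights, dirs = [], []
        for j in ind[i][1:]:
            dx = X[j] - X[i]
            ndx = np.linalg.norm(dx)
            d2 = embedding_coords[j] - embedding_coords[i]
            nd2 = np.linalg.norm(d2)
            if ndx == 0 or nd2 == 0:
                continue
            corr = float(np.dot(dx, v) / (ndx * nv))
            if corr > 0:
                weights.append(corr)
                dirs.append(d2 / nd2)
        if weights:
            w = np.asarray(weights)
            disp[i] = (w[:, None] * np.asarray(dirs)).sum(axis=0) / w.sum()
    return disp


def vector_field(
    umap_coords: np.ndarray,
    displacement: np.ndarray,
    grid: int = 30,
    min_weight: float = 1e-3,
) -> pd.DataFrame:
    """Gaussian-kernel arrow grid over the embedding (visualization export).

    Grid points with no nearby cell emit no arrow.
    """
    lo = umap_coords.min(axis=0)
    hi = umap_coords.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    gx = np.linspace(lo[0], hi[0], grid)
    gy = np.linspace(lo[1], hi[1], grid)
    sigma = float(span.max() / grid)

    rows = []
    for x in gx:
        for y in gy:
            d2 = ((umap_coords - [x, y]) ** 2).sum(axis=1)
            w = np.exp(-d2 / (2 * sigma**2))
            total = w.sum()
            if total < min_weight:
                continue
            arrow = (w[:, None] * displacement).sum(axis=0) / total
            rows.append({"x": float(x), "y": float(y), "dx": float(arrow[0]), "dy": float(arrow[1])})
    return pd.DataFrame(rows)
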