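"""InferCNV-style copy-number scoring from smoothed, reference-centered
expression along genomic coordinates.

Per gene, log-normalized expression is centered on the reference-cell mean
and capped at ±clip reference standard deviations; the centered values are
then smoothed along the chromosome with a centered moving average that never
crosses chromosome boundaries (the window shrinks at edges), and finally each
cell is re-centered by its own median score. Scores stay continuous — no HMM
state calling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .io import GenePositionTable
from .transcriptome import NormalizedMatrix

__all__ = ["CNVMatrix", "order_genes", "cnv_scores", "clone_cnv_profile", "detect_blocks"]

logger = logging.getLogger(__name__)


@dataclass
class CNVMatrix:
    """Cells x (genomically ordered genes) smoothed CNV scores."""

    scores: np.ndarray  # cells x ordered genes
    cell_barcodes: list[str]
    genes: list[str]  # genomic order
    boundaries: dict[str, tuple[int, int]]  # chrom -> [start, end) in gene-index space
    reference_cells: list[str]

    def gene_span(self, chrom: str) -> slice:
        start, end = self.boundaries[chrom]
        return slice(start, end)


def order_genes(
    genes: Sequence[str],
    positions: GenePositionTable,
    min_genes_per_chrom: int = 5,
) -> tuple[list[str], dict[str, tuple[int, int]]]:
    """Genomic ordering of the genes present in both the matrix and the table.

    Returns the ordered gene list and per-chromosome [start, end) boundaries.
    Genes without a position, on unlisted chromosomes, or on chromosomes with
    fewer than ``min_genes_per_chrom`` placed genes are dropped (counts logged).
    Deterministic and invariant to the input order: sorted by (chromosome
    rank, start, gene name).
    """
    chrom_rank = {c: i for i, c in enumerate(positions.chromosomes)}
    placed = []
    n_unplaced = 0
    for g in genes:
        if g not in positions:
            n_unplaced += 1
            continue
        chrom = str(positions.chrom(g))
        if chrom not in chrom_rank:
            n_unplaced += 1
            continue
        placed.append((chrom_rank[chrom], positions.start(g), g, chrom))
    if not placed:
        raise ConfigurationError("no matrix gene has a genomic position")
    if n_unplaced:
        logger.info("order_genes: dropped %d genes without usable positions", n_unplaced)

    placed.sort()
    by_chrom: dict[str, list[str]] = {}
    for _, _, g, chrom in placed:
        by_chrom.setdefault(chrom, []).append(g)

    ordered: list[str] = []
    boundaries: dict[str, tuple[int, int]] = {}
    for chrom in positions.chromosomes:
        members = by_chrom.get(chrom, [])
        if len(members) < min_genes_per_chrom:
            if members:
                logger.info(
                    "order_genes: dropped chromosome %s (%d < %d genes)",
                    chrom, len(members), min_genes_per_chrom,
                )
            continue
        boundaries[chrom] = (len(ordered), len(ordered) + len(members))
        ordered.extend(members)
    return ordered, boundaries


def _moving_average_rows(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edges (cumsum based)."""
    n = x.shape[1]
    h = window // 2
    cs = np.cumsum(x, axis=1)
    cs = np.concatenate([np.zeros((x.shape[0], 1)), cs], axis=1)
    starts = np.maximum(np.arange(n) - h, 0)
    ends = np.minimum(np.arange(n) + h + 1, n)
    sums = cs[:, ends] - cs[:, starts]
    return sums / (ends - starts)[None, :]


def cnv_scores(
    norm: NormalizedMatrix,
    ordered_genes: Sequence[str],
    boundaries: Mapping[str, tuple[int, int]],
    reference_cells: Sequence[str],
    window: int = 101,
    clip: float = 3.0,
    min_reference_sd: float = 0.1,
) -> CNVMatrix:
    """Reference-centered, clipped, chromosome-wise smoothed CNV scores.

    Requires at least 10 reference cells and an odd window. A window wider
    than a chromosome shrinks to that chromosome's length (warned once).
    """
    reference_cells = list(reference_cells)
    if len(reference_cells) < 10:
        raise ConfigurationError(f"need >= 10 reference cells, got {len(reference_cells)}")
    if window % 2 == 0:
        raise ConfigurationError("smoothing window must be odd")

    gidx = norm.gene_index(ordered_genes)
    if len(gidx) != len(ordered_genes):
        raise ConfigurationError("ordered gene list contains genes absent from the matrix")
    x = norm.x[gidx, :]
    x = (x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)).T  # cells x genes

    ref_set = set(reference_cells)
    ref_rows = np.array([i for i, b in enumerate(norm.cell_barcodes) if b in ref_set])
    ref_mean = x[ref_rows].mean(axis=0)
    ref_sd = np.maximum(x[ref_rows].std(axis=0, ddof=1), min_reference_sd)

    centered = x - ref_mean[None, :]
    np.clip(centered, -clip * ref_sd[None, :], clip * ref_sd[None, :], out=centered)

    smoothed = np.empty_like(centered)
    for chrom, (start, end) in boundaries.items():
        span = end - start
        w = window
        if w >= span:
            w = span if span % 2 == 1 else span - 1
            warnings.warn(
                f"chromosome {chrom}: window {window} >= {span} genes; shrunk to {w}",
                stacklevel=2,
            )
        smoothed[:, start:end] = _moving_average_rows(centered[:, start:end], w)

    smoothed -= np.median(smoothed, axis=1)[:, None]  # per-cell median re-centering

    return CNVMatrix(
        scores=smoothed,
        cell_barcodes=list(norm.cell_barcodes),
        genes=list(ordered_genes),
        boundaries=dict(boundaries),
        reference_cells=reference_cells,
    )


def clone_cnv_profile(
    cnv: CNVMatrix,
    labels: pd.Series,
    subcluster_k: Optional[int] = None,
    seed: int = 0,
) -> dict:
    """Per-group mean CNV profiles, optionally with CNV-based sub-clustering
    of the malignant cells (intra-patient CNV heterogeneity)."""
    groups = sorted(set(labels.dropna()))
    profiles = {}
    for group in groups:
        rows = [i for i, b in enumerate(cnv.cell_barcodes) if labels.get(b) == group]
        if rows:
            profiles[group] = cnv.scores[rows].mean(axis=0)
    profile_df = pd.DataFrame(profiles, index=cnv.genes).T

    subclusters = None
    if subcluster_k and subcluster_k > 1:
        from sklearn.cluster import KMeans

        mal_rows = [i for i, b in enumerate(cnv.cell_barcodes) if labels.get(b) == "malignant"]
        if len(mal_rows) >= subcluster_k:
            km = KMeans(n_clusters=subcluster_k, n_init=10, random_state=seed)
            assign = km.fit_predict(cnv.scores[mal_rows])
            subclusters = pd.Series(
                assign, index=[cnv.cell_barcodes[i] for i in mal_rows], name="cnv_subclone"
            )
    return {"profiles": profile_df, "subclusters": subclusters}


def detect_blocks(
    profile: np.ndarray,
    boundaries: Mapping[str, tuple[int, int]],
    block_size: int = 30,
    step: int = 5,
) -> pd.DataFrame:
    """Rank contiguous within-chromosome windows of ``block_size`` genes by the
    absolute mean of a CNV profile (gain/loss candidate regions)."""
    rows = []
    for chrom, (start, end) in boundaries.items():
        span = end - start
        size = min(block_size, span)
        for s in range(start, end - size + 1, step):
            seg = profile[s : s + size]
            rows.append(
                {
                    "chrom": chrom,
                    "start_index": s,
                    "end_index": s + size,
                    "mean_score": float(seg.mean()),
                    "abs_score": float(abs(seg.mean())),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["abs_score", "chrom", "start_index"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
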