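"""Per-cell quality gates and CD3-based T-cell identification.

A cell is kept when it clears all four viability gates simultaneously:
mitochondrial UMI fraction < 0.12, total UMI count > 500, detected genes
> 200 and > 40 distinct housekeeping genes with at least one UMI. All
thresholds are strict inequalities; boundary values fail.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, ContractError
from .io import CountMatrix, load_gene_list

__all__ = [
    "QCThresholds",
    "default_housekeeping_genes",
    "compute_cell_qc",
    "filter_cells",
    "identify_t_cells",
]

DEFAULT_CD3_GENES = ("CD3D", "CD3E", "CD3G")


class QCThresholds:
    """The four viability gates; defaults are the study's stated cut-offs."""

    def __init__(
        self,
        max_mito_fraction: float = 0.12,
        min_umi: int = 500,
        min_genes: int = 200,
        min_housekeeping: int = 40,
    ):
        self.max_mito_fraction = max_mito_fraction
        self.min_umi = min_umi
        self.min_genes = min_genes
        self.min_housekeeping = min_housekeeping

    def as_dict(self) -> dict:
        return dict(
            max_mito_fraction=self.max_mito_fraction,
            min_umi=self.min_umi,
            min_genes=self.min_genes,
            min_housekeeping=self.min_housekeeping,
        )


def default_housekeeping_genes() -> list[str]:
    return load_gene_list("housekeeping_genes")


def _resolve_mito_genes(symbols: Sequence[str], mito_rule: Union[str, Sequence[str]]) -> np.ndarray:
    """Row mask of mitochondrial genes from a symbol prefix or an explicit list."""
    symbols = np.asarray(symbols, dtype=object)
    if isinstance(mito_rule, str):
        prefix = mito_rule.lower()
        return np.array([str(s).lower().startswith(prefix) for s in symbols])
    mito_set = set(mito_rule)
    return np.array([s in mito_set for s in symbols])


def compute_cell_qc(
    matrix: CountMatrix,
    housekeeping_genes: Sequence[str] | None = None,
    mito_rule: Union[str, Sequence[str]] = "MT-",
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Compute the per-cell QC table (one row per barcode, in matrix order).

    ``mito_fraction`` is mitochondrial UMIs over total UMIs, defined as 0 for
    an empty cell. Housekeeping genes are matched by symbol; a symbol present
    several times counts once (distinct housekeepers).
    """
    if housekeeping_genes is None:
        housekeeping_genes = default_housekeeping_genes()
    if not len(housekeeping_genes):
        raise ConfigurationError("housekeeping gene list is empty")
    thresholds = thresholds or QCThresholds()

    counts = sp.csc_matrix(matrix.counts)
    symbols = np.asarray(matrix.gene_symbols, dtype=object)

    umi = np.asarray(counts.sum(axis=0)).ravel()
    gene_count = np.asarray((counts > 0).sum(axis=0)).ravel()

    mito_mask = _resolve_mito_genes(symbols, mito_rule)
    mito_umi = np.asarray(counts[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(umi > 0, mito_umi / np.maximum(umi, 1), 0.0)

    hk_set = set(housekeeping_genes)
    hk_rows = np.flatnonzero([s in hk_set for s in symbols])
    detected = counts[hk_rows, :] > 0
    # distinct housekeeping symbols with >=1 UMI (duplicate rows of a symbol count once)
    hk_symbols = symbols[hk_rows]
    if len(hk_rows):
        per_symbol = pd.DataFrame(detected.toarray(), index=hk_symbols)
        hk_expressed = per_symbol.groupby(level=0).any().sum(axis=0).to_numpy()
    else:
        hk_expressed = np.zeros(matrix.n_cells, dtype=int)

    passes = (
        (mito_fraction < thresholds.max_mito_fraction)
        & (umi > thresholds.min_umi)
        & (gene_count > thresholds.min_genes)
        & (hk_expressed > thresholds.min_housekeeping)
    )

    return pd.DataFrame(
        {
            "barcode": matrix.cell_barcodes,
            "umi_count": umi.astype(int),
            "gene_count": gene_count.astype(int),
            "mito_fraction": mito_fraction,
            "housekeeping_expressed": np.asarray(hk_expressed, dtype=int),
            "passes_qc": passes,
        }
    ).set_index("barcode")


def filter_cells(matrix: CountMatrix, qc: pd.DataFrame) -> CountMatrix:
    """Keep exactly the QC-passing cells; gene axis and layer order untouched."""
    missing = set(matrix.cell_barcodes) - set(qc.index)
    if missing:
        raise ContractError(f"QC table missing {len(missing)} barcodes present in the matrix")
    keep = qc.loc[matrix.cell_barcodes, "passes_qc"].to_numpy(dtype=bool)
    return matrix.subset_cells(keep)


def identify_t_cells(
    matrix: CountMatrix,
    cd3_genes: Sequence[str] = DEFAULT_CD3_GENES,
    min_umi: int = 1,
) -> pd.Series:
    """Flag T cells: at least ``min_umi`` UMIs summed over the CD3 gene set."""
    symbols = np.asarray(matrix.gene_symbols, dtype=object)
    rows = np.flatnonzero(np.isin(symbols, list(cd3_genes)))
    if rows.size == 0:
        raise ConfigurationError(f"none of the CD3 genes {list(cd3_genes)} are in the matrix")
    cd3_umi = np.asarray(sp.csc_matrix(matrix.counts)[rows, :].sum(axis=0)).ravel()
    return pd.Series(cd3_umi >= min_umi, index=matrix.cell_barcodes, name="is_t_cell")
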