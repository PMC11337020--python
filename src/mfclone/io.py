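"""Reading and writing the standard single-cell formats the pipeline touches.

Count matrices follow the 10x triplet convention: a MatrixMarket file with
genes as rows and cells as columns, a features table (1 column = symbol only,
>=2 columns = id, symbol[, type]) and a one-column barcodes list, each
optionally gzipped. VDJ contigs follow the Cell Ranger
``filtered_contig_annotations.csv`` schema.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

__all__ = [
    "CountMatrix",
    "ContigRecord",
    "GenePositionTable",
    "CHROMOSOMES",
    "read_count_matrix",
    "read_contig_annotations",
    "write_table",
    "read_table",
]

#: Ordered autosomes + X used for genomic ordering; other labels are dropped.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)


def _opener(path: Path) -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with optional spliced/unspliced layers."""

    gene_ids: list[str]
    gene_symbols: list[str]
    cell_barcodes: list[str]
    counts: sp.csr_matrix
    sample_id: str
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.layers = {k: sp.csr_matrix(v) for k, v in self.layers.items()}
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"gene annotation length mismatch: matrix has {n_genes} rows, "
                f"{len(self.gene_ids)} ids / {len(self.gene_symbols)} symbols"
            )
        if len(self.cell_barcodes) != n_cells:
            raise FormatError(
                f"barcode count {len(self.cell_barcodes)} != matrix columns {n_cells}"
            )
        if len(set(self.cell_barcodes)) != n_cells:
            raise FormatError(f"duplicate cell barcodes in sample {self.sample_id!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise FormatError(
                    f"layer {name!r} shape {layer.shape} != counts shape {self.counts.shape}"
                )

    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "CountMatrix":
        """Column subset (cells); gene axis untouched, layers sliced congruently."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            gene_symbols=list(self.gene_symbols),
            cell_barcodes=[self.cell_barcodes[i] for i in index],
            counts=self.counts[:, index],
            sample_id=self.sample_id,
            layers={k: v[:, index] for k, v in self.layers.items()},
        )

    def subset_genes(self, index: Sequence[int] | np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in index],
            gene_symbols=[self.gene_symbols[i] for i in index],
            cell_barcodes=list(self.cell_barcodes),
            counts=self.counts[index, :],
            sample_id=self.sample_id,
            layers={k: v[index, :] for k, v in self.layers.items()},
        )


@dataclass(frozen=True)
class ContigRecord:
    """One parsed row of a VDJ filtered-contig annotation table.

    ``productive`` is ``True``/``False`` when Cell Ranger printed a call and
    ``None`` when the call was indeterminate (the ``"None"`` dialect value).
    """

    barcode: str
    is_cell: bool
    high_confidence: bool
    chain: str
    productive: Optional[bool]
    cdr3_nt: Optional[str]
    umis: int
    v_gene: str = ""
    j_gene: str = ""
    c_gene: str = ""
    full_length: bool = True
    raw_clonotype_id: Optional[str] = None


class GenePositionTable:
    """Per-gene genomic intervals (1-based inclusive) on an ordered chromosome set."""

    def __init__(self, table: pd.DataFrame, chromosomes: Sequence[str] = CHROMOSOMES):
        required = {"gene", "chrom", "start", "end"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"gene position table missing columns: {sorted(missing)}")
        table = table.copy()
        # tolerate hg19-style "chr" prefixes
        table["chrom"] = table["chrom"].astype(str).str.replace("^chr", "", regex=True)
        if table["gene"].duplicated().any():
            dups = table.loc[table["gene"].duplicated(), "gene"].tolist()[:5]
            raise FormatError(f"duplicate genes in position table: {dups}")
        if (table["start"] > table["end"]).any():
            raise FormatError("gene position table has start > end")
        self.table = table.set_index("gene")
        self.chromosomes = tuple(str(c).removeprefix("chr") for c in chromosomes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def chrom(self, gene: str) -> str:
        return self.table.at[gene, "chrom"]

    def start(self, gene: str) -> int:
        return int(self.table.at[gene, "start"])

    @classmethod
    def read_tsv(cls, path: str | Path, **kw) -> "GenePositionTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, **kw)

    def write_tsv(self, path: str | Path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_gtf(cls, path: str | Path, **kw) -> "GenePositionTable":
        """Import gene intervals from a GTF annotation (gene features only)."""
        import pyranges

        gr = pyranges.read_gtf(str(path))
        df = gr.df
        df = df[df["Feature"] == "gene"]
        name_col = "gene_name" if "gene_name" in df.columns else "gene_id"
        out = pd.DataFrame(
            {
                "gene": df[name_col].values,
                "chrom": df["Chromosome"].astype(str).values,
                "start": df["Start"].values + 1,  # GTF via pyranges is 0-based half-open
                "end": df["End"].values,
                "strand": df.get("Strand", pd.Series(["+"] * len(df))).values,
            }
        ).drop_duplicates(subset="gene")
        return cls(out, **kw)


def _read_lines(path: Path) -> list[str]:
    with _opener(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    sample_id: str,
    layer_paths: Optional[dict[str, str | Path]] = None,
) -> CountMatrix:
    """Read a 10x-style MTX triplet into a :class:`CountMatrix`.

    A pure transcription of what is on disk: no reordering, duplicate gene
    symbols preserved. ``layer_paths`` may supply extra same-shape MTX files
    (e.g. ``{"spliced": ..., "unspliced": ...}``).
    """
    matrix_path = Path(matrix_path)
    features_path = Path(features_path)
    barcodes_path = Path(barcodes_path)

    mat = _read_mtx(matrix_path)
    feat_lines = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)

    if mat.shape[0] != len(feat_lines):
        raise FormatError(
            f"{features_path.name}: {len(feat_lines)} features but matrix declares "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path.name}: {len(barcodes)} barcodes but matrix declares "
            f"{mat.shape[1]} columns"
        )

    gene_ids, gene_symbols = [], []
    for line in feat_lines:
        parts = line.split("\t")
        if len(parts) == 1:
            gene_ids.append(parts[0])
            gene_symbols.append(parts[0])
        else:
            gene_ids.append(parts[0])
            gene_symbols.append(parts[1])

    layers = {}
    for name, lp in (layer_paths or {}).items():
        layer = _read_mtx(Path(lp))
        if layer.shape != mat.shape:
            raise FormatError(
                f"{Path(lp).name}: layer shape {layer.shape} != matrix shape {mat.shape}"
            )
        layers[name] = layer

    return CountMatrix(
        gene_ids=gene_ids,
        gene_symbols=gene_symbols,
        cell_barcodes=barcodes,
        counts=mat,
        sample_id=sample_id,
        layers=layers,
    )


def _read_mtx(path: Path) -> sp.csr_matrix:
    try:
        with _opener(path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # malformed header / body
        raise FormatError(f"{path.name}: not a readable MatrixMarket file ({exc})") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise FormatError(f"{path.name}: non-integer entries in count matrix")
    mat = sp.csr_matrix(mat)
    mat.data = np.round(mat.data).astype(np.int64).astype(np.float64)
    return mat


_CONTIG_REQUIRED = ["barcode", "is_cell", "high_confidence", "chain", "productive", "cdr3_nt", "umis"]


def _parse_flag(value) -> Optional[bool]:
    """Normalize the 10x boolean dialect: True/true/False/false/None/NA/''."""
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text in {"true", "t", "1"}:
        return True
    if text in {"false", "f", "0"}:
        return False
    return None  # "none", "na", ""


def read_contig_annotations(path: str | Path) -> list[ContigRecord]:
    """Parse a ``filtered_contig_annotations.csv`` into :class:`ContigRecord` rows."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CONTIG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing required columns {missing}")

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        cdr3_nt = d["cdr3_nt"].strip()
        if cdr3_nt.lower() in {"", "none", "na"}:
            cdr3_nt = None
        umis_raw = d["umis"].strip()
        records.append(
            ContigRecord(
                barcode=d["barcode"],
                is_cell=bool(_parse_flag(d["is_cell"])),
                high_confidence=bool(_parse_flag(d["high_confidence"])),
                chain=d["chain"].strip(),
                productive=_parse_flag(d["productive"]),
                cdr3_nt=cdr3_nt,
                umis=int(float(umis_raw)) if umis_raw else 0,
                v_gene=d.get("v_gene", ""),
                j_gene=d.get("j_gene", ""),
                c_gene=d.get("c_gene", ""),
                full_length=_parse_flag(d.get("full_length", "True")) is not False,
                raw_clonotype_id=d.get("raw_clonotype_id") or None,
            )
        )
    return records


def write_table(rows, path: str | Path, format: str = "csv") -> None:
    """Write a result table (DataFrame or list of dicts) as csv/tsv/json.

    Written so that reading it back (:func:`read_table`) reproduces the values.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    path = Path(path)
    if format == "csv":
        rows.to_csv(path, index=False)
    elif format == "tsv":
        rows.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(rows.to_dict(orient="records"), indent=1, default=str))
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path, format: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown table format {fmt!r}")


def load_gene_list(name_or_path: str | Path) -> list[str]:
    """Load a packaged resource gene list (by bare name) or a user file (by path)."""
    from importlib import resources as ir

    p = Path(name_or_path)
    if p.exists():
        lines = p.read_text().splitlines()
    else:
        ref = ir.files("mfclone.resources") / f"{name_or_path}.txt"
        lines = ref.read_text().splitlines()
    return [l.strip() for l in lines if l.strip() and not l.startswith("#")]
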