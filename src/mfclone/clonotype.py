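"""Clonotype construction and malignant-clone calling.

Clone identity is the set of (chain, CDR3 nucleotide) pairs recovered for a
cell. The most frequent clonotype in a lesion is taken to be the malignant
T-cell clone; everything else is the polyclonal reactive infiltrate. Cells
sequenced with only one chain of an otherwise fully paired clone are merged
back into that clone when the assignment is unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import NoTCRInformationError
from .io import ContigRecord

__all__ = [
    "CellChains",
    "Clonotype",
    "CloneCall",
    "build_cell_clonotypes",
    "reconcile_chain_subsets",
    "call_malignant_clone",
    "partition_cells",
]

USABLE_CHAINS = ("TRA", "TRB")

ChainPair = tuple[str, str]  # (chain, cdr3_nt)


@dataclass
class CellChains:
    """The recovered chain pairs of one cell, with per-pair support."""

    barcode: str
    pairs: frozenset[ChainPair]
    productive: dict[ChainPair, Optional[bool]]
    umis: dict[ChainPair, int]

    @property
    def is_paired(self) -> bool:
        chains = {c for c, _ in self.pairs}
        return "TRA" in chains and "TRB" in chains

    @property
    def total_umis(self) -> int:
        return sum(self.umis.values())


def clone_key(pairs: Iterable[ChainPair]) -> str:
    """Canonical clone identifier: sorted ``chain:cdr3`` joined by ';'."""
    return ";".join(f"{c}:{s}" for c, s in sorted(pairs))


@dataclass
class Clonotype:
    clone_key: str
    chains: frozenset[ChainPair]
    productive: bool
    cell_count: int
    total_umis: int = 0


@dataclass
class CloneCall:
    """Per-sample malignant-clone decision and the induced cell partition."""

    sample_id: str
    malignant_clone_key: str
    malignant_is_productive: bool
    dominance_ratio: float
    labels: pd.Series = field(repr=False)  # barcode -> malignant/reactive/unassigned
    malignant_fraction: float = float("nan")
    tie_warning: bool = False


def build_cell_clonotypes(contigs: Sequence[ContigRecord]) -> dict[str, CellChains]:
    """Collapse usable contigs to per-barcode chain-pair sets.

    Only cell-associated, high-confidence TRA/TRB contigs with a CDR3
    nucleotide sequence are used; at most the two best-supported contigs per
    chain (by UMIs, ties broken lexicographically on CDR3) are kept.
    """
    per_barcode: dict[str, list[ContigRecord]] = {}
    for rec in contigs:
        if not (rec.is_cell and rec.high_confidence):
            continue
        if rec.chain not in USABLE_CHAINS or rec.cdr3_nt is None:
            continue
        per_barcode.setdefault(rec.barcode, []).append(rec)

    out: dict[str, CellChains] = {}
    for barcode, recs in per_barcode.items():
        kept: list[ContigRecord] = []
        for chain in USABLE_CHAINS:
            chain_recs = [r for r in recs if r.chain == chain]
            chain_recs.sort(key=lambda r: (-r.umis, r.cdr3_nt))
            kept.extend(chain_recs[:2])
        if not kept:
            continue
        pairs = frozenset((r.chain, r.cdr3_nt) for r in kept)
        productive: dict[ChainPair, Optional[bool]] = {}
        umis: dict[ChainPair, int] = {}
        for r in kept:
            pair = (r.chain, r.cdr3_nt)
            umis[pair] = umis.get(pair, 0) + r.umis
            prev = productive.get(pair)
            productive[pair] = r.productive if prev is None else prev
        out[barcode] = CellChains(barcode, pairs, productive, umis)
    return out


def reconcile_chain_subsets(cell_clonotypes: Mapping[str, CellChains]) -> dict[str, str]:
    """Assign each cell a clone key, merging single-chain cells into paired clones.

    A cell whose pair set is a proper non-empty subset of exactly one fully
    paired clone's pair set inherits that clone's key; a cell compatible with
    two or more paired clones keeps its own key (ambiguous). Fully paired
    cells are never re-assigned.
    """
    # paired clones = distinct pair sets containing both chains
    paired_sets: dict[frozenset[ChainPair], str] = {}
    for cell in cell_clonotypes.values():
        if cell.is_paired:
            paired_sets.setdefault(cell.pairs, clone_key(cell.pairs))

    assignment: dict[str, str] = {}
    for barcode, cell in cell_clonotypes.items():
        own = clone_key(cell.pairs)
        if cell.is_paired:
            assignment[barcode] = own
            continue
        hosts = {key for pairs, key in paired_sets.items() if cell.pairs < pairs}
        assignment[barcode] = hosts.pop() if len(hosts) == 1 else own
    return assignment


def summarize_clonotypes(
    cell_clonotypes: Mapping[str, CellChains], assignment: Mapping[str, str]
) -> dict[str, Clonotype]:
    """Aggregate cells into clonotypes after reconciliation."""
    clones: dict[str, Clonotype] = {}
    for barcode, key in assignment.items():
        cell = cell_clonotypes[barcode]
        if key not in clones:
            clones[key] = Clonotype(
                clone_key=key,
                chains=cell.pairs,
                productive=True,
                cell_count=0,
            )
        clone = clones[key]
        clone.cell_count += 1
        clone.total_umis += cell.total_umis
        # union of chains observed across member cells (subset cells add nothing new)
        clone.chains = clone.chains | cell.pairs
        if any(cell.productive.get(p) is not True for p in cell.pairs):
            clone.productive = False
    return clones


def call_malignant_clone(
    cell_clonotypes: Mapping[str, CellChains],
    sample_id: str,
    min_fraction: float = 0.10,
) -> tuple[str, bool, float, bool]:
    """Pick the malignant clone for one sample.

    Returns ``(clone_key, is_productive, dominance_ratio, tie_warning)``.
    Productive clones are considered first; if none reaches ``min_fraction``
    of TCR-bearing cells, a dominant non-productive clone may be called (the
    non-productive-TCR tumour case). Ties break on total UMI support, then
    lexicographic clone key, and are reported.
    """
    if not cell_clonotypes:
        raise NoTCRInformationError(f"sample {sample_id!r}: no TCR information")
    assignment = reconcile_chain_subsets(cell_clonotypes)
    clones = summarize_clonotypes(cell_clonotypes, assignment)
    n_tcr = len(assignment)

    def ranked(cands: list[Clonotype]) -> list[Clonotype]:
        return sorted(cands, key=lambda c: (-c.cell_count, -c.total_umis, c.clone_key))

    productive = ranked([c for c in clones.values() if c.productive])
    everything = ranked(list(clones.values()))

    winner: Optional[Clonotype] = None
    if productive and productive[0].cell_count / n_tcr >= min_fraction:
        winner = productive[0]
    elif everything and everything[0].cell_count / n_tcr >= min_fraction:
        winner = everything[0]  # dominant but non-productive clone
    if winner is None:
        raise NoTCRInformationError(
            f"sample {sample_id!r}: no clonotype reaches the dominance threshold "
            f"({min_fraction:.0%} of {n_tcr} TCR-bearing cells)"
        )

    runners = [c for c in everything if c.clone_key != winner.clone_key]
    second = runners[0].cell_count if runners else 1
    dominance_ratio = winner.cell_count / max(second, 1)

    tie = bool(
        runners
        and runners[0].cell_count == winner.cell_count
        and runners[0].total_umis == winner.total_umis
    )
    if tie:
        warnings.warn(
            f"sample {sample_id!r}: top clonotypes tied at {winner.cell_count} cells; "
            "winner chosen lexicographically",
            stacklevel=2,
        )
    return winner.clone_key, winner.productive, dominance_ratio, tie


def partition_cells(
    t_cell_barcodes: Sequence[str],
    cell_clonotypes: Mapping[str, CellChains],
    sample_id: str,
    min_fraction: float = 0.10,
) -> CloneCall:
    """Label every QC-passing T cell malignant / reactive / unassigned.

    Cells carrying the malignant clone key are malignant; cells carrying any
    other clonotype are reactive (polyclonal); cells with no recovered TCR are
    unassigned. The malignant fraction is computed over labelled cells only.
    """
    usable = {b: c for b, c in cell_clonotypes.items() if b in set(t_cell_barcodes)}
    key, is_prod, ratio, tie = call_malignant_clone(usable, sample_id, min_fraction)
    assignment = reconcile_chain_subsets(usable)

    labels = {}
    for barcode in t_cell_barcodes:
        if barcode not in assignment:
            labels[barcode] = "unassigned"
        elif assignment[barcode] == key:
            labels[barcode] = "malignant"
        else:
            labels[barcode] = "reactive"
    series = pd.Series(labels, name="label").loc[list(t_cell_barcodes)]

    n_mal = int((series == "malignant").sum())
    n_rea = int((series == "reactive").sum())
    frac = n_mal / (n_mal + n_rea) if (n_mal + n_rea) else float("nan")
    return CloneCall(
        sample_id=sample_id,
        malignant_clone_key=key,
        malignant_is_productive=is_prod,
        dominance_ratio=ratio,
        labels=series,
        malignant_fraction=frac,
        tie_warning=tie,
    )


def clone_report(cell_clonotypes: Mapping[str, CellChains], malignant_key: str) -> pd.DataFrame:
    """Per-clone summary table (clone_key, chains, productive, cell_count, is_malignant)."""
    assignment = reconcile_chain_subsets(cell_clonotypes)
    clones = summarize_clonotypes(cell_clonotypes, assignment)
    rows = [
        {
            "clone_key": c.clone_key,
            "chains": clone_key(c.chains),
            "productive": c.productive,
            "cell_count": c.cell_count,
            "total_umis": c.total_umis,
            "is_malignant": c.clone_key == malignant_key,
        }
        for c in sorted(clones.values(), key=lambda c: (-c.cell_count, c.clone_key))
    ]
    return pd.DataFrame(rows)
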