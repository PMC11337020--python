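"""Synthetic lesion cohorts with known ground truth.

Generates per-patient 10x-style inputs (count matrix with spliced/unspliced
layers, VDJ contig table, gene-position table) whose statistical structure
matches what the analysis assumes: one dominant malignant clonotype per
patient atop a polyclonal reactive infiltrate, planted malignant-vs-reactive
marker genes recurring in a configurable number of patients, chromosomal
gain/loss blocks confined to malignant cells, and spliced/unspliced counts
following first-order splicing kinetics with per-population dynamics
regimes.

Count model: per-gene base means from category-specific distributions,
per-cell log-normal size factors, negative-binomial sampling with fixed
dispersion. Unspliced counts are drawn conditionally on the realized
spliced counts, u ~ Poisson(reg * gamma * s), so the steady-state relation
u = gamma * s holds in conditional expectation (reg > 1 for induced, < 1
for repressed gene/cell combinations). Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .clonotype import clone_key
from .errors import ConfigurationError
from .io import CHROMOSOMES, ContigRecord, CountMatrix, GenePositionTable, load_gene_list

__all__ = [
    "CNVBlockSpec",
    "CohortConfig",
    "TruthTables",
    "SampleData",
    "Cohort",
    "generate_cohort",
    "emulate_paper_cohort",
    "write_cohort",
    "read_cohort",
]

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
CD3_GENES = ["CD3D", "CD3E", "CD3G"]
DEFAULT_SIGNATURE = [
    "BATF", "IL32", "MIF", "CD9", "ENO1", "KDSR",
    "S100A4", "S100A6", "LGALS1", "LGALS3", "KRT81", "KRT86",
]
MEMORY_PROGRAM = ["IL7R", "CCR7", "CD27", "SELL", "KLF2", "CXCL13", "IL4", "IL13"]
CYTOTOXIC_PROGRAM = ["GZMA", "GZMB", "GNLY", "NKG7", "PRF1", "CTSW", "KLRD1", "CCL5"]

REGIMES = ("steady", "induction", "repression")


@dataclass(frozen=True)
class CNVBlockSpec:
    """A planted copy-number block: ``n_genes`` consecutive genes (genomic
    order) on ``chrom`` starting at within-chromosome offset ``start``,
    multiplied by ``multiplier`` in malignant cells (optionally only in one
    malignant subpopulation)."""

    chrom: str
    start: int
    n_genes: int
    multiplier: float
    subpop: Optional[int] = None


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_patients: int = 7
    n_cells: Sequence[int] = ()
    malignant_fraction: Sequence[float] = ()
    n_genes: int = 1500
    dispersion: float = 0.5

    signature_genes: Sequence[str] = tuple(DEFAULT_SIGNATURE)
    signature_shift: float = 1.0
    recurrence_plan: dict = field(default_factory=dict)  # gene -> tuple of patient idx
    decoy_genes: Sequence[str] = ()
    decoy_plan: dict = field(default_factory=dict)
    program_plan: dict = field(default_factory=dict)  # gene -> (patients, shift)
    n_private_program_genes: int = 25
    private_shift: float = 1.0

    n_subpops: Sequence[int] = ()
    subpop_gene_count: int = 40
    subpop_shift: float = 1.5

    cnv_blocks: dict = field(default_factory=dict)  # patient idx -> list[CNVBlockSpec]

    alpha_dropout: float = 0.10
    beta_dropout: float = 0.10
    reactive_dropout: float = 0.05
    no_tcr_frac: float = 0.05
    nonproductive_patients: Sequence[int] = ()

    dynamics_regime: Sequence[str] = ()
    transitioning_frac: float = 0.7  # fraction of malignant cells mid-flight
    n_dynamic_genes: int = 150
    dynamic_shift: float = 1.0  # ln-scale span of the induced/repressed expression program
    induction_factor: float = 2.5
    repression_factor: float = 0.3

    non_t_frac: float = 0.07
    low_quality_frac: float = 0.04
    cycling_frac: float = 0.10
    cycle_shift: float = 1.0

    def __post_init__(self) -> None:
        if not self.n_cells:
            self.n_cells = tuple([285] * self.n_patients)
        if not self.malignant_fraction:
            self.malignant_fraction = tuple(
                np.linspace(0.47, 0.98, self.n_patients).round(2)
            )
        if not self.dynamics_regime:
            self.dynamics_regime = tuple(["steady"] * self.n_patients)
        if not self.n_subpops:
            self.n_subpops = tuple([1] * self.n_patients)

    def validate(self, chrom_spans: dict[str, int]) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if len(self.n_cells) != self.n_patients or len(self.malignant_fraction) != self.n_patients:
            raise ConfigurationError("per-patient lists must have n_patients entries")
        for f in self.malignant_fraction:
            if not 0 <= f <= 1:
                raise ConfigurationError(f"malignant fraction {f} outside [0, 1]")
        for regime in self.dynamics_regime:
            if regime not in REGIMES:
                raise ConfigurationError(f"unknown dynamics regime {regime!r}")
        for patient, blocks in self.cnv_blocks.items():
            for b in blocks:
                if b.multiplier <= 0:
                    raise ConfigurationError("CNV multipliers must be > 0")
                span = chrom_spans.get(str(b.chrom), 0)
                if b.start < 0 or b.start + b.n_genes > span:
                    raise ConfigurationError(
                        f"patient {patient}: CNV block {b} exceeds chromosome "
                        f"{b.chrom} span of {span} genes"
                    )


@dataclass
class TruthTables:
    """Ground truth aligned to the emitted matrices by construction."""

    cells: pd.DataFrame  # per-cell: patient, is_t_cell, is_malignant, ...
    genes: pd.DataFrame  # per-gene: category, planted_patients, gamma_true, ...
    cnv_blocks: pd.DataFrame  # planted blocks with member gene lists
    clone_keys: dict  # patient sample_id -> malignant clone key


@dataclass
class SampleData:
    matrix: CountMatrix
    contigs: list


@dataclass
class Cohort:
    samples: dict  # sample_id -> SampleData
    positions: GenePositionTable
    truth: TruthTables
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.keys())


def _gene_universe(config: CohortConfig) -> pd.DataFrame:
    """Assemble the gene table: symbols, categories and chromosome layout.

    Special genes (mito, housekeeping, CD3, cycle, signature, decoy, program)
    come first, filler genes pad to ``n_genes``; nuclear genes are dealt
    round-robin across chromosomes 1..22, X so planted CNV blocks (consecutive
    genes in genomic order) mix gene categories like a real chromosome does.
    """
    housekeeping = load_gene_list("housekeeping_genes")[:60]
    s_genes = load_gene_list("cell_cycle_s_genes")[:20]
    g2m_genes = load_gene_list("cell_cycle_g2m_genes")[:20]
    program_genes = sorted(config.program_plan)

    rows: list[tuple[str, str]] = []
    rows += [(g, "mito") for g in MITO_GENES]
    rows += [(g, "housekeeping") for g in housekeeping]
    rows += [(g, "cd3") for g in CD3_GENES]
    rows += [(g, "cycle_s") for g in s_genes]
    rows += [(g, "cycle_g2m") for g in g2m_genes]
    rows += [(g, "signature") for g in config.signature_genes]
    rows += [(g, "decoy") for g in config.decoy_genes]
    rows += [(g, "program") for g in program_genes if g not in {r[0] for r in rows}]

    seen = {r[0] for r in rows}
    if len(seen) != len(rows):
        raise ConfigurationError("duplicate gene symbols across configured categories")
    n_filler = config.n_genes - len(rows)
    if n_filler < config.n_private_program_genes * config.n_patients + 200:
        raise ConfigurationError(
            f"n_genes={config.n_genes} leaves too few filler genes ({n_filler})"
        )
    rows += [(f"F{i:04d}", "filler") for i in range(1, n_filler + 1)]

    table = pd.DataFrame(rows, columns=["symbol", "category"])

    # reserve filler gene roles deterministically, in disjoint stretches
    filler = table.index[table["category"] == "filler"].to_numpy()
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = filler[cursor : cursor + n]
        cursor += n
        return out

    table["role"] = ""
    table.loc[take(60), "role"] = "balance"
    for p in range(config.n_patients):
        table.loc[take(config.n_private_program_genes), "role"] = f"private_p{p}"
    for p in range(config.n_patients):
        for sub in range(1, config.n_subpops[p]):
            table.loc[take(config.subpop_gene_count), "role"] = f"subpop_p{p}_s{sub}"
    table.loc[take(config.n_dynamic_genes), "role"] = "dynamic"

    # chromosome layout: mito genes on MT, everything else round-robin
    table["chrom"] = ""
    table["chrom_index"] = 0
    nuclear = table.index[table["category"] != "mito"].to_numpy()
    n_chrom = len(CHROMOSOMES)
    counters = {c: 0 for c in CHROMOSOMES}
    for i, gi in enumerate(nuclear):
        chrom = CHROMOSOMES[i % n_chrom]
        table.at[gi, "chrom"] = chrom
        table.at[gi, "chrom_index"] = counters[chrom]
        counters[chrom] += 1
    mito_idx = table.index[table["category"] == "mito"]
    table.loc[mito_idx, "chrom"] = "MT"
    table.loc[mito_idx, "chrom_index"] = np.arange(len(mito_idx))
    return table


def _base_means(table: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Category-specific base expression means (UMI per cell scale)."""
    n = len(table)
    mu = np.empty(n)
    cat = table["category"].to_numpy()
    mu[cat == "filler"] = rng.lognormal(np.log(0.5), 1.0, (cat == "filler").sum())
    mu[cat == "housekeeping"] = rng.uniform(3.0, 8.0, (cat == "housekeeping").sum())
    mu[cat == "mito"] = rng.uniform(5.0, 10.0, (cat == "mito").sum())
    mu[cat == "cycle_s"] = rng.uniform(0.5, 2.0, (cat == "cycle_s").sum())
    mu[cat == "cycle_g2m"] = rng.uniform(0.5, 2.0, (cat == "cycle_g2m").sum())
    # planted markers emulate abundant T-cell transcripts (the S100/galectin/
    # MIF class), where a 1.0 ln-shift is well inside rank-sum sensitivity
    mu[cat == "signature"] = rng.uniform(4.0, 10.0, (cat == "signature").sum())
    mu[cat == "decoy"] = rng.uniform(4.0, 10.0, (cat == "decoy").sum())
    mu[cat == "program"] = rng.uniform(1.5, 4.0, (cat == "program").sum())
    cd3_means = {"CD3D": 4.0, "CD3E": 3.0, "CD3G": 2.0}
    for g, m in cd3_means.items():
        mu[(table["symbol"] == g).to_numpy()] = m
    # dynamic and transition-marker fillers get boosted means so the velocity
    # and clustering layers see real signal
    role = table["role"].to_numpy()
    mu[role == "dynamic"] = rng.uniform(2.0, 8.0, (role == "dynamic").sum())
    # very abundant genes carry the complementary "lost in malignant" program
    # (the IL7R/SELL/KLF2 class): even scaled down in malignant cells they
    # remain in the top expression bins, clear of the module-scoring pools
    mu[role == "balance"] = rng.uniform(15.0, 30.0, (role == "balance").sum())
    # tumor-program genes sit above the (low-expressed) cycle markers in the
    # mean-expression ranking, keeping bin-matched control pools for module
    # scoring free of malignant-program contamination
    for r in np.unique(role):
        if r.startswith("private_") or r.startswith("subpop_"):
            mu[role == r] = rng.uniform(2.5, 6.0, (role == r).sum())
    return mu


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and var mu + dispersion * mu^2."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def _random_cdr3(rng: np.random.Generator, length: int = 36) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _barcodes(rng: np.random.Generator, n: int) -> list[str]:
    out: set[str] = set()
    codes: list[str] = []
    while len(codes) < n:
        bc = "".join(rng.choice(list("ACGT"), size=16)) + "-1"
        if bc not in out:
            out.add(bc)
            codes.append(bc)
    return codes


def _positions_from_table(table: pd.DataFrame) -> GenePositionTable:
    rows = []
    for sym, chrom, ci in zip(table["symbol"], table["chrom"], table["chrom_index"]):
        start = int(ci + 1) * 100_000
        rows.append({"gene": sym, "chrom": chrom, "start": start, "end": start + 500, "strand": "+"})
    return GenePositionTable(pd.DataFrame(rows), chromosomes=CHROMOSOMES)


def _exact_flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean vector with an exact count of True, in random positions."""
    k = int(round(fraction * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the cohort described by ``config`` with full truth tables."""
    table = _gene_universe(config)
    chrom_spans = table[table["chrom"] != "MT"].groupby("chrom").size().to_dict()
    config.validate(chrom_spans)

    rng = np.random.default_rng(config.seed)
    base_mu = _base_means(table, rng)
    gamma_true = rng.uniform(0.2, 1.0, len(table))

    symbols = table["symbol"].tolist()
    sym_pos = {s: i for i, s in enumerate(symbols)}
    role = table["role"].to_numpy()
    cat = table["category"].to_numpy()
    mito_rows = np.flatnonzero(cat == "mito")
    cd3_rows = np.flatnonzero(cat == "cd3")
    s_rows = np.flatnonzero(cat == "cycle_s")
    g2m_rows = np.flatnonzero(cat == "cycle_g2m")
    dynamic_rows = np.flatnonzero(role == "dynamic")
    # alternate induced/repressed members within the dynamic program
    dyn_dir = np.where(np.arange(len(dynamic_rows)) % 2 == 0, 1.0, -1.0)

    # per-chromosome genomic order for CNV block -> gene resolution
    chrom_order: dict[str, np.ndarray] = {
        chrom: grp.sort_values("chrom_index").index.to_numpy()
        for chrom, grp in table[table["chrom"] != "MT"].groupby("chrom")
    }

    samples: dict[str, SampleData] = {}
    cell_rows = []
    cnv_rows = []
    clone_keys: dict[str, str] = {}
    planted_by_gene: dict[str, list[int]] = {g: sorted(p) for g, p in config.recurrence_plan.items()}

    for p in range(config.n_patients):
        sample_id = f"P{p + 1}"
        n = config.n_cells[p]
        regime = config.dynamics_regime[p]
        barcodes = _barcodes(rng, n)

        is_t = _exact_flags(rng, n, 1.0 - config.non_t_frac)
        t_idx = np.flatnonzero(is_t)
        is_malignant = np.zeros(n, dtype=bool)
        mal_among_t = _exact_flags(rng, len(t_idx), config.malignant_fraction[p])
        is_malignant[t_idx[mal_among_t]] = True

        subpop = np.zeros(n, dtype=int)
        n_sub = config.n_subpops[p]
        mal_idx = np.flatnonzero(is_malignant)
        if n_sub > 1 and len(mal_idx):
            subpop[mal_idx] = rng.integers(0, n_sub, len(mal_idx))

        cycling = np.array(["none"] * n, dtype=object)
        cyc = rng.random(n) < config.cycling_frac
        phase = rng.random(n) < 0.5
        cycling[cyc & phase] = "S"
        cycling[cyc & ~phase] = "G2M"

        low_quality = rng.random(n) < config.low_quality_frac
        lq_kind = rng.random(n) < 0.5  # True: tiny cell, False: mito blow-up

        # transcriptional dynamics belong to the malignant population: in a
        # non-steady patient the malignant cells are spread along a transition
        # of their tumor program. progress t=0 marks the departure state, t=1
        # the arrival (steady) state; unspliced excess decays as cells arrive,
        # which is exactly the structure a steady-state velocity fit assumes.
        # non-transitioning malignant cells anchor BOTH ends of the path at
        # steady state (half not yet departed, half arrived), which is what
        # lets an extreme-quantile steady-state fit see falling genes too
        progress = np.ones(n)
        transitioning = np.zeros(n, dtype=bool)
        if regime != "steady":
            transitioning = is_malignant & (rng.random(n) < config.transitioning_frac)
            progress[transitioning] = rng.uniform(0.0, 1.0, int(transitioning.sum()))
            anchors = is_malignant & ~transitioning
            progress[anchors] = rng.integers(0, 2, int(anchors.sum())).astype(float)

        # --- expression means -------------------------------------------------
        size = rng.lognormal(0.0, 0.35, n)
        size[low_quality & lq_kind] *= 0.15
        mu = base_mu[:, None] * size[None, :]

        mu[np.ix_(cd3_rows, np.flatnonzero(~is_t))] = 0.0
        base_totals = mu.sum(axis=0)  # content before planted programs

        mal_cols = np.flatnonzero(is_malignant)
        if len(mal_cols):
            for gene, patients in config.recurrence_plan.items():
                if p in patients:
                    mu[sym_pos[gene], mal_cols] *= np.exp(config.signature_shift)
            for gene, patients in config.decoy_plan.items():
                if p in patients:
                    mu[sym_pos[gene], mal_cols] *= np.exp(config.signature_shift)
            for gene, (patients, shift) in config.program_plan.items():
                if p in patients:
                    mu[sym_pos[gene], mal_cols] *= np.exp(shift)
            # the patient-private tumor program and, in dynamic patients, the
            # dynamic gene set follow the transition: expression interpolates
            # between the departure and arrival states along per-cell progress
            private = np.flatnonzero(role == f"private_p{p}")
            if regime == "steady":
                mu[np.ix_(private, mal_cols)] *= np.exp(config.private_shift)
            else:
                state = progress if regime == "induction" else 1.0 - progress
                mu[np.ix_(private, mal_cols)] *= np.exp(
                    config.private_shift * state[mal_cols][None, :]
                )
                # the transiting program moves genes in both directions, which
                # keeps the malignant cells' total content roughly balanced
                mu[np.ix_(dynamic_rows, mal_cols)] *= np.exp(
                    dyn_dir[:, None] * config.dynamic_shift * state[mal_cols][None, :]
                )
            for sub in range(1, n_sub):
                sub_cols = np.flatnonzero(is_malignant & (subpop == sub))
                sub_rows = np.flatnonzero(role == f"subpop_p{p}_s{sub}")
                if len(sub_cols):
                    # half the subclone program up, half down: depth-balanced
                    half = len(sub_rows) // 2
                    mu[np.ix_(sub_rows[:half], sub_cols)] *= np.exp(config.subpop_shift)
                    mu[np.ix_(sub_rows[half:], sub_cols)] *= np.exp(-config.subpop_shift)
            for block in config.cnv_blocks.get(p, []):
                genes = chrom_order[str(block.chrom)][block.start : block.start + block.n_genes]
                cols = (
                    np.flatnonzero(is_malignant & (subpop == block.subpop))
                    if block.subpop is not None
                    else mal_cols
                )
                if len(cols):
                    mu[np.ix_(genes, cols)] *= block.multiplier
                cnv_rows.append(
                    {
                        "patient": sample_id,
                        "chrom": str(block.chrom),
                        "start": block.start,
                        "n_genes": block.n_genes,
                        "multiplier": block.multiplier,
                        "subpop": -1 if block.subpop is None else block.subpop,
                        "genes": ";".join(symbols[g] for g in genes),
                    }
                )

        s_cells = np.flatnonzero(cycling == "S")
        g2m_cells = np.flatnonzero(cycling == "G2M")
        if len(s_cells):
            mu[np.ix_(s_rows, s_cells)] *= np.exp(config.cycle_shift)
        if len(g2m_cells):
            mu[np.ix_(g2m_rows, g2m_cells)] *= np.exp(config.cycle_shift)
        trans_cols = np.flatnonzero(transitioning)

        # complementary program: gained content is compensated by losing an
        # abundant "resting T cell" gene set (and vice versa), keeping every
        # cell's expected total at its baseline. This is both what the tissue
        # shows (memory/naive genes down in malignant cells) and what keeps
        # planted fold changes from being diluted by depth normalization.
        balance_rows = np.flatnonzero(role == "balance")
        deficit = mu.sum(axis=0) - base_totals
        bal_content = mu[balance_rows, :].sum(axis=0)
        factor = np.clip(1.0 - deficit / np.maximum(bal_content, 1e-9), 0.05, 3.0)
        mu[balance_rows, :] *= factor[None, :]

        mito_blow = np.flatnonzero(low_quality & ~lq_kind)
        if len(mito_blow):
            mu[np.ix_(mito_rows, mito_blow)] *= 8.0

        # --- sampling ---------------------------------------------------------
        spliced = _nb_sample(rng, mu, config.dispersion)

        reg = np.ones_like(mu)
        if regime != "steady" and len(trans_cols):
            factor = (
                config.induction_factor if regime == "induction" else config.repression_factor
            )
            # unspliced/spliced ratio excess (rising genes) or deficit (falling
            # genes) decays as cells arrive (t -> 1): reg = K^(1-t) with
            # K = factor^dir, so arrived cells sit on the steady-state line
            private_rows = np.flatnonzero(role == f"private_p{p}")
            rest = (1.0 - progress[trans_cols])[None, :]
            reg[np.ix_(dynamic_rows, trans_cols)] = (factor ** dyn_dir)[:, None] ** rest
            reg[np.ix_(private_rows, trans_cols)] = factor**rest
        unspliced = rng.poisson(gamma_true[:, None] * reg * spliced)

        s_mat = sp.csr_matrix(spliced)
        u_mat = sp.csr_matrix(unspliced)
        matrix = CountMatrix(
            gene_ids=[f"ENSG{i:08d}" for i in range(len(symbols))],
            gene_symbols=symbols,
            cell_barcodes=barcodes,
            counts=s_mat.copy(),
            sample_id=sample_id,
            layers={"spliced": s_mat, "unspliced": u_mat},
        )

        # --- TCR --------------------------------------------------------------
        productive_clone = p not in set(config.nonproductive_patients)
        mal_tra = _random_cdr3(rng)
        mal_trb = _random_cdr3(rng)
        mal_key = clone_key([("TRA", mal_tra), ("TRB", mal_trb)])
        clone_keys[sample_id] = mal_key

        used_cdr3 = {mal_tra, mal_trb}
        contigs: list[ContigRecord] = []
        tcr_status = np.array(["none"] * n, dtype=object)
        truth_clone = np.array([""] * n, dtype=object)

        for ci in t_idx:
            if rng.random() < config.no_tcr_frac:
                continue
            bc = barcodes[ci]
            if is_malignant[ci]:
                r = rng.random()
                if r < config.alpha_dropout:
                    chains = [("TRA", mal_tra)]
                    tcr_status[ci] = "alpha_only"
                elif r < config.alpha_dropout + config.beta_dropout:
                    chains = [("TRB", mal_trb)]
                    tcr_status[ci] = "beta_only"
                else:
                    chains = [("TRA", mal_tra), ("TRB", mal_trb)]
                    tcr_status[ci] = "paired"
                truth_clone[ci] = mal_key
                prod = productive_clone
            else:
                tra = _random_cdr3(rng)
                while tra in used_cdr3:
                    tra = _random_cdr3(rng)
                used_cdr3.add(tra)
                trb = _random_cdr3(rng)
                while trb in used_cdr3:
                    trb = _random_cdr3(rng)
                used_cdr3.add(trb)
                r = rng.random()
                if r < config.reactive_dropout:
                    chains = [("TRA", tra)]
                    tcr_status[ci] = "alpha_only"
                elif r < 2 * config.reactive_dropout:
                    chains = [("TRB", trb)]
                    tcr_status[ci] = "beta_only"
                else:
                    chains = [("TRA", tra), ("TRB", trb)]
                    tcr_status[ci] = "paired"
                truth_clone[ci] = clone_key(chains)
                prod = True
            for chain, cdr3 in chains:
                v_fam = "TRAV" if chain == "TRA" else "TRBV"
                j_fam = "TRAJ" if chain == "TRA" else "TRBJ"
                contigs.append(
                    ContigRecord(
                        barcode=bc,
                        is_cell=True,
                        high_confidence=True,
                        chain=chain,
                        productive=prod,
                        cdr3_nt=cdr3,
                        umis=int(rng.integers(5, 60)),
                        v_gene=f"{v_fam}{int(rng.integers(1, 30))}",
                        j_gene=f"{j_fam}{int(rng.integers(1, 30))}",
                        c_gene="TRAC" if chain == "TRA" else "TRBC2",
                        raw_clonotype_id=None,
                    )
                )

        samples[sample_id] = SampleData(matrix=matrix, contigs=contigs)
        cell_rows.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "patient": sample_id,
                    "is_t_cell": is_t,
                    "is_malignant": is_malignant,
                    "clone_key": truth_clone,
                    "tcr_status": tcr_status,
                    "subpop": subpop,
                    "cycling": cycling,
                    "transitioning": transitioning,
                    "progress": progress,
                    "low_quality": low_quality,
                }
            )
        )

    genes_truth = table[["symbol", "category", "role", "chrom", "chrom_index"]].copy()
    genes_truth["base_mean"] = base_mu
    genes_truth["gamma_true"] = gamma_true
    genes_truth["is_dynamic"] = np.isin(np.arange(len(table)), dynamic_rows)
    direction = np.zeros(len(table))
    direction[dynamic_rows] = dyn_dir
    genes_truth["dyn_direction"] = direction
    genes_truth["is_signature"] = genes_truth["symbol"].isin(config.signature_genes)
    genes_truth["planted_patients"] = [
        ";".join(str(q) for q in planted_by_gene.get(s, [])) for s in genes_truth["symbol"]
    ]
    genes_truth["n_planted_patients"] = [
        len(planted_by_gene.get(s, [])) for s in genes_truth["symbol"]
    ]

    truth = TruthTables(
        cells=pd.concat(cell_rows, ignore_index=True),
        genes=genes_truth.reset_index(drop=True),
        cnv_blocks=pd.DataFrame(
            cnv_rows,
            columns=["patient", "chrom", "start", "n_genes", "multiplier", "subpop", "genes"],
        ),
        clone_keys=clone_keys,
    )
    return Cohort(samples=samples, positions=_positions_from_table(table), truth=truth, config=config)


def emulate_paper_cohort(seed: int, n_cells_per_patient: int = 285) -> Cohort:
    """Desk-scale preset mirroring the study cohort's shape.

    Seven patients, ~1,850 T cells in total, malignant fractions spread over
    [0.47, 0.98], twelve signature genes each planted in at least four
    patients (with carriers drawn from the patients whose reactive
    infiltrate is large enough to power a rank-sum test), twenty decoys in
    at most three patients, one patient whose dominant clone is
    non-productive, and per-patient dynamics regimes.
    """
    fractions = (0.47, 0.55, 0.65, 0.75, 0.85, 0.92, 0.98)
    signature = list(DEFAULT_SIGNATURE)
    # required carriers are the four patients whose reactive infiltrate is
    # large (fractions <= 0.75, >= ~60 reactive cells, where the Bonferroni-
    # gated rank-sum test has ample power); high-fraction patients appear
    # only as bonus carriers since ~5-35 reactive cells cannot reliably
    # clear the adjusted-p gate over ~1500 tested genes
    recurrence_plan = {}
    for i, gene in enumerate(signature):
        carriers = [0, 1, 2, 3]
        if i % 3 == 0:
            carriers.append(4)
        if i % 4 == 0:
            carriers.append(5)
        recurrence_plan[gene] = tuple(carriers)
    decoys = [f"DEC{i:02d}" for i in range(1, 21)]
    decoy_plan = {g: tuple(sorted({i % 7, (i + 2) % 7, (i + 4) % 7})) for i, g in enumerate(decoys)}

    program_plan = {
        "IL7R": ((0, 1), 1.2), "CCR7": ((0, 4), 1.2), "CD27": ((1, 4), 1.2),
        "SELL": ((0, 1), 1.2), "KLF2": ((4,), 1.2), "CXCL13": ((0, 1, 4), 1.2),
        "IL4": ((5,), 1.2), "IL13": ((5,), 1.2),
        "GZMA": ((2, 3, 6), 1.2), "GNLY": ((2, 3), 1.2), "NKG7": ((2, 3, 6), 1.2),
        "GZMB": ((6,), 1.2), "PRF1": ((6,), 1.2), "CTSW": ((2,), 1.2),
        "KLRD1": ((3, 6), 1.2), "CCL5": ((2, 3), 1.2),
    }

    cnv_blocks = {
        0: [CNVBlockSpec("1", 5, 30, 1.5)],
        1: [CNVBlockSpec("7", 10, 30, 1.5), CNVBlockSpec("17", 5, 30, 0.5),
            CNVBlockSpec("3", 20, 30, 1.5, subpop=1)],
        2: [CNVBlockSpec("2", 15, 30, 0.5)],
        3: [CNVBlockSpec("5", 8, 30, 1.5)],
        4: [CNVBlockSpec("10", 12, 30, 0.5), CNVBlockSpec("6", 18, 30, 0.5)],
        5: [CNVBlockSpec("12", 6, 30, 1.5)],
        6: [CNVBlockSpec("9", 9, 30, 1.5), CNVBlockSpec("17", 25, 30, 0.5)],
    }

    return generate_cohort(
        CohortConfig(
            seed=seed,
            n_patients=7,
            n_cells=tuple([n_cells_per_patient] * 7),
            malignant_fraction=fractions,
            signature_genes=tuple(signature),
            recurrence_plan=recurrence_plan,
            decoy_genes=tuple(decoys),
            decoy_plan=decoy_plan,
            program_plan=program_plan,
            n_subpops=(2, 2, 1, 3, 1, 2, 2),
            cnv_blocks=cnv_blocks,
            nonproductive_patients=(6,),
            # dynamic regimes sit on the high-malignant-fraction patients: the
            # per-sample median transition distance only responds when the
            # transiting (malignant) population is the sample majority
            dynamics_regime=("steady", "steady", "steady", "steady",
                             "repression", "induction", "induction"),
        )
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the exact on-disk formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample_id, data in cohort.samples.items():
        d = outdir / sample_id
        d.mkdir(exist_ok=True)
        m = data.matrix
        scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(m.counts.astype(np.int64)))
        scipy.io.mmwrite(d / "unspliced.mtx", sp.coo_matrix(m.layers["unspliced"].astype(np.int64)))
        with open(d / "features.tsv", "w") as fh:
            for gid, sym in zip(m.gene_ids, m.gene_symbols):
                fh.write(f"{gid}\t{sym}\tGene Expression\n")
        with open(d / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(m.cell_barcodes) + "\n")
        contig_rows = [
            {
                "barcode": c.barcode, "is_cell": c.is_cell, "high_confidence": c.high_confidence,
                "chain": c.chain, "v_gene": c.v_gene, "j_gene": c.j_gene, "c_gene": c.c_gene,
                "full_length": c.full_length,
                "productive": "None" if c.productive is None else str(c.productive),
                "cdr3_nt": c.cdr3_nt or "None", "umis": c.umis,
                "raw_clonotype_id": c.raw_clonotype_id or "",
            }
            for c in data.contigs
        ]
        pd.DataFrame(contig_rows).to_csv(d / "filtered_contig_annotations.csv", index=False)
    cohort.positions.write_tsv(outdir / "gene_positions.tsv")
    cohort.truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
    cohort.truth.genes.to_csv(outdir / "truth_genes.csv", index=False)
    cohort.truth.cnv_blocks.to_csv(outdir / "truth_cnv_blocks.csv", index=False)


def read_cohort(outdir: str | Path) -> tuple[dict, GenePositionTable]:
    """Load a written cohort back (samples + positions); truth files optional."""
    from .io import read_contig_annotations, read_count_matrix

    outdir = Path(outdir)
    samples: dict[str, SampleData] = {}
    for d in sorted(p for p in outdir.iterdir() if p.is_dir()):
        matrix = read_count_matrix(
            d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", sample_id=d.name,
            layer_paths={"unspliced": d / "unspliced.mtx"},
        )
        matrix.layers["spliced"] = matrix.counts.copy()
        contigs = read_contig_annotations(d / "filtered_contig_annotations.csv")
        samples[d.name] = SampleData(matrix=matrix, contigs=contigs)
    positions = GenePositionTable.read_tsv(outdir / "gene_positions.tsv")
    return samples, positions
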