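# Methods

This note documents the models, the tunable parameters and their defaults,
the design of the synthetic cohort generator, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

A cutaneous lymphoma lesion contains one expanded malignant T-cell clone and
a polyclonal reactive infiltrate. The central assumption, which all
downstream statistics inherit, is that **the most frequent TCR clonotype in
a lesion is the malignant clone**; the reactive cells then double as an
intra-sample healthy reference for differential expression and copy-number
inference. This assumption is reasonable for lesions known to contain tumor
at substantial purity and is guarded by a dominance policy (below); it fails
for genuinely polyclonal samples, which the pipeline refuses rather than
mislabels.

## Quality control

Cells pass when all four gates hold simultaneously, each a strict
inequality: mitochondrial UMI fraction < 0.12, total UMIs > 500, detected
genes > 200, expressed housekeeping genes > 40. Mitochondrial genes default
to the `MT-` symbol prefix (case-insensitive); an explicit list may be
given. The packaged housekeeping set is a curated list of ~95 ribosomal and
canonical housekeeping genes and is overridable per run — the gate counts
*distinct* expressed symbols, so duplicated feature rows do not inflate it.
T cells are cells with ≥ 1 UMI summed over {CD3D, CD3E, CD3G}; the threshold
and the gene set are configurable and recorded in the run report. A
per-cell-rule alternative would be cluster-level marker annotation; the
direct rule is used because it is auditable per cell.

## Clonotyping

Clone identity is the exact set of (chain, CDR3 nucleotide) pairs — no
amino-acid collapsing and no V/J requirement, the strictest reading of
"clonotype". Only cell-associated, high-confidence TRA/TRB contigs with a
CDR3 sequence are used; at most the two best-supported contigs per chain
(by UMIs, ties broken lexicographically) are kept per cell. Cells observed
with only one chain inherit the clone of the unique fully paired clone whose
pair set contains theirs; cells compatible with two or more paired clones
stay unmerged. The malignant call considers productive clones first and
requires the winner to hold ≥ `min_fraction` (default 0.10) of TCR-bearing
cells; a non-productive clone can only be called when no productive clone
reaches that bar — the observed tumor biology includes clones whose
rearrangement cannot encode a receptor but still marks the clone. Ties break
on total UMI support, then lexicographic clone key, and emit a warning.
Cells whose clonotype matches no other cell are labelled *reactive*
(polyclonal); the alternative (unassigned) would shrink the reference
compartment without changing the malignant call. `dominance_ratio` uses a
second-place count of 1 when only one clone exists, keeping it finite.

## Transcriptome core

* Log-normalization: `ln(1 + c/total · 10⁴)`; zero-total cells map to zero
  columns.
* Module scores: mean expression of the gene set minus the mean of control
  genes drawn from the same average-expression rank bins (25 bins, up to 100
  controls per set gene, seeded RNG). S and G2M sets are the standard
  Tirosh-style marker lists shipped as resources.
* Covariate removal: per-gene OLS of expression on S score, G2M score and
  mitochondrial fraction (with intercept), residuals plus intercept
  returned; collinear covariates are dropped with a warning. Note that any
  covariate correlated with malignancy — e.g. module scores whose control
  bins contain malignancy-responsive genes — removes true signal; this is a
  property of the procedure itself, visible in the synthetic cohort when
  tumor-program genes are placed in the cycle markers' expression bins.
* HVGs: genes ranked by log dispersion (var/mean of back-transformed
  expression), z-scored within 20 equal-size mean bins; numerically constant
  genes (relative variance < 1e-12) never qualify. Default n = 2000; when
  fewer variable genes exist, all are returned with a warning.
* PCA: per-gene z-scaling capped at ±10, full SVD, deterministic sign
  convention (largest-magnitude loading positive). The number of PCs is the
  elbow — the last PC before the largest second difference of the variance
  curve — clamped to [15, 25].
* Clustering: exact k-NN (k = 20) in PC space, shared-neighbor Jaccard
  weights pruned below 1/15, Louvain modularity (igraph multilevel) at
  resolution 0.5 with a seeded RNG; labels re-indexed by cluster size.
* UMAP: visualization only; seeded and therefore reproducible. No statistic
  depends on it.

Samples are processed individually, then merged and re-log-normalized; the
merged object is re-regressed and re-clustered. Per-patient intra-clone
cluster counts are computed by re-running HVG/PCA/Louvain on each patient's
malignant cells alone.

## Differential expression and recurrence signature

Two-sided Wilcoxon rank-sum per gene on the post-regression log-normalized
matrix. For groups of ≤ 16 cells each the exact null distribution is used
when the pooled values are tie-free (the normal approximation deviates by up
to ~0.04 at n ≈ 4); otherwise the tie-corrected normal approximation with
continuity correction. Genes enter the test universe when expressed in
≥ 10 % of either group; Bonferroni divides by the number tested. The fold
change is `ln((mean(expm1 a)+1)/(mean(expm1 b)+1))` (back-transformed-mean
convention). Significance = |lnFC| > 0.25 ∧ adjusted P < 0.05. The
recurrence signature counts, per gene, patients significant in the stated
direction (default up) and admits members at ≥ 4 patients; per-patient DE
always uses that patient's own reactive cells. Rank-sum power should be kept
in mind when interpreting per-patient results: at ~1500 tested genes a
patient with only a handful of reactive cells cannot produce a
Bonferroni-significant gene no matter how clean the separation (the maximal
|z| at n₁ = 5 is ≈ 3.8).

## Copy-number scoring

Log-normalized expression of genes ordered by (chromosome 1–22, X; start
coordinate) is centered on the reactive-reference mean per gene, clipped at
±3 reference SD (SD floored at 0.1 so a zero-variance reference gene cannot
erase a real shift), smoothed along each chromosome with a centered moving
average of 101 genes that shrinks at chromosome edges and never crosses a
boundary, and finally re-centered per cell by its own median. Scores stay
continuous — no HMM state calls. On cohorts with few genes per chromosome
the window shrinks to the chromosome length (with a warning), which smooths
block positions within a chromosome; candidate regions are ranked by
`detect_blocks` (absolute mean over sliding within-chromosome windows) and
intra-patient CNV subclones by k-means on the per-cell score matrix.

## RNA velocity and transition distances

Under first-order splicing kinetics at steady state u = γ·s. The pipeline:

1. depth-normalizes spliced and unspliced layers to the **median cell
   depth**, keeping values on a count-like scale (the steady-state relation
   is linear in expression; fitting in log space leaves a systematic
   residual, and large scale factors turn single unspliced counts into
   rectified noise in the later log-space projection);
2. pools both layers over k = 30 PC-space neighbors **before** the fit —
   raw counts blur the expression states the extreme-quantile fit must
   anchor on;
3. fits γ per gene by a zero-intercept regression of unspliced on spliced
   restricted to the bottom/top 5 % of spliced expression, flagging genes
   expressed in < 20 cells as unused;
4. takes v = u − γ·s on the pooled values;
5. extrapolates `max(s + v·dt, 0)`, log1p-transforms the current and future
   states, and pushes both through the retained per-sample PCA transform;
6. reports td = √(ΔPC1² + ΔPC2²) per cell, normalized within each sample as
   (td − min)/max — the printed convention, implemented verbatim; a strict
   min–max variant is available (`transition_distance_minmax`). Median and
   IQR (q75 − q25, linear-interpolation quantiles) are computed per sample
   over normalized values, with raw-scale summaries reported alongside
   because the per-sample normalization removes cross-sample magnitude
   information (the normalization scope is genuinely ambiguous; per-sample
   is the default, and raw medians carry the cross-sample comparison).

The spec-level operation `project_future` (future = current + v·dt through
the loadings, no log wrap) is also provided for direct use. Vector fields
for display use a correlation-based projection of velocities onto embedding
neighbor directions and a Gaussian-kernel arrow grid; grid points without
nearby cells emit no arrow.

## Synthetic cohort generator

The generator emits what the pipeline consumes — MTX triplets,
`filtered_contig_annotations.csv`, gene positions, spliced/unspliced layers —
plus truth tables, deterministically per seed.

**Count model.** Per-gene base means are category-specific: filler genes
log-normal(ln 0.5, 1), housekeepers U(3, 8), mitochondrial U(5, 10), cycle
markers U(0.5, 2), planted signature/decoy markers U(4, 10) (the real-world
analogues — S100 proteins, galectins, MIF, ENO1 — are abundant transcripts;
abundance is also what gives a 1.0 ln-shift rank-sum power at realistic
reactive-group sizes), tumor-program genes U(2.5, 6) (above the cycle
markers' bins so module-score control pools stay clean), and a 60-gene
"lost in malignant" program at U(15, 30). Cells draw log-normal(0, 0.35)
size factors; counts are negative binomial with dispersion 0.5 (variance
µ + 0.5µ²).

**Planted structure.** Malignant cells add ln-scale shifts on their
patient's signature/decoy/program genes, a 25-gene private program, and
40-gene subclone programs (half up, half down at ±1.5 — strong enough that
the subclone eigen-direction clears the Marchenko–Pastur noise edge of a
few-hundred-cell PCA); CNV blocks multiply in-block gene means. Each cell's
gained content is compensated by scaling the abundant "lost in malignant"
program so every cell's expected total stays at baseline. This mirrors the
biology (memory/naive genes down in malignant cells) and, crucially, keeps
depth normalization from diluting planted fold changes and from inducing a
mitochondrial-fraction/malignancy correlation that the covariate regression
would convert into signal loss.

**TCR.** One malignant clone per patient (random CDR3 pairs), configurable
α-only/β-only dropout (default 10 % + 10 %), 5 % of T cells with no
recovered TCR, reactive cells with unique clonotypes (5 % single-chain), and
configurable non-productive-clone patients.

**Dynamics.** In a dynamic patient the malignant cells lie along a
transition of their tumor program: per-cell progress t ~ U(0, 1) for a
`transitioning_frac` (default 0.7) of them, the rest anchored at t = 0 or
t = 1 **at steady state** — without anchors at both ends, genes falling
during the transition are unidentifiable to a steady-state fit because
their top-expression cells are all off the steady line. Spliced means
interpolate exp(dir·shift·state); the unspliced-to-spliced ratio carries an
excess (rising genes) or deficit (falling genes) of `factor^(1−t)` that
decays as cells arrive. Unspliced counts are drawn conditionally on the
realized spliced counts, u ~ Poisson(reg·γ·s), so the zero-intercept
estimator is consistent (an independent draw of u would attenuate it). The
global dynamic program moves half its genes up and half down. Dynamic
regimes are placed on high-malignant-fraction patients in the preset: a
whole-sample median transition distance responds only when the transiting
population is the sample majority.

**The preset** (`emulate_paper_cohort`): 7 patients × 285 cells (~1,850
T cells), malignant fractions (0.47, 0.55, 0.65, 0.75, 0.85, 0.92, 0.98),
twelve signature genes whose required carriers are the four patients with
fractions ≤ 0.75 (≥ ~60 reactive cells — where the Bonferroni-gated test is
powered; higher-fraction patients appear only as bonus carriers), twenty
decoys in ≤ 3 patients each, per-patient CNV gains/losses (one subclone-
restricted), 1–3 subclones per patient, one non-productive-clone patient,
and regimes (steady ×4, repression, induction ×2).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: ambient RNA, doublets, batch effects, the full
skin cell-type composition (keratinocytes, fibroblasts, myeloid cells),
UMI saturation, gene-length or GC biases, correlated gene modules beyond
the planted programs, allele-specific CNV, and TCR sequencing artifacts
(chimeras, cross-cell contamination). Tests demonstrate that the
implementation recovers structure it is pointed at under its stated model,
not that the model captures everything in a lesion.

## Determinism and reproducibility

Every stochastic step (module-score controls, PCA solver, Louvain, UMAP,
k-means, generator) takes an explicit seed surfaced in `RunConfig`; the run
report (`report.json`) is byte-identical across repeated runs with the same
seeds and records every parameter with its provenance (stated default vs
artifact decision). Timings are written to a separate file so they cannot
perturb report comparison.

## Known limitations

* The whole-chromosome smoothing at desk scale (~65 genes per chromosome)
  localizes CNV blocks only to chromosome resolution.
* Steady-state velocity cannot see a population that is uniformly off
  steady state; the statistic is meaningful only when part of the
  population anchors the fit.
* Per-patient DE against very small reactive infiltrates (< ~40 cells) is
  structurally underpowered at Bonferroni thresholds; recurrence membership
  should be interpreted with the per-patient group sizes in hand (they are
  in the report).
* The dominance policy trades sensitivity in low-purity lesions for safety
  in polyclonal samples; `clone_min_fraction` is the knob.
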