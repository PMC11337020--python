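# mfclone

Combined single-cell RNA + TCR analysis of cutaneous T-cell lymphoma
(mycosis fungoides) lesions. In such lesions the malignant population is a
single expanded T-cell clone living among a polyclonal reactive infiltrate;
because both compartments are T cells, ordinary marker-based annotation
cannot separate them — but the TCR can. `mfclone` implements the full
analysis as a tested, reusable pipeline:

1. **Per-cell quality control** — mitochondrial fraction < 12 %, > 500 UMIs,
   > 200 genes, > 40 expressed housekeeping genes (all strict); T cells are
   identified by CD3D/CD3E/CD3G expression.
2. **Clonotyping** — clonotypes are keyed by the set of (chain, CDR3
   nucleotide) pairs; the most frequent clonotype per lesion is called the
   malignant T-cell clone (MTC), with α-only/β-only cells merged back into
   their paired clone and a guard against calling a clone in truly
   polyclonal samples. A dominant clone with a non-productive rearrangement
   is called with `malignant_is_productive = False`.
3. **Transcriptome core** — log-normalization, S/G2M module scoring with
   expression-bin-matched controls, per-gene OLS removal of cycle and
   mitochondrial covariates, 2000 dispersion-ranked HVGs, PCA with an
   elbow-chosen dimensionality clamped to 15–25 PCs, shared-nearest-neighbor
   Louvain clustering at resolution 0.5, and UMAP for display.
4. **Differential expression** — malignant vs reactive two-sided Wilcoxon
   rank-sum tests (exact for small tie-free groups, tie-corrected normal
   approximation otherwise) gated at |lnFC| > 0.25 and Bonferroni-adjusted
   P < 0.05, pooled and per patient, plus the **recurrence signature**:
   genes significantly up in the malignant cells of ≥ 4 patients.
5. **Copy-number scoring** — inferCNV-style: genomically ordered genes,
   reference-centering on the reactive T cells, per-gene clipping at ±3
   reference SD, chromosome-bounded moving-average smoothing, per-cell
   median re-centering; per-clone mean profiles and CNV-based subclone
   splits.
6. **RNA velocity** — steady-state model `v = u − γ·s` on k-NN-pooled,
   depth-normalized spliced/unspliced expression, γ per gene from a
   zero-intercept fit on the extreme spliced quantiles; predicted states are
   projected through the retained PCA to give per-cell transition distances
   `td = √(ΔPC1² + ΔPC2²)`, summarized per sample by median and IQR.

Patient data of this kind is controlled-access, so the package ships a
**synthetic cohort generator** (`mfclone.synthetic`) that emits 10x-style
triplets, VDJ contig tables, spliced/unspliced layers and complete truth
tables: negative-binomial counts, one dominant (optionally non-productive)
clone per patient, planted recurrent marker genes, chromosomal gain/loss
blocks confined to malignant cells, intra-clone subpopulations, and
first-order splicing kinetics with per-patient dynamics regimes.

## Worked example

```bash
mfclone simulate --outdir cohort --seed 1
mfclone run-all --cohort cohort --outdir results_run --seed 1
```

or, equivalently, in Python:

```python
from mfclone.synthetic import emulate_paper_cohort
from mfclone.pipeline import RunConfig, run

cohort = emulate_paper_cohort(seed=1)          # 7 patients, ~1,850 T cells
result = run(cohort, RunConfig(seed=1), outdir="results_run")

info = result.report["samples"]["P1"]
print(info["n_t_cells"], info["n_malignant"], info["malignant_fraction"])
# 252 111 0.468354
print(sorted(result.signature.index[result.signature.member]))
# ['BATF', 'CD9', 'ENO1', 'IL32', 'KDSR', 'KRT81', 'KRT86',
#  'LGALS1', 'LGALS3', 'MIF', 'S100A4', 'S100A6']
```

For patient P1 the pipeline keeps 252 QC-passing T cells of which 111 carry
the dominant clonotype — a malignant fraction of 46.8 %, recovering the
47.2 % planted by the generator. The recurrence signature contains exactly
the twelve genes planted as upregulated in four or more patients; the twenty
decoy genes planted in at most three patients are all rejected. The run
directory contains the QC, clone, DE, signature, CNV-profile, embedding and
transition-distance tables plus `report.json` with per-sample counts,
malignant fractions, cluster counts, and median/IQR transition distances,
each parameter tagged as a stated default or an artifact decision.

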