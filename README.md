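# metaniche

Tumour meta-program discovery, signature scoring, cell-type enrichment
and spatial colocalization for single-cell and spatial transcriptomics
of urothelial carcinoma (UC) — the bladder/upper-tract cancer setting in
which muscle-invasive (MI) tumours split into luminal and basal
phenotypes and a subset of cancer cells aberrantly expresses MHC class
II. The package is aimed at computational biologists who want these
analyses as reusable, deterministic, tested building blocks rather than
one-off notebook code, and it ships a synthetic-data generator with
planted ground truth so every stage can be validated end to end without
access to restricted patient data.

## What it computes

**Consensus NMF meta-programs.** Per sample, the malignant-cell count
matrix X (N cells × G genes; CP10k, top variable genes, unit gene
variance) is factorised X ≈ W·H at each rank K = 4..12 from many random
initialisations (default 200 replicates). Replicate spectra are pooled,
outliers removed by a local-density filter, the rest clustered into K
groups whose medians are the consensus programs; usages are re-fitted
by non-negative least squares. Programs recurring across K within a
sample (≥ 35/50 top-gene overlap) and across samples (≥ 10/50) are
*robust*; greedy Jaccard clustering of robust programs yields
*meta-programs* (MPs), each summarised by the 30 genes shared by the
most member programs, with single-sample MPs discarded. MP signatures
are annotated by hypergeometric enrichment with BH correction.

**Scoring and the MHC-II gate.** Control-gene module scores (signature
mean minus expression-bin-matched control mean), rank-AUC recovery
scores in [0, 1], pseudobulk aggregation, score-based luminal/basal
calls, and the four-gene gate: a cell is MHC-II⁺ iff HLA-DRA, HLA-DRB1,
HLA-DPA1 and HLA-DPB1 all have count > 0.

**R_o/e enrichment.** For a cluster × phenotype table,
R_o/e = observed / (rowsum·colsum/total); > 1 enrichment, < 1 depletion.

**Spatial colocalization.** Cell-type abundances over spots are
normalised to distributions; colocalization is the symmetric KL
divergence ½[KL(p‖q)+KL(q‖p)] (nats), with a null built by resampling
80% of spots 1000 times and an empirical p = fraction of null values
exceeding the observed (see `docs/methods.md` for what this null does
and does not measure). NMF on the spot × cell-type matrix summarises
spatial co-occurrence compartments.

## Worked example

```python
import metaniche as mn

planted = [mn.PlantedProgram(tuple(range(40 + j * 50, 90 + j * 50)), 0.3, 2.0)
           for j in range(2)]
cfg = mn.CohortConfig(
    n_samples=3, cells_per_sample=120, n_genes=500,
    planted_programs=planted,
    group_labels={"S01": "MI-basal", "S02": "MI-luminal", "S03": "NMI"},
    mhc2_positive_fraction_by_group={"MI-basal": 0.2},
    seed=0,
)
matrix, truth = mn.generate_cohort(cfg)
matrix, qc = mn.qc_filter(matrix)          # 200-8000 genes, <=10% mito
matrix = mn.strip_mito_ribo(matrix)

progs = []
for sid in matrix.cell_meta["sample"].unique():
    sub = matrix.subset_cells((matrix.cell_meta["sample"] == sid).to_numpy())
    pcfg = mn.ProgramSetConfig(k_min=4, k_max=8, n_replicates=5, seed=1)
    ps, _ = mn.programs_for_sample(sub, pcfg)
    progs.extend(ps)
robust = mn.select_robust(progs)
mps = mn.cluster_metaprograms(robust)
call = mn.mhc2_gate(matrix)
roe = mn.roe_from_cells(matrix.cell_meta)
```

Output of the full script (in seconds on one CPU):

```
QC retained 358 of 360 cells
90 programs across 3 samples (K = 4..8)
81 robust programs -> 5 meta-programs
planted program 1: best signature Jaccard = 0.60
planted program 2: best signature Jaccard = 0.60
MHC-II+ fraction S01 (MI-basal): 0.267
MHC-II+ fraction S02 (MI-luminal): 0.059
MHC-II+ fraction S03 (NMI): 0.050
R_o/e (celltype x group):
group     MI-basal  MI-luminal   NMI
celltype
CT1           0.97        1.03  1.00
CT2           1.00        0.96  1.04
CT3           1.03        1.01  0.96
```

Reading it: 90 per-sample programs (Σ K for K = 4..8, times 3 samples)
collapse into 5 meta-programs; both planted 50-gene programs are
recovered — Jaccard 0.60 is the maximum a 30-gene signature can reach
against a 50-gene set (30/50), i.e. every signature gene is a planted
gene. The gate recovers the 20% planted MHC-II⁺ fraction in the
MI-basal sample (26.7% observed = planted plus chance positives; the
~5% in the other samples is the chance rate). Cell types were assigned
uniformly, so all R_o/e ratios sit near 1 — no spurious enrichment.

A YAML-driven end-to-end run (QC → programs → MPs → gate → R_o/e →
colocalization) is available as `metaniche run --config cfg.yaml --seed 1`,
with per-stage subcommands (`synth`, `qc`, `programs`, `mp`, `score`,
`gate`, `roe`, `coloc`).

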