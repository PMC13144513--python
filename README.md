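# urinprot

Statistical pipeline for urinary-proteomics studies of genotype-driven kinase
dysfunction (LRRK2-type designs): genotype–proteome association mapping, a
ridge-regression co-regulation network, a staged SVM mutation-status
classifier, and perturbation-arm differential analysis with cross-species
signature transfer — together with a synthetic multi-cohort generator that
plants known effects so every stage can be validated by recovery and null
calibration.

It is written for computational proteomics researchers who analyse sample ×
protein log2-intensity matrices with clinical metadata and variant dosage
tables, and who need a tested, reproducible implementation of this family of
analyses rather than one-off notebook code.

## What it computes

* **QC** (`urinprot.qc_filtering`) — log2 transform; pooled-replicate CVs
  (sd/mean per plate and protein, linear scale); blood-contamination and
  technical-outlier sample exclusion (robust z with the 1.4826·MAD constant,
  |z| > 3.5 counts, Tukey Q3 + 1.5·IQR fence per experimental group);
  valid-value filtering (≥70% quantified in some group); shifted-Gaussian
  imputation from N(μ − 3σ, (0.3σ)²) per sample; location/scale batch
  adjustment.
* **Association** (`urinprot.genotype_association`) — per protein,
  y = β₀ + β₁·age + β₂·sex + β₃·dosage₁ + … on standardized covariates, with
  per-covariate Benjamini–Hochberg families across proteins; locus-level
  dosage aggregation (0/1/2 summed per locus); beta-profile correlations
  between variants; max-|β| normalization; significant-set Venn algebra;
  severity-score correlations.
* **Network** (`urinprot.protein_network`) — pairwise univariate ridge
  (coefficient n·r/(n+λ), λ = 1) over all ordered pairs; edges at q < 5% and
  |coefficient| ≥ 0.15; Louvain clustering; pivotal ranking by mean R²;
  incremental top-k ridge curve with a kneedle elbow.
* **Classifier** (`urinprot.signature_classifier`) — per-cohort stratified
  70/30 split; F-test ∩ mutual-information feature reduction; linear-SVM
  |coefficient| ranking; incremental addition under repeated stratified 5×3
  CV with a train/validation-intersection stopping rule; per-cohort ROC/AUC,
  average precision, confusion matrices; restricted-panel and cross-cohort
  modes.
* **Perturbation arm** (`urinprot.perturbation_differential`) — Student
  t-test contrasts with BH within contrast; cross-contrast fold-change
  correlations; all-contrast consensus signatures; ortholog transfer and
  normalized direction comparison between species.
* **Synthetic cohorts** (`urinprot.synthetic_cohort`) — multi-cohort human
  data with planted dosage effects, age/sex confounding, plate batches,
  pooled replicates at a 25% CV target, logistic left-censoring, blood
  contamination and technical outliers; a four-contrast rat arm with a
  controllable gain-/loss-of-function anticorrelation.

Full model descriptions, parameter defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from urinprot import SimConfig, simulate_human_cohorts
from urinprot.qc_filtering import run_qc_pipeline, ImputeParams
from urinprot.genotype_association import fit_protein_regressions, significant_set

cfg = SimConfig(n_proteins=500, n_samples_per_cohort={"PPMI": 300},
                n_signature_proteins=20,
                variant_table=[("G2019S", "LRRK2", 0.15)], seed=5)
matrix, meta, genotypes, truth = simulate_human_cohorts(cfg)
clean, clean_meta, report = run_qc_pipeline(matrix, meta,
                                            impute_params=ImputeParams(seed=5))
genotypes.dosages = genotypes.dosages.reindex(clean.sample_ids)
assoc = fit_protein_regressions(clean, clean_meta, genotypes)
sig = significant_set(assoc, "G2019S")

print(f"median pooled CV: {report.median_pooled_cv:.3f}")
print("clean matrix:", clean.data.shape)
print("significant proteins (q<0.05):", len(sig))
print("true positives:", len(sig & truth.signature_protein_ids),
      "of", len(truth.signature_protein_ids), "planted")
```

prints

```
median pooled CV: 0.235
clean matrix: (293, 493)
significant proteins (q<0.05): 20
true positives: 19 of 20 planted
```

i.e. the pooled technical replicates reproduce the ~25% CV design target,
QC removes flagged samples and unquantifiable proteins (300 + pooled wells →
293 biological samples, 500 → 493 proteins), and the association stage finds
20 dosage-associated proteins at q < 0.05, 19 of them planted — one false
positive and one planted protein lost to the valid-value filter.

The same stages are available from the shell:

```sh
urinprot simulate --config config.yaml --seed 5 --out sim/
urinprot qc --matrix sim/matrix.tsv --meta sim/meta.tsv --seed 5 --out qc/
urinprot associate --matrix qc/matrix_clean.tsv --meta qc/meta_clean.tsv \
    --genotypes sim/genotypes.tsv --locus-map sim/variant_locus_map.tsv \
    --out assoc.tsv
urinprot network --matrix qc/matrix_clean.tsv --out net/
urinprot classify --matrix qc/matrix_clean.tsv --meta qc/meta_clean.tsv --out clf/
urinprot contrast --matrix rat_imputed.tsv --groups rat_groups.tsv \
    --case-group KO --control-group WT --out ko.tsv
```

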