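# Methods

`urinprot` implements the downstream statistical pipeline of a urinary
proteomics study of LRRK2 dysfunction: genotype–proteome association mapping
with covariate adjustment, a pairwise ridge-regression co-regulation network,
a staged linear-SVM mutation-status classifier, and a perturbation-arm
differential analysis with cross-species signature transfer.  Because the real
cohort data (PPMI and two LRRK2 consortium cohorts, plus rat perturbation
experiments) cannot be redistributed, the package ships a synthetic-cohort
generator that plants known effects inside data with the same statistical
structure, so every stage can be validated by parameter recovery and null
calibration.

## The synthetic study

`synthetic_cohort.SimConfig` holds the study design.  A sample's log2
intensity for protein *p* is

```
y = b_p + beta_age * age + beta_sex * sex + sum_v beta_{p,v} * dosage_v
    + plate_{plate,p} + e
```

with protein baselines `b_p ~ N(20, 2)` (log2 units), flat age and sex effects
(0.01 log2/year, 0.25 log2 M−F), per-(plate, protein) batch shifts
(sd 0.2), and residual noise of sd 1 — the log2 equivalent of the ~68%
biological CV such cohorts report.  Dosages are drawn per variant as
Binomial(2, carrier frequency), a Hardy–Weinberg-like simplification; only the
`n_signature_proteins` signature proteins receive dosage effects
(±`effect_size_per_dosage`, random sign per protein).

Residual noise carries a 1% per-cell heavy-tailed "spike" component
(sd multiplier 5) emulating the sporadic misquantifications of DIA data.  This
matters for the technical-outlier rule: with purely Gaussian noise every
sample's robust-z outlier-protein count is ≈0 and a quantile fence over counts
is degenerate; with a realistic per-sample count level (tens of spiked cells
per sample at thousands of proteins) the fence separates cleanly.

Missingness is logistic left-censoring on the true intensity:
`P(missing) = sigmoid(steepness * (midpoint − y))`, midpoint 15 log2 units
(≈5–10% missing overall, concentrated in low-abundance proteins) — the
mechanism the shifted-Gaussian imputation presumes.  Pooled-QC replicates are
appended per plate (8 per plate, mirroring an every-12th-well layout) with
replicate noise solved from the linear-scale CV target:
`sigma_log2 = sqrt(ln(1 + CV^2)) / ln 2`, CV 0.25.  Blood contamination
elevates a fixed 8-marker erythrocyte/plasma panel (HBB, HBA1, ALB, CA1, CA2,
CAT, PRDX2, SLC4A1) by +4 log2 in a configurable fraction of samples;
technical outliers shift 40% of (non-panel) proteins by +8 log2.  Planted
outlier shifts avoid the blood panel so that the two planted truth channels
remain separately measurable — a whole-proteome shift would (correctly) be
caught by the blood rule first.

The rat arm draws six groups at the study's sizes (WT 13, KO 9, G2019S 8,
Ctrl 13, MLi-2 7, PF-475 7).  Planted fold-change vectors share a latent
loss-of-function component: the gain-of-function vector mixes it to hit the
anticorrelation target exactly (and is an exact mirror at −1); the two
inhibitors share a positive loading on it plus a common inhibitor component,
giving corr(inhibitors) ≈ 0.85 and corr(inhibitor, KO) ≈ 0.5.  Fold-change
scale (sd 2.5 on a 70% perturbed fraction) is calibrated so that the KO
contrast flags roughly half of the proteome at p < 0.05 at these group sizes,
matching the study-scale observation that a knockout perturbs the majority of
the urinary proteome.

What the generator does **not** emulate: protein–protein covariance beyond
the planted structure, peptide-level effects, retention-time or batch drift,
non-linear age effects, and genotype–diagnosis correlation.  Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery, not performance on real cohorts.

## QC pipeline

Fixed order: log2 transform (if the input is linear) → blood-contamination
flagging → technical-outlier flagging → valid-value filtering → shifted-
Gaussian imputation → optional batch adjustment.  Observed values are altered
only by the transform and the batch adjustment.

* **Pooled CV** — per plate and protein, sample sd / mean of the pooled
  replicates on the linear scale (the field convention behind "CV of 25%");
  proteins with a missing pooled value on a plate are skipped for that plate;
  the summary is the median over (protein, plate).
* **Blood rule** — per sample, the mean log2 intensity of quantified panel
  markers; flagged if its robust z across samples exceeds 3.5 (upper tail:
  contamination elevates the panel).
* **Technical rule** — per protein, robust z = (x − median)/(1.4826·MAD)
  across samples; a sample's outlier count is the number of proteins with
  |z| > 3.5; within each experimental group, samples above the Tukey fence
  Q3 + 1.5·IQR of the counts are excluded (upper tail only — low counts are
  unproblematic).  The rule is peeled to a fixed point (z, counts and fences
  recomputed on survivors until nothing new is flagged), which makes a re-run
  on its own output a no-op.  The count fence is a within-group quantile and
  is only stable with a few hundred samples per group and a realistic
  per-sample count level; the validation runs therefore use a single
  500-sample group at 3000 proteins (the study's protein-count range).
* **Valid-value filter** — keep a protein if ≥70% of some experimental
  group's samples quantify it (the fraction is configurable; "valid values in
  at least one group" is operationalized as a fraction threshold).
* **Imputation** — per sample with observed mean μ and sd σ, missing entries
  are drawn from N(μ − 3σ, (0.3σ)²), seeded.  Per-sample moments (not global)
  are used, following the left-censored proteomics convention.
* **Batch adjustment** — per protein, each batch is standardized and mapped
  back onto the protein's grand mean and pooled sd; batch means agree to
  numerical tolerance afterwards.  This is a deliberate plain location/scale
  adjuster without empirical-Bayes shrinkage: reproducible, assumption-light,
  and sufficient for the robustness-check role it plays here.  A zero-sd
  batch degenerates to a location-only shift.

A known interaction: imputed values are deliberately down-shifted, so
re-running outlier flagging *after* imputation would flag high-missingness
samples; idempotence holds at the flagging stage's own (pre-imputation)
matrix, which is what the pipeline re-uses.

## Genotype–proteome association

Per protein, ordinary least squares of log2 intensity on standardized
covariates (age, sex encoded 0/1, and dosage covariates, all scaled to mean 0
and sd 1): `y = β0 + β1·age + β2·sex + β3·dosage_1 + …`.  Betas, standard
errors and two-sided t-test p values are extracted per covariate;
Benjamini–Hochberg q values are computed across proteins separately within
each covariate family (matching per-variant reporting).  Dosages may enter
variant-by-variant or aggregated per locus (summing 0/1/2 encodings across a
locus's variants); aggregated and raw modes agree exactly for single-variant
loci.  The default path runs post-imputation on a balanced design (vectorized
single solve); with missing values each protein is fit complete-case.
Reported betas are per standardized unit; the covariate's raw sd is included
so `beta / covariate_sd` recovers natural units.  Because imputation pulls
censored low values below their true intensities, recovered dosage effects
carry a small upward bias (~+0.05 log2 at the default ~5–10% missingness) —
an honest property of shifted-Gaussian imputation near the censoring limit.

Beta-profile comparisons correlate two covariates' beta vectors over shared
proteins (Pearson, t-approximation p, BH across requested pairs).  Beta
normalization divides by the maximum **absolute** beta within a covariate
(keeping outputs in [−1, 1] and signs intact).  Venn utilities give exact
region cardinalities for 2–3 significant sets plus the "in ≥2 sets" count.
Severity correlations are per-protein Pearson r against a clinical score
within a subgroup, BH-corrected.

## Co-regulation network

For every ordered pair of proteins, a univariate ridge regression on
population-standardized log2 intensities; the coefficient is
`n·r/(n + λ)` with λ = 1 by default (λ = 0 recovers the Pearson correlation
exactly, which the tests exploit as the OLS limit).  The p value is the exact
correlation t-test — ridge shrinkage has no standard finite-sample test, so
the unpenalized test is used for screening; q is BH across all ordered pairs.
Edges join pairs where either direction has q < 0.05 (strict) and
|coefficient| ≥ 0.15 (inclusive); when both directions pass, the edge carries
the larger-|coefficient| direction's statistics.  Louvain community detection
(networkx implementation, resolution 1, unweighted, seeded) partitions the
graph.

Pivotal proteins are ranked by their mean univariate-ridge R² predicting
every other network protein.  The cumulative curve refits a multi-predictor
ridge of the top-k proteins against every network protein, dropping the
target from its own predictor set; keeping the target set fixed makes the
curve comparable (and empirically non-decreasing) across k.  The elbow is the
kneedle rule — the k with maximal perpendicular distance from the chord — with
the chord anchored at the origin (zero proteins explain zero variance), so a
curve that jumps once and stagnates elbows at the jump and an exactly
proportional curve ties at zero and resolves to k = 1.

## Staged SVM classifier

Per-cohort stratified 70/30 split; the cohorts' training parts are combined.
Stage one ranks features by ANOVA F and, separately, by nearest-neighbour
mutual information (3 neighbours, seeded) and intersects the two top-k lists
(union fallback if the intersection is below 30, logged).  Stage two fits one
linear-kernel SVM (C = 1, standardized features) on all candidates and orders
them by |coefficient|.  Stage three adds features in rank order under
repeated stratified 5×3 cross-validation, recording train- and
validation-fold ROC AUC, accuracy and average precision (standardization
learned inside each training fold).  The feature count is the smallest k
whose train−validation AUC gap is ≤ δ (0.05) with validation AUC within ε
(0.01) of its maximum — an explicit operationalization of stopping "where the
train and validation curves meet".  Evaluation is per held-out cohort plus
pooled: ROC/AUC, precision–recall/AP, and the confusion matrix at decision
threshold 0 on the margin.  A restricted mode trains on a fixed externally
supplied panel (e.g. perturbation-derived features) with no selection; a
cross-cohort mode selects on one cohort's training split only and drops
candidates absent from any designated test cohort's feature universe.

## Perturbation differentials and species transfer

Contrasts use the unpaired two-tailed Student (pooled-variance) t-test —
Welch is available behind a flag — with log2 fold-change as the difference of
log2 group means and BH within each contrast (adding a contrast never touches
another's q values).  Perturbation-arm significance defaults to unadjusted
p < 0.05 (volcano convention), while human-arm significance uses q < 0.05;
the thresholds are separate parameters and never conflated.  Cross-contrast
Pearson correlations of fold-change vectors are offered over all shared
proteins or a jointly significant subset.  The consensus signature is the
all-contrast intersection of significant sets, with full membership-pattern
region counts.  Ortholog transfer consumes an explicit one-to-one mapping
table (a case-normalizing symbol matcher, HEXB↔Hexb, is provided as a logged
convenience heuristic) and reports detected and significantly regulated
homolog counts.  Direction comparison normalizes human betas and per-contrast
rat fold-changes by their maximum absolute values and reports per-protein
sign concordance and per-contrast concordant fractions.

## Validation design and problem sizes

The test suite validates by: exact equivalence to independent brute-force
oracles (BH step-up, Student t, ridge normal equations, Venn enumeration, at
1e−10); null calibration (≤1% q < 0.05 proteins in association and
differential nulls, ≤5% of ordered pairs in network nulls); parameter
recovery (dosage effects 0.8 log2/dosage at n = 300 recovered within ±0.1
with ≥90% signature power; planted fold-change anticorrelation −0.7 recovered
within ±0.15 both from planted truth and re-estimated through the t-test
stage); structure recovery (Louvain ARI ≥ 0.9 on 4-block data; elbow within
{3,4,5} on 4-factor data; permuted-label AUC 0.5 ± 0.1); and QC behaviour
(planted contamination and outliers flagged at ≥90% sensitivity with ≤1%
false flags; imputed moments within tolerance of the stated Gaussian).
Simulation sizes (500–3000 proteins, 300–600 samples, 5–20 seeds per
quantity) are chosen as the smallest at which these estimates are stable.

## Known limitations

* **Panel recall under the stopping rule.**  With 30 equally strong planted
  features (0.8 log2/dosage, residual sd 1, n = 600) roughly 15 features
  already achieve validation AUC ≈ 0.98, so the train/validation-intersection
  rule stops at k ≈ 15–22 and recovers only ~50–65% of the planted panel
  (held-out AUC ≥ 0.9 throughout).  This is a property of the selection rule
  under strongly separable effects, not an implementation defect; the
  corresponding acceptance check is intentionally left failing with this
  analysis.  Smaller ε or a fixed k = 30 recovers more of the panel.
* Shifted-Gaussian imputation biases effect estimates upward near the
  censoring limit (see above); complete-case association is available where
  that matters.
* The location/scale batch adjuster does not shrink across proteins; with
  very small batches an empirical-Bayes method would be preferable.
* Ridge p values are screening statistics (unpenalized correlation tests),
  not inference on the shrunken coefficients.
* The generator's independence assumptions (variants, proteins, plates) make
  null calibration easier than on real data with correlated proteins; the
  network stage is exercised on explicitly correlated planted structures to
  compensate.
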