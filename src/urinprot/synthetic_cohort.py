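"""Synthetic multi-cohort urinary-proteomics generator with planted ground truth.

Emulates the statistical structure of a multi-cohort human urine study
(genotype effects on a signature protein subset, age/sex confounding, plate
batches, pooled technical replicates, intensity-dependent left-censoring,
blood-contaminated samples) and a four-contrast rat perturbation arm in which
the gain-of-function contrast is anticorrelated with loss-of-function and
kinase-inhibition contrasts.

Every stochastic choice flows from a single :class:`numpy.random.Generator`
seeded from ``SimConfig.seed``, so identical configs give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable, ProteinMatrix

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "DEFAULT_BLOOD_PANEL",
    "simulate_human_cohorts",
    "simulate_rat_arm",
]

#: erythrocyte / plasma proteins used as the blood-contamination marker panel
DEFAULT_BLOOD_PANEL = ("HBB", "HBA1", "ALB", "CA1", "CA2", "CAT", "PRDX2", "SLC4A1")

#: rat perturbation groups: (case group, control group) per contrast
RAT_CONTRASTS = {
    "KO_vs_WT": ("KO", "WT"),
    "G2019S_vs_WT": ("G2019S", "WT"),
    "MLi2_vs_Ctrl": ("MLi2", "Ctrl"),
    "PF475_vs_Ctrl": ("PF475", "Ctrl"),
}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Intensity units are log2 throughout.  Defaults emulate a desk-scale
    version of a three-cohort urinary study: a large discovery cohort plus two
    smaller replication cohorts, ~25% pooled technical CV, ~1 log2-unit
    residual biological spread, modest plate effects and a logistic
    left-censoring rule that removes predominantly low-abundance values.
    """

    n_proteins: int = 1000
    n_samples_per_cohort: dict[str, int] = field(
        default_factory=lambda: {"PPMI": 300, "LCC": 100, "Columbia": 100}
    )
    n_signature_proteins: int = 30
    effect_size_per_dosage: float = 0.8  # log2 units per dosage unit
    age_slope: float = 0.01  # log2 units per year, all proteins
    sex_offset: float = 0.25  # log2 units (male - female), all proteins
    plate_sd: float = 0.2  # sd of per-(plate, protein) batch shifts
    residual_sd: float = 1.0  # biological + technical residual sd
    pooled_cv_target: float = 0.25  # linear-scale CV of pooled replicates
    censor_midpoint: float = 15.0  # log2 intensity of 50% missingness
    censor_steepness: float = 0.7  # logistic slope of the censoring rule
    blood_contamination_rate: float = 0.02
    variant_table: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("LRRK2_G2019S", "LRRK2", 0.15),
            ("LRRK2_R1441G", "LRRK2", 0.05),
            ("GBA_N370S", "GBA", 0.10),
        ]
    )
    seed: int = 0

    # --- generator plumbing (not part of the study design proper) ---
    baseline_mean: float = 20.0  # log2 centre of protein baselines
    baseline_sd: float = 2.0  # spread of protein baselines
    plate_size: int = 80  # biological samples per plate
    n_pooled_per_plate: int = 8  # pooled-QC replicates appended per plate
    blood_panel: tuple[str, ...] = DEFAULT_BLOOD_PANEL
    blood_offset: float = 4.0  # log2 elevation of panel in contaminated samples
    technical_outlier_rate: float = 0.01
    outlier_shift: float = 8.0  # log2 shift applied to outlier samples
    outlier_protein_fraction: float = 0.4
    spike_rate: float = 0.01  # per-cell sporadic misquantification probability
    spike_sd_multiplier: float = 5.0  # sd of a spike relative to residual_sd
    age_range: tuple[float, float] = (40.0, 80.0)
    rat_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"WT": 13, "KO": 9, "G2019S": 8, "Ctrl": 13, "MLi2": 7, "PF475": 7}
    )
    rat_effect_sd: float = 2.5  # sd of planted rat log2 fold-changes
    rat_perturbed_fraction: float = 0.7

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if any(n <= 0 for n in self.n_samples_per_cohort.values()):
            raise ValueError("cohort sizes must be positive")
        if self.n_signature_proteins > self.n_proteins:
            raise ValueError("n_signature_proteins exceeds n_proteins")
        for name in ("plate_sd", "residual_sd", "pooled_cv_target", "effect_size_per_dosage"):
            pass
        if min(self.plate_sd, self.residual_sd, self.pooled_cv_target) < 0:
            raise ValueError("standard deviations and CV targets must be >= 0")
        for frac in (self.blood_contamination_rate, self.technical_outlier_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"rate {frac} outside [0, 1]")
        for _, _, freq in self.variant_table:
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"carrier frequency {freq} outside [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth injected by the generator.

    ``true_betas`` is protein x covariate (age, sex and one column per
    variant) in log2 units per natural covariate unit.  ``rat_fold_changes``
    is protein x contrast (zero rows for unperturbed proteins).
    """

    signature_protein_ids: set[str] = field(default_factory=set)
    true_betas: pd.DataFrame | None = None
    rat_fold_changes: pd.DataFrame | None = None
    contaminated_sample_ids: set[str] = field(default_factory=set)
    outlier_sample_ids: set[str] = field(default_factory=set)


def _protein_ids(config: SimConfig) -> list[str]:
    """Generic protein ids with the blood panel occupying the final slots."""
    panel = list(config.blood_panel)
    n_generic = config.n_proteins - len(panel)
    if n_generic < config.n_signature_proteins:
        raise ValueError("n_proteins too small for signature plus blood panel")
    ids = [f"P{i:05d}" for i in range(n_generic)]
    return ids + panel


def _noise(rng: np.random.Generator, sd: float, size: int, config: SimConfig) -> np.ndarray:
    """Residual noise with a sporadic heavy-tailed spike component.

    Most cells get Normal(0, sd); a small fraction (``spike_rate``) get a
    wider Normal, emulating the sporadic misquantifications of real DIA data
    (without them, robust-z outlier counts would be unrealistically uniform
    across samples).
    """
    x = rng.normal(0.0, sd, size)
    if config.spike_rate > 0:
        mask = rng.random(size) < config.spike_rate
        x[mask] = rng.normal(0.0, config.spike_sd_multiplier * sd, int(mask.sum()))
    return x


def _censor(rng: np.random.Generator, values: np.ndarray, config: SimConfig) -> np.ndarray:
    """Logistic left-censoring on true log2 intensity; returns values with NaN."""
    if np.isneginf(config.censor_midpoint):
        return values
    p_miss = 1.0 / (1.0 + np.exp(-config.censor_steepness * (config.censor_midpoint - values)))
    mask = rng.random(values.shape) < p_miss
    out = values.copy()
    out[mask] = np.nan
    return out


def simulate_human_cohorts(
    config: SimConfig,
) -> tuple[ProteinMatrix, pd.DataFrame, GenotypeTable, PlantedTruth]:
    """Generate the human multi-cohort dataset.

    Returns the log2 intensity matrix (pooled-QC replicates included), sample
    metadata, the variant dosage table (biological samples only) and the
    planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proteins = _protein_ids(config)
    n_prot = len(proteins)
    signature = proteins[: config.n_signature_proteins]
    panel_idx = np.arange(n_prot - len(config.blood_panel), n_prot)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_prot)

    # planted regression truth: flat age/sex effects, signature-only dosage betas
    variants = [v for v, _, _ in config.variant_table]
    betas = pd.DataFrame(0.0, index=proteins, columns=["age", "sex"] + variants)
    betas["age"] = config.age_slope
    betas["sex"] = config.sex_offset
    for v in variants:
        signs = rng.choice([-1.0, 1.0], size=len(signature))
        betas.loc[signature, v] = config.effect_size_per_dosage * signs

    rows, meta_rows, geno_rows = [], [], []
    sample_ids, bio_ids = [], []
    for cohort, n_samples in config.n_samples_per_cohort.items():
        n_plates = max(1, int(np.ceil(n_samples / config.plate_size)))
        plate_effects = rng.normal(0.0, config.plate_sd, size=(n_plates, n_prot))
        ages = rng.uniform(*config.age_range, n_samples)
        sexes = rng.integers(0, 2, n_samples)  # 1 = male
        dosages = np.column_stack(
            [rng.binomial(2, freq, n_samples) for _, _, freq in config.variant_table]
        ) if variants else np.zeros((n_samples, 0), int)
        diagnosis = rng.choice(["PD", "prodromal", "HC"], size=n_samples, p=[0.5, 0.35, 0.15])

        for i in range(n_samples):
            sid = f"{cohort}_S{i:04d}"
            plate_no = i // config.plate_size
            true = (
                baselines
                + betas["age"].to_numpy() * ages[i]
                + betas["sex"].to_numpy() * sexes[i]
                + plate_effects[plate_no]
                + _noise(rng, config.residual_sd, n_prot, config)
            )
            for j, v in enumerate(variants):
                true = true + betas[v].to_numpy() * dosages[i, j]
            rows.append(true)
            sample_ids.append(sid)
            bio_ids.append(sid)
            carrier = bool(variants) and dosages[i, :].sum() > 0
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cohort": cohort,
                    "diagnosis": diagnosis[i],
                    "age": ages[i],
                    "sex": "M" if sexes[i] else "F",
                    "plate": f"{cohort}_plate{plate_no}",
                    "is_pooled_qc": False,
                    "mutation_label": "carrier" if carrier else "non-carrier",
                    "experimental_group": cohort,
                }
            )
            geno_rows.append(dosages[i])

        # pooled-QC replicates: a common pool measured repeatedly on each plate
        pool_true = baselines + betas["age"].to_numpy() * np.mean(ages)
        cv = config.pooled_cv_target
        rep_sd = np.sqrt(np.log1p(cv**2)) / np.log(2.0) if cv > 0 else 0.0
        for plate_no in range(n_plates):
            for r in range(config.n_pooled_per_plate):
                sid = f"{cohort}_pool_p{plate_no}_r{r}"
                true = pool_true + plate_effects[plate_no] + _noise(rng, rep_sd, n_prot, config)
                rows.append(true)
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cohort": cohort,
                        "diagnosis": "pool",
                        "age": np.nan,
                        "sex": "F",
                        "plate": f"{cohort}_plate{plate_no}",
                        "is_pooled_qc": True,
                        "mutation_label": "pool",
                        "experimental_group": cohort,
                    }
                )

    values = np.asarray(rows)
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    is_bio = ~meta["is_pooled_qc"].to_numpy()
    bio_positions = np.flatnonzero(is_bio)

    # blood contamination: elevate the marker panel in a random sample subset
    n_contam = rng.binomial(len(bio_positions), config.blood_contamination_rate)
    contam_pos = rng.choice(bio_positions, size=n_contam, replace=False)
    for pos in contam_pos:
        values[pos, panel_idx] += config.blood_offset

    # technical outliers: large shift on a random protein subset
    remaining = np.setdiff1d(bio_positions, contam_pos)
    n_out = rng.binomial(len(remaining), config.technical_outlier_rate)
    out_pos = rng.choice(remaining, size=n_out, replace=False)
    non_panel = np.setdiff1d(np.arange(n_prot), panel_idx)
    for pos in out_pos:
        n_shift = int(round(config.outlier_protein_fraction * len(non_panel)))
        cols = rng.choice(non_panel, size=n_shift, replace=False)
        values[pos, cols] += config.outlier_shift

    values = _censor(rng, values, config)

    matrix = ProteinMatrix(
        pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=proteins),
        scale="log2",
    )
    genotypes = GenotypeTable(
        pd.DataFrame(
            np.asarray(geno_rows, dtype=int) if geno_rows else np.zeros((0, 0)),
            index=pd.Index(bio_ids, name="sample_id"),
            columns=variants,
        ),
        variant_to_locus={v: locus for v, locus, _ in config.variant_table},
    )
    truth = PlantedTruth(
        signature_protein_ids=set(signature),
        true_betas=betas,
        contaminated_sample_ids={sample_ids[p] for p in contam_pos},
        outlier_sample_ids={sample_ids[p] for p in out_pos},
    )
    return matrix, meta, genotypes, truth


def _planted_fold_changes(
    rng: np.random.Generator, n_perturbed: int, anticorrelation: float, scale: float
) -> np.ndarray:
    """Planted (n_perturbed x 4) fold-change matrix [KO, G2019S, MLi2, PF475].

    Construction: KO fold-changes are a latent vector z; the gain-of-function
    contrast mixes z with fresh noise to hit the anticorrelation target exactly
    in expectation (and exactly in sign at -1); the two inhibitors share a
    positive loading on z plus a common inhibitor component, giving
    corr(inhibitor, KO) > 0 and corr(MLi2, PF475) > 0.
    """
    a = float(anticorrelation)
    if not -1.0 <= a <= 0.0:
        raise ValueError("anticorrelation must lie in [-1, 0]")
    z = rng.standard_normal(n_perturbed)
    e_g = rng.standard_normal(n_perturbed)
    w = rng.standard_normal(n_perturbed)
    e_p = rng.standard_normal(n_perturbed)
    f_ko = z
    f_g = a * z + np.sqrt(1.0 - a * a) * e_g
    f_m = 0.5 * z + np.sqrt(0.75) * w
    f_p = 0.5 * z + np.sqrt(0.75) * (0.8 * w + 0.6 * e_p)
    return scale * np.column_stack([f_ko, f_g, f_m, f_p])


def simulate_rat_arm(
    config: SimConfig, anticorrelation: float = -0.7
) -> tuple[ProteinMatrix, pd.Series, PlantedTruth]:
    """Generate the four-contrast rat perturbation dataset.

    Returns the log2 matrix over all six groups (WT, KO, G2019S, Ctrl, MLi-2,
    PF-475), a sample -> group label Series, and the planted truth with the
    per-contrast fold-change vectors.
    """
    config.validate()
    if any(n < 2 for n in config.rat_group_sizes.values()):
        raise ValueError("each rat group needs >= 2 samples")
    rng = np.random.default_rng(config.seed + 1)
    proteins = [f"R{i:05d}" for i in range(config.n_proteins)]
    n_prot = len(proteins)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_prot)

    n_pert = int(round(config.rat_perturbed_fraction * n_prot))
    pert_idx = rng.choice(n_prot, size=n_pert, replace=False)
    fc = np.zeros((n_prot, 4))
    fc[pert_idx] = _planted_fold_changes(rng, n_pert, anticorrelation, config.rat_effect_sd)
    fc_df = pd.DataFrame(fc, index=proteins, columns=list(RAT_CONTRASTS))

    group_shift = {
        "WT": np.zeros(n_prot),
        "Ctrl": np.zeros(n_prot),
        "KO": fc[:, 0],
        "G2019S": fc[:, 1],
        "MLi2": fc[:, 2],
        "PF475": fc[:, 3],
    }

    rows, ids, labels = [], [], []
    for group, n in config.rat_group_sizes.items():
        for i in range(n):
            ids.append(f"rat_{group}_{i:02d}")
            labels.append(group)
            rows.append(
                baselines + group_shift[group] + _noise(rng, config.residual_sd, n_prot, config)
            )
    values = _censor(rng, np.asarray(rows), config)
    matrix = ProteinMatrix(
        pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=proteins),
        scale="log2",
    )
    groups = pd.Series(labels, index=matrix.sample_ids, name="experimental_group")
    truth = PlantedTruth(
        signature_protein_ids={proteins[i] for i in pert_idx},
        rat_fold_changes=fc_df,
    )
    return matrix, groups, truth
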