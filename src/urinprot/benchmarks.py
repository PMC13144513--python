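"""Benchmark computations: calibration, recovery and worked-example checks.

Each function recomputes one headline quantity of the pipeline from scratch —
generating synthetic cohorts, running the relevant stages, and measuring the
result.  They back both the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ProteinMatrix
from .genotype_association import fit_protein_regressions
from .perturbation_differential import Contrast, contrast_correlation, run_contrast
from .protein_network import (
    build_network,
    cluster_louvain,
    elbow_select,
    incremental_r2,
    pairwise_ridge,
    rank_pivotal,
)
from .qc_filtering import (
    ImputeParams,
    filter_valid_values,
    flag_blood_contamination,
    flag_technical_outliers,
    impute_shifted_gaussian,
    pooled_cv,
    run_qc_pipeline,
)
from .signature_classifier import CohortEvaluation, train_classifier
from .synthetic_cohort import RAT_CONTRASTS, SimConfig, simulate_human_cohorts, simulate_rat_arm

#: aggregate held-out confusion counts of the published mutation-status
#: classifier (carriers correct / total, controls correct / total)
PUBLISHED_CONFUSION = {"tp": 80, "fn": 11, "tn": 137, "fp": 34}

#: published per-cohort held-out ROC AUCs (PPMI, LCC, Columbia)
PUBLISHED_TEST_AUCS = (0.89, 0.89, 0.96)


def confusion_statistics(counts: dict | None = None) -> dict:
    """Sensitivity/specificity (percent) from aggregate confusion counts."""
    counts = counts or PUBLISHED_CONFUSION
    ev = CohortEvaluation("pooled", None, np.nan, None, np.nan, **counts)
    return {
        "sensitivity_percent": 100.0 * ev.sensitivity,
        "specificity_percent": 100.0 * ev.specificity,
        "n": ev.tp + ev.fn + ev.tn + ev.fp,
    }


def mean_test_auc(aucs=PUBLISHED_TEST_AUCS) -> float:
    """Mean of the per-cohort held-out ROC AUCs."""
    return float(np.mean(aucs))


def _recovery_config(seed: int) -> SimConfig:
    return SimConfig(
        n_proteins=500,
        n_samples_per_cohort={"PPMI": 300},
        n_signature_proteins=20,
        effect_size_per_dosage=0.8,
        variant_table=[("G2019S", "LRRK2", 0.15)],
        seed=seed,
    )


def association_null_rate(seeds) -> float:
    """Fraction of proteins with dosage q < 0.05 on fully null simulations."""
    rates = []
    for seed in seeds:
        config = _recovery_config(seed)
        config.effect_size_per_dosage = 0.0
        config.age_slope = 0.0
        config.sex_offset = 0.0
        matrix, meta, genotypes, _ = simulate_human_cohorts(config)
        clean, clean_meta, _ = run_qc_pipeline(
            matrix, meta, impute_params=ImputeParams(seed=seed)
        )
        genotypes.dosages = genotypes.dosages.reindex(clean.sample_ids)
        assoc = fit_protein_regressions(clean, clean_meta, genotypes)
        dosage = assoc.covariate_frame("G2019S")
        rates.append(float((dosage["q"] < 0.05).mean()))
    return float(np.mean(rates))


def differential_null_rate(seeds) -> float:
    """Fraction of proteins with q < 0.05 in zero-effect rat contrasts."""
    rates = []
    for seed in seeds:
        config = SimConfig(n_proteins=1000, rat_effect_sd=0.0, seed=seed)
        matrix, groups, _ = simulate_rat_arm(config, 0.0)
        gdict = {g: list(groups.index[groups == g]) for g in groups.unique()}
        imputed = impute_shifted_gaussian(
            filter_valid_values(matrix, gdict, 0.7), ImputeParams(seed=seed)
        )
        res = run_contrast(imputed, Contrast("KO_vs_WT", gdict["KO"], gdict["WT"]))
        rates.append(float((res.table["q"] < 0.05).mean()))
    return float(np.mean(rates))


def network_null_rate(seeds, n_samples: int = 300, n_proteins: int = 40) -> float:
    """Fraction of ordered pairs with q < 0.05 on independent noise."""
    rates = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        mat = ProteinMatrix(
            pd.DataFrame(
                rng.standard_normal((n_samples, n_proteins)),
                index=[f"s{i}" for i in range(n_samples)],
                columns=[f"p{j}" for j in range(n_proteins)],
            )
        )
        stats_ = pairwise_ridge(mat)
        rates.append(float(np.nanmean(stats_.q.to_numpy() < 0.05)))
    return float(np.mean(rates))


def dosage_effect_recovery(seeds) -> dict:
    """Mean signed error of recovered dosage betas and signature power."""
    errors, powers = [], []
    for seed in seeds:
        config = _recovery_config(seed)
        matrix, meta, genotypes, truth = simulate_human_cohorts(config)
        clean, clean_meta, _ = run_qc_pipeline(
            matrix, meta, impute_params=ImputeParams(seed=seed)
        )
        genotypes.dosages = genotypes.dosages.reindex(clean.sample_ids)
        assoc = fit_protein_regressions(clean, clean_meta, genotypes)
        dosage = assoc.covariate_frame("G2019S")
        sig = sorted(truth.signature_protein_ids & set(dosage.index))
        unstd = dosage.loc[sig, "beta"] / dosage.loc[sig, "covariate_sd"]
        planted = truth.true_betas.loc[sig, "G2019S"]
        errors.extend((unstd / np.sign(planted) - np.abs(planted)).tolist())
        powers.extend((dosage.loc[sig, "q"] < 0.05).tolist())
    return {
        "mean_beta_error": float(np.mean(errors)),
        "power": float(np.mean(powers)),
        "n": len(errors),
    }


def rat_anticorrelation_recovery(seeds, target: float = -0.7) -> dict:
    """Planted and re-estimated KO vs gain-of-function fold-change correlation."""
    planted_r, estimated_r = [], []
    for seed in seeds:
        config = SimConfig(n_proteins=1000, seed=seed)
        matrix, groups, truth = simulate_rat_arm(config, target)
        pert = sorted(truth.signature_protein_ids)
        fc = truth.rat_fold_changes.loc[pert]
        planted_r.append(float(np.corrcoef(fc["KO_vs_WT"], fc["G2019S_vs_WT"])[0, 1]))
        gdict = {g: list(groups.index[groups == g]) for g in groups.unique()}
        imputed = impute_shifted_gaussian(
            filter_valid_values(matrix, gdict, 0.7), ImputeParams(seed=seed)
        )
        results = {
            name: run_contrast(imputed, Contrast(name, gdict[case], gdict[ctrl]))
            for name, (case, ctrl) in RAT_CONTRASTS.items()
        }
        r, _, _ = contrast_correlation(results["KO_vs_WT"], results["G2019S_vs_WT"])
        estimated_r.append(float(r))
    return {
        "planted_r": float(np.mean(planted_r)),
        "estimated_r": float(np.mean(estimated_r)),
        "n": len(seeds),
    }


def _block_matrix(seed, n=500, blocks=4, per=10, wcorr=0.7):
    rng = np.random.default_rng(seed)
    a = np.sqrt(wcorr)
    cols, labels = [], []
    for b in range(blocks):
        f = rng.standard_normal(n)
        for _ in range(per):
            cols.append(a * f + np.sqrt(1 - a * a) * rng.standard_normal(n))
            labels.append(b)
    names = [f"b{lab}_{j:02d}" for j, lab in enumerate(labels)]
    mat = ProteinMatrix(
        pd.DataFrame(np.column_stack(cols), index=[f"s{i}" for i in range(n)], columns=names)
    )
    return mat, labels


def louvain_block_recovery(seeds) -> float:
    """Mean adjusted Rand index on planted 4-block networks."""
    from sklearn.metrics import adjusted_rand_score

    aris = []
    for seed in seeds:
        mat, labels = _block_matrix(seed)
        model = cluster_louvain(build_network(pairwise_ridge(mat)), seed=seed)
        pred = [model.clusters[c] for c in mat.protein_ids]
        aris.append(adjusted_rand_score(labels, pred))
    return float(np.mean(aris))


def _hub_matrix(seed, n=400, n_factors=4, targets_per=9, load=0.8):
    rng = np.random.default_rng(seed)
    cols, names = [], []
    for b in range(n_factors):
        f = rng.standard_normal(n)
        cols.append(f + 0.1 * rng.standard_normal(n))
        names.append(f"hub{b}")
        for j in range(targets_per):
            cols.append(np.sqrt(load) * f + np.sqrt(1 - load) * rng.standard_normal(n))
            names.append(f"t{b}_{j}")
    return ProteinMatrix(
        pd.DataFrame(np.column_stack(cols), index=[f"s{i}" for i in range(n)], columns=names)
    )


def elbow_hit_rate(seeds, expected=(3, 4, 5)) -> float:
    """Fraction of planted 4-factor runs with elbow in the expected range."""
    hits = 0
    for seed in seeds:
        mat = _hub_matrix(seed)
        ranked = list(rank_pivotal(mat, mat.protein_ids).index)
        curve = incremental_r2(mat, ranked, max_k=15)
        hits += elbow_select(curve) in expected
    return hits / len(list(seeds))


def classifier_panel_recovery(seeds) -> dict:
    """Staged-pipeline recovery of a 30-protein planted panel (effect 0.8, n=600)."""
    recalls, aucs, chosen = [], [], []
    for seed in seeds:
        config = SimConfig(
            n_proteins=400,
            n_samples_per_cohort={"PPMI": 300, "LCC": 150, "Columbia": 150},
            n_signature_proteins=30,
            effect_size_per_dosage=0.8,
            variant_table=[("G2019S", "LRRK2", 0.3)],
            seed=seed,
        )
        matrix, meta, genotypes, truth = simulate_human_cohorts(config)
        clean, clean_meta, _ = run_qc_pipeline(
            matrix, meta, impute_params=ImputeParams(seed=seed)
        )
        labels = (genotypes.dosages.reindex(clean.sample_ids)["G2019S"] > 0).astype(int)
        report = train_classifier(clean, clean_meta, labels, seed=seed, k_each=128, max_k=60)
        recalls.append(len(set(report.features) & truth.signature_protein_ids) / 30)
        aucs.append(report.pooled.auc)
        chosen.append(report.trace.chosen_k)
    return {
        "panel_recall": float(np.mean(recalls)),
        "holdout_auc": float(np.mean(aucs)),
        "chosen_k": float(np.mean(chosen)),
        "n": len(list(seeds)),
    }


def permuted_label_auc(seeds, matrix=None, meta=None, labels=None) -> float:
    """Mean held-out AUC of the staged pipeline under label permutation."""
    if matrix is None:
        config = SimConfig(
            n_proteins=200,
            n_samples_per_cohort={"PPMI": 120, "LCC": 80},
            n_signature_proteins=15,
            variant_table=[("G2019S", "LRRK2", 0.3)],
            seed=11,
        )
        raw, raw_meta, genotypes, _ = simulate_human_cohorts(config)
        matrix, meta, _ = run_qc_pipeline(raw, raw_meta, impute_params=ImputeParams(seed=11))
        labels = (genotypes.dosages.reindex(matrix.sample_ids)["G2019S"] > 0).astype(int)
    aucs = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        report = train_classifier(matrix, meta, perm, seed=seed, k_each=48, max_k=8)
        aucs.append(report.pooled.auc)
    return float(np.mean(aucs))


def qc_flagging_performance(seeds) -> dict:
    """Sensitivity and false-flag rates of the blood and outlier rules."""
    blood_tp = blood_n = blood_fp = blood_neg = 0
    tech_tp = tech_n = tech_fp = tech_neg = 0
    cvs = []
    for seed in seeds:
        config = SimConfig(
            n_proteins=3000,
            n_samples_per_cohort={"PPMI": 500},
            blood_contamination_rate=0.05,
            technical_outlier_rate=0.02,
            seed=seed,
        )
        matrix, meta, _, truth = simulate_human_cohorts(config)
        cvs.append(pooled_cv(matrix, meta).median_pooled_cv)
        bio = meta.index[~meta.is_pooled_qc]
        blood = set(flag_blood_contamination(matrix.subset_samples(bio)))
        contam = truth.contaminated_sample_ids
        blood_tp += len(blood & contam)
        blood_n += len(contam)
        blood_fp += len(blood - contam)
        blood_neg += len(bio) - len(contam)
        keep = bio.difference(blood)
        tech = set(flag_technical_outliers(matrix.subset_samples(keep), meta.loc[keep]))
        outliers = truth.outlier_sample_ids
        tech_tp += len(tech & outliers)
        tech_n += len(outliers)
        tech_fp += len(tech - outliers)
        tech_neg += len(keep) - len(outliers)
    return {
        "blood_sensitivity": blood_tp / blood_n,
        "blood_false_rate": blood_fp / blood_neg,
        "technical_sensitivity": tech_tp / tech_n,
        "technical_false_rate": tech_fp / tech_neg,
        "median_pooled_cv": float(np.median(cvs)),
        "n_planted": blood_n + tech_n,
    }


def imputation_moments(seed: int = 0, n_obs: int = 4000, n_miss: int = 1500) -> dict:
    """Offsets of imputed-value moments from the stated shifted Gaussian.

    Returns the deviation of the imputed mean from (mu - 3 sd) and of the
    imputed sd from 0.3 sd, both in units of the sample's observed sd.
    """
    rng = np.random.default_rng(seed)
    vals = np.empty((1, n_obs + n_miss))
    vals[0, :n_obs] = rng.normal(20, 2, n_obs)
    vals[0, n_obs:] = np.nan
    mat = ProteinMatrix(
        pd.DataFrame(vals, index=["s0"], columns=[f"p{j}" for j in range(n_obs + n_miss)])
    )
    out = impute_shifted_gaussian(mat, ImputeParams(seed=seed))
    obs = vals[0, :n_obs]
    mu, sd = obs.mean(), obs.std(ddof=1)
    imputed = out.data.iloc[0, n_obs:]
    return {
        "mean_offset_sd_units": float((imputed.mean() - (mu - 3 * sd)) / sd),
        "sd_offset_sd_units": float((imputed.std(ddof=1) - 0.3 * sd) / sd),
        "n": n_miss,
    }
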