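"""QC stage: transforms, CV, exclusion rules, imputation, batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from urinprot.containers import ProteinMatrix
from urinprot.qc_filtering import (
    ImputeParams,
    QcReport,
    batch_adjust,
    filter_valid_values,
    flag_blood_contamination,
    flag_technical_outliers,
    impute_shifted_gaussian,
    log2_transform,
    pooled_cv,
    run_qc_pipeline,
)
from urinprot.synthetic_cohort import SimConfig, simulate_human_cohorts


def matrix_from(values, scale="log2", samples=None, proteins=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    proteins = proteins or [f"p{j}" for j in range(values.shape[1])]
    return ProteinMatrix(pd.DataFrame(values, index=samples, columns=proteins), scale)


class TestLog2Transform:
    def test_elementwise_log2(self):
        mat = matrix_from([[1024.0, 1.0, 8.0]], scale="linear")
        out = log2_transform(mat)
        assert out.scale == "log2"
        assert out.data.iloc[0].tolist() == [10.0, 0.0, 3.0]

    def test_matches_numpy_oracle_and_preserves_missing(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.5, 1e6, size=(3, 3))
        vals[1, 2] = np.nan
        out = log2_transform(matrix_from(vals, scale="linear"))
        expected = np.log2(vals)
        assert np.allclose(out.data.to_numpy(), expected, equal_nan=True)

    def test_nonpositive_value_names_offending_cell(self):
        mat = matrix_from([[2.0, -1.0]], scale="linear")
        with pytest.raises(ValueError, match="s0.*p1"):
            log2_transform(mat)

    def test_rejects_log2_input(self):
        with pytest.raises(ValueError, match="linear"):
            log2_transform(matrix_from([[1.0]], scale="log2"))


def pooled_meta(sample_ids, plate="A"):
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "plate": plate,
            "is_pooled_qc": True,
            "experimental_group": "x",
        }
    ).set_index("sample_id", drop=False)


class TestPooledCv:
    def test_identical_replicates_give_zero_cv(self):
        mat = matrix_from(np.full((3, 4), 100.0), scale="linear")
        report = pooled_cv(mat, pooled_meta(list(mat.sample_ids)))
        assert (report.cv_table["cv"] == 0).all()
        assert report.median_pooled_cv == 0.0

    def test_two_replicates_hand_computed(self):
        """CV of linear values 90 and 110 = sample sd / mean = 14.142/100."""
        mat = matrix_from([[90.0], [110.0]], scale="linear")
        report = pooled_cv(mat, pooled_meta(list(mat.sample_ids)))
        expected = np.std([90, 110], ddof=1) / 100.0
        assert report.median_pooled_cv == pytest.approx(expected)
        assert report.median_pooled_cv == pytest.approx(0.1414, abs=5e-4)

    def test_log2_input_is_backtransformed(self):
        lin = np.array([[90.0], [110.0]])
        report = pooled_cv(matrix_from(np.log2(lin), scale="log2"),
                           pooled_meta(["s0", "s1"]))
        assert report.median_pooled_cv == pytest.approx(np.std([90, 110], ddof=1) / 100.0)

    def test_no_pooled_samples_is_an_error(self):
        mat = matrix_from(np.ones((3, 2)))
        meta = pooled_meta(list(mat.sample_ids))
        meta["is_pooled_qc"] = False
        with pytest.raises(ValueError):
            pooled_cv(mat, meta)


def group_meta(sample_ids, group="g1"):
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_pooled_qc": False,
            "experimental_group": group,
        }
    ).set_index("sample_id", drop=False)


class TestTechnicalOutliers:
    def test_identical_samples_no_exclusion(self):
        mat = matrix_from(np.ones((10, 5)))
        assert flag_technical_outliers(mat, group_meta(list(mat.sample_ids))) == []

    def test_massively_shifted_sample_excluded(self):
        """+10 log2 on half the proteins in a 20-sample group trips the fence."""
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 1, size=(20, 100))
        vals[0, :50] += 10.0
        mat = matrix_from(vals)
        meta = group_meta(list(mat.sample_ids))
        excluded = flag_technical_outliers(mat, meta)
        assert "s0" in excluded
        # direct oracle: robust-z counts and the Tukey fence, first pass
        med = np.median(vals, axis=0)
        mad = np.median(np.abs(vals - med), axis=0)
        z = (vals - med) / (1.4826 * mad)
        counts = (np.abs(z) > 3.5).sum(axis=1)
        q1, q3 = np.quantile(counts, [0.25, 0.75])
        assert counts[0] > q3 + 1.5 * (q3 - q1)

    def test_planted_outliers_recovered_on_simulation(self):
        config = SimConfig(
            n_proteins=3000,
            n_samples_per_cohort={"PPMI": 400},
            blood_contamination_rate=0.0,
            technical_outlier_rate=0.02,
            seed=21,
        )
        matrix, meta, _, truth = simulate_human_cohorts(config)
        bio = meta.index[~meta.is_pooled_qc]
        excluded = set(flag_technical_outliers(matrix.subset_samples(bio), meta.loc[bio]))
        assert len(truth.outlier_sample_ids) >= 3
        sens = len(excluded & truth.outlier_sample_ids) / len(truth.outlier_sample_ids)
        assert sens >= 0.9

    def test_rerun_on_cleaned_matrix_is_idempotent(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 1, size=(60, 200))
        vals[rng.random(vals.shape) < 0.01] += rng.normal(0, 5)
        mat = matrix_from(vals)
        meta = group_meta(list(mat.sample_ids))
        excluded = flag_technical_outliers(mat, meta)
        keep = mat.sample_ids.difference(excluded)
        again = flag_technical_outliers(mat.subset_samples(keep), meta.loc[keep])
        assert again == []

    def test_zero_mad_proteins_recorded(self):
        vals = np.random.default_rng(3).normal(0, 1, size=(10, 3))
        vals[:, 0] = 7.0  # constant protein: MAD = 0
        report = QcReport()
        flag_technical_outliers(matrix_from(vals), group_meta([f"s{i}" for i in range(10)]),
                                report=report)
        assert "p0" in report.skipped_proteins


class TestBloodContamination:
    def test_no_elevation_no_flags(self):
        rng = np.random.default_rng(4)
        mat = matrix_from(rng.normal(20, 1, (200, 10)), proteins=[f"HB{i}" for i in range(10)])
        assert flag_blood_contamination(mat, panel=[f"HB{i}" for i in range(10)]) == []

    def test_single_panel_protein_extreme_sample_flagged(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 1, size=(40, 5))
        scores = vals[:, 0]
        med = np.median(scores)
        mad = np.median(np.abs(scores - med))
        vals[7, 0] = med + 10 * 1.4826 * mad
        mat = matrix_from(vals)
        flagged = flag_blood_contamination(mat, panel=["p0"])
        assert flagged == ["s7"]

    def test_planted_contamination_recovered_on_simulation(self):
        config = SimConfig(
            n_proteins=1000,
            n_samples_per_cohort={"PPMI": 400},
            blood_contamination_rate=0.05,
            technical_outlier_rate=0.0,
            seed=22,
        )
        matrix, meta, _, truth = simulate_human_cohorts(config)
        bio = meta.index[~meta.is_pooled_qc]
        flagged = set(flag_blood_contamination(matrix.subset_samples(bio)))
        contam = truth.contaminated_sample_ids
        assert len(contam) >= 10
        assert len(flagged & contam) / len(contam) >= 0.9
        false = len(flagged - contam) / (len(bio) - len(contam))
        assert false <= 0.01

    def test_empty_panel_intersection_is_an_error(self):
        mat = matrix_from(np.ones((5, 2)))
        with pytest.raises(ValueError):
            flag_blood_contamination(mat, panel=["HBB"])


class TestValidValueFilter:
    def test_fully_observed_unchanged(self):
        mat = matrix_from(np.ones((10, 4)))
        out = filter_valid_values(mat, {"a": list(mat.sample_ids)}, 0.7)
        pd.testing.assert_frame_equal(out.data, mat.data)

    def test_kept_when_one_group_reaches_fraction(self):
        vals = np.ones((20, 1))
        vals[8:10, 0] = np.nan  # group A: 8/10 observed
        vals[10:, 0] = np.nan  # group B: 0/10 observed
        mat = matrix_from(vals)
        groups = {"A": [f"s{i}" for i in range(10)], "B": [f"s{i}" for i in range(10, 20)]}
        out = filter_valid_values(mat, groups, 0.7)
        assert list(out.protein_ids) == ["p0"]

    def test_dropped_when_no_group_reaches_fraction(self):
        vals = np.ones((20, 1))
        vals[5:10, 0] = np.nan  # 5/10 in A
        vals[15:, 0] = np.nan  # 5/10 in B
        mat = matrix_from(vals)
        groups = {"A": [f"s{i}" for i in range(10)], "B": [f"s{i}" for i in range(10, 20)]}
        out = filter_valid_values(mat, groups, 0.7)
        assert len(out.protein_ids) == 0

    def test_empty_group_is_an_error(self):
        mat = matrix_from(np.ones((4, 2)))
        with pytest.raises(ValueError):
            filter_valid_values(mat, {"A": list(mat.sample_ids), "B": []}, 0.7)


class TestImputation:
    def test_identity_when_nothing_missing(self):
        mat = matrix_from(np.random.default_rng(6).normal(20, 2, (5, 30)))
        out = impute_shifted_gaussian(mat, ImputeParams(seed=0))
        pd.testing.assert_frame_equal(out.data, mat.data)

    def test_imputed_values_follow_shifted_gaussian(self):
        """Missing cells of a mu=20, sigma=2 sample land near N(14, 0.6^2)."""
        rng = np.random.default_rng(7)
        n_obs, n_miss = 4000, 1500
        vals = np.empty((1, n_obs + n_miss))
        vals[0, :n_obs] = rng.normal(20, 2, n_obs)
        vals[0, n_obs:] = np.nan
        mat = matrix_from(vals)
        out = impute_shifted_gaussian(mat, ImputeParams(seed=1))
        obs = vals[0, :n_obs]
        mu, sd = obs.mean(), obs.std(ddof=1)
        imputed = out.data.iloc[0, n_obs:]
        assert imputed.mean() == pytest.approx(mu - 3 * sd, abs=0.2)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, abs=0.15)
        assert np.allclose(out.data.iloc[0, :n_obs], obs)  # observed untouched

    def test_same_seed_reproducible(self):
        vals = np.random.default_rng(8).normal(20, 2, (6, 50))
        vals[np.random.default_rng(9).random(vals.shape) < 0.2] = np.nan
        mat = matrix_from(vals)
        a = impute_shifted_gaussian(mat, ImputeParams(seed=5))
        b = impute_shifted_gaussian(mat, ImputeParams(seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)
        c = impute_shifted_gaussian(mat, ImputeParams(seed=6))
        assert not a.data.equals(c.data)

    def test_sample_with_too_few_observations_is_an_error(self):
        vals = np.full((2, 5), np.nan)
        vals[0] = 1.0
        vals[1, 0] = 1.0
        with pytest.raises(ValueError, match="s1"):
            impute_shifted_gaussian(matrix_from(vals), ImputeParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ImputeParams(shift=-1.0)
        with pytest.raises(ValueError):
            ImputeParams(width=0.0)


class TestBatchAdjust:
    def test_single_batch_identity(self):
        mat = matrix_from(np.random.default_rng(10).normal(20, 1, (6, 4)))
        batches = pd.Series("A", index=mat.sample_ids)
        out = batch_adjust(mat, batches)
        assert np.allclose(out.data.to_numpy(), mat.data.to_numpy())

    def test_offset_batches_aligned(self):
        rng = np.random.default_rng(11)
        base = rng.normal(20, 1, (10, 8))
        vals = np.vstack([base, base + 1.0])
        mat = matrix_from(vals)
        batches = pd.Series(["A"] * 10 + ["B"] * 10, index=mat.sample_ids)
        out = batch_adjust(mat, batches)
        means_a = out.data.iloc[:10].mean()
        means_b = out.data.iloc[10:].mean()
        assert np.abs(means_a - means_b).max() < 1e-10

    def test_plate_effects_removed_on_simulation(self):
        """After adjustment, one-way plate F-tests find <1% significant proteins."""
        from scipy.stats import f_oneway

        from urinprot._stats import bh_adjust

        config = SimConfig(
            n_proteins=400,
            n_samples_per_cohort={"PPMI": 240},
            plate_sd=0.5,
            blood_contamination_rate=0.0,
            technical_outlier_rate=0.0,
            censor_midpoint=float("-inf"),
            seed=23,
        )
        matrix, meta, *_ = simulate_human_cohorts(config)
        bio = meta.index[~meta.is_pooled_qc]
        mat = matrix.subset_samples(bio)
        plates = meta.loc[bio, "plate"]
        out = batch_adjust(mat, plates)

        def plate_q_fraction(m):
            groups = [m.data.loc[ids].to_numpy() for _, ids in plates.groupby(plates).groups.items()]
            ps = [f_oneway(*[g[:, j] for g in groups]).pvalue for j in range(m.data.shape[1])]
            return float(np.mean(bh_adjust(ps) < 0.05))

        assert plate_q_fraction(mat) > 0.1  # effect clearly present before
        assert plate_q_fraction(out) < 0.01

    def test_zero_sd_batch_falls_back_to_location(self):
        vals = np.vstack([np.full((3, 2), 5.0), np.random.default_rng(12).normal(8, 1, (3, 2))])
        mat = matrix_from(vals)
        batches = pd.Series(["A"] * 3 + ["B"] * 3, index=mat.sample_ids)
        out = batch_adjust(mat, batches)
        assert np.isfinite(out.data.to_numpy()).all()
        assert np.abs(out.data.iloc[:3].mean() - out.data.iloc[3:].mean()).max() < 1e-10

    def test_missing_values_rejected(self):
        vals = np.ones((6, 2))
        vals[0, 0] = np.nan
        mat = matrix_from(vals)
        with pytest.raises(ValueError, match="impute"):
            batch_adjust(mat, pd.Series(["A"] * 3 + ["B"] * 3, index=mat.sample_ids))


class TestPipeline:
    def test_full_pipeline_outputs_clean_matrix(self, recovery_clean):
        clean, clean_meta, _, _, report = recovery_clean
        assert clean.n_missing == 0
        assert set(clean.sample_ids) == set(clean_meta.index)
        assert not clean_meta["is_pooled_qc"].any()
        assert report.median_pooled_cv is not None
        assert len(report.log) >= 3

    def test_pipeline_exclusions_subset_of_samples(self, recovery_sim, recovery_clean):
        _, matrix, *_ = recovery_sim
        _, _, _, _, report = recovery_clean
        assert set(report.excluded) <= set(matrix.sample_ids)

    def test_flagging_idempotent_at_flagging_stage(self, recovery_sim, recovery_clean):
        """Re-running the outlier rule on the samples it kept flags nobody new.

        Checked on the matrix the flagging stage itself saw (pre-imputation):
        imputed values are deliberately down-shifted and would look like
        genuine low outliers to a fresh robust-z pass.
        """
        _, matrix, meta, *_ = recovery_sim
        _, clean_meta, _, _, report = recovery_clean
        survivors = meta.index[~meta.is_pooled_qc].difference(list(report.excluded))
        again = flag_technical_outliers(matrix.subset_samples(survivors), meta.loc[survivors])
        assert again == []
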