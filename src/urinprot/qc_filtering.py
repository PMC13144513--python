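"""Preprocessing and quality control for urinary proteome matrices.

The pipeline order is fixed: log2 transform (if needed) -> blood-contamination
flagging -> technical-outlier flagging -> valid-value filtering -> shifted-
Gaussian imputation -> optional batch adjustment.  ``run_qc_pipeline`` enforces
that order and records every action in a :class:`QcReport`.

Observed values are only ever altered by the log2 transform and the batch
adjustment; flagging and filtering drop whole samples or proteins, and
imputation fills missing cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import robust_z
from .containers import ProteinMatrix
from .synthetic_cohort import DEFAULT_BLOOD_PANEL

__all__ = [
    "ImputeParams",
    "QcReport",
    "log2_transform",
    "pooled_cv",
    "flag_technical_outliers",
    "flag_blood_contamination",
    "filter_valid_values",
    "impute_shifted_gaussian",
    "batch_adjust",
    "run_qc_pipeline",
]

ROBUST_Z_CUTOFF = 3.5  # |robust z| above which a cell counts as an outlier protein


@dataclass
class ImputeParams:
    """Shifted-Gaussian imputation parameters (units: per-sample sd)."""

    shift: float = 3.0
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")


@dataclass
class QcReport:
    """Record of QC metrics and every exclusion/filtering decision."""

    cv_table: pd.DataFrame | None = None  # (protein, plate) -> CV
    median_pooled_cv: float | None = None
    outlier_counts: pd.Series | None = None  # per-sample outlier-protein count
    excluded: dict[str, str] = field(default_factory=dict)  # sample id -> reason
    dropped_proteins: list[str] = field(default_factory=list)
    skipped_proteins: list[str] = field(default_factory=list)  # MAD == 0
    log: list[str] = field(default_factory=list)

    def record(self, message: str) -> None:
        self.log.append(message)

    def exclude(self, sample_ids, reason: str) -> None:
        for sid in sample_ids:
            self.excluded.setdefault(sid, reason)


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """log2-transform a linear-scale matrix; missing entries are preserved."""
    if matrix.scale != "linear":
        raise ValueError("matrix is not on linear scale")
    vals = matrix.data.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at sample {matrix.sample_ids[i]!r}, "
            f"protein {matrix.protein_ids[j]!r}"
        )
    return ProteinMatrix(
        pd.DataFrame(np.log2(vals), index=matrix.sample_ids, columns=matrix.protein_ids),
        scale="log2",
    )


def pooled_cv(matrix: ProteinMatrix, meta: pd.DataFrame) -> QcReport:
    """Per-plate per-protein CV of pooled-QC replicates, on the linear scale.

    CV = sample sd / mean over a plate's pooled replicates.  Proteins with any
    missing pooled value on a plate are skipped for that plate.  The median is
    taken over all retained (protein, plate) CVs.
    """
    pooled_ids = meta.index[meta["is_pooled_qc"].astype(bool)]
    pooled_ids = pooled_ids.intersection(matrix.sample_ids)
    if len(pooled_ids) < 2:
        raise ValueError("need >= 2 pooled-QC samples to compute CVs")
    data = matrix.data.loc[pooled_ids]
    if matrix.scale == "log2":
        data = 2.0**data
    plates = meta.loc[pooled_ids, "plate"]

    records = []
    for plate, ids in plates.groupby(plates).groups.items():
        sub = data.loc[ids]
        if len(sub) < 2:
            continue
        complete = sub.columns[sub.notna().all(axis=0)]
        sub = sub[complete]
        cv = sub.std(axis=0, ddof=1) / sub.mean(axis=0)
        for protein, value in cv.items():
            records.append({"protein": protein, "plate": plate, "cv": value})
    if not records:
        raise ValueError("no plate had >= 2 pooled replicates with complete proteins")
    table = pd.DataFrame(records)
    report = QcReport(cv_table=table, median_pooled_cv=float(table["cv"].median()))
    report.record(
        f"pooled CV over {table['plate'].nunique()} plates: median {report.median_pooled_cv:.3f}"
    )
    return report


def flag_technical_outliers(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    z_cutoff: float = ROBUST_Z_CUTOFF,
    report: QcReport | None = None,
) -> list[str]:
    """Samples with an outlier-protein count above Q3 + 1.5*IQR of their group.

    Per protein, robust z-scores are computed across biological samples; a
    sample's outlier count is the number of proteins with |z| > ``z_cutoff``;
    within each experimental group, samples above the Tukey upper fence of the
    counts are excluded (only the upper tail — a low count is unproblematic).
    The rule is peeled to a fixed point: z-scores, counts and fences are
    recomputed on the survivors until no further sample is excluded, so
    re-running it on its own output never flags anything new.  Proteins with
    zero MAD are skipped and recorded.
    """
    bio = meta.index[~meta["is_pooled_qc"].astype(bool)].intersection(matrix.sample_ids)
    excluded: list[str] = []
    counts = None
    while True:
        data = matrix.data.loc[bio]
        z = robust_z(data.to_numpy(), axis=0)
        if counts is None:  # record zero-MAD proteins once, on the full matrix
            mad_zero = np.isnan(z).all(axis=0) & data.notna().any(axis=0).to_numpy()
            if report is not None and mad_zero.any():
                skipped = list(data.columns[mad_zero])
                report.skipped_proteins.extend(skipped)
                report.record(f"robust z skipped {len(skipped)} zero-MAD proteins")
        new_counts = pd.Series(
            np.nansum(np.abs(z) > z_cutoff, axis=1), index=bio, name="outlier_count"
        )
        if counts is None:
            counts = new_counts
        newly: list[str] = []
        for _, ids in meta.loc[bio].groupby("experimental_group").groups.items():
            grp = new_counts.loc[ids]
            q1, q3 = grp.quantile([0.25, 0.75])
            fence = q3 + 1.5 * (q3 - q1)
            newly.extend(grp.index[grp > fence])
        if not newly:
            break
        excluded.extend(newly)
        bio = bio.difference(newly)
    if report is not None:
        report.outlier_counts = counts
        report.exclude(excluded, "technical")
        report.record(f"technical-outlier rule excluded {len(excluded)} samples")
    return excluded


def flag_blood_contamination(
    matrix: ProteinMatrix,
    panel=DEFAULT_BLOOD_PANEL,
    z_cutoff: float = ROBUST_Z_CUTOFF,
    report: QcReport | None = None,
) -> list[str]:
    """Samples whose mean blood-marker-panel intensity is a robust-z outlier.

    The panel score is the mean log2 intensity over the quantified panel
    proteins; a sample is flagged iff the robust z of its score across samples
    exceeds ``z_cutoff`` (upper tail only: contamination elevates the panel).
    """
    present = [p for p in panel if p in matrix.protein_ids]
    if not present:
        raise ValueError("no blood-panel protein present in the matrix")
    scores = matrix.data[present].mean(axis=1, skipna=True)
    z = robust_z(scores.to_numpy())
    flagged = list(scores.index[np.nan_to_num(z) > z_cutoff])
    if report is not None:
        report.exclude(flagged, "blood")
        report.record(
            f"blood panel ({len(present)} markers) flagged {len(flagged)} samples"
        )
    return flagged


def filter_valid_values(
    matrix: ProteinMatrix,
    groups: dict[str, list],
    min_fraction: float = 0.7,
    report: QcReport | None = None,
) -> ProteinMatrix:
    """Keep proteins quantified in >= ``min_fraction`` of some group's samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    keep = pd.Series(False, index=matrix.protein_ids)
    for name, ids in groups.items():
        ids = pd.Index(ids).intersection(matrix.sample_ids)
        if len(ids) == 0:
            raise ValueError(f"group {name!r} has no samples in the matrix")
        frac = matrix.data.loc[ids].notna().mean(axis=0)
        keep |= frac >= min_fraction
    dropped = list(matrix.protein_ids[~keep])
    if report is not None:
        report.dropped_proteins.extend(dropped)
        report.record(
            f"valid-value filter (>= {min_fraction:.0%} in some group) "
            f"dropped {len(dropped)}/{len(keep)} proteins"
        )
    return ProteinMatrix(matrix.data.loc[:, keep], matrix.scale)


def impute_shifted_gaussian(matrix: ProteinMatrix, params: ImputeParams) -> ProteinMatrix:
    """Fill missing values from a down-shifted narrow Gaussian, per sample.

    For each sample with observed mean mu and sd sigma, missing entries are
    drawn from Normal(mu - shift*sigma, (width*sigma)^2), modelling
    left-censored low-abundance proteins.  Observed values are untouched;
    the draw is reproducible from ``params.seed``.
    """
    if matrix.scale != "log2":
        raise ValueError("imputation expects a log2-scale matrix")
    rng = np.random.default_rng(params.seed)
    vals = matrix.data.to_numpy(dtype=float).copy()
    n_obs = (~np.isnan(vals)).sum(axis=1)
    too_few = n_obs < 2
    if too_few.any():
        bad = list(matrix.sample_ids[too_few])
        raise ValueError(f"samples with < 2 observed values cannot be imputed: {bad}")
    for i in range(vals.shape[0]):
        missing = np.isnan(vals[i])
        if not missing.any():
            continue
        obs = vals[i][~missing]
        mu, sigma = obs.mean(), obs.std(ddof=1)
        vals[i, missing] = rng.normal(
            mu - params.shift * sigma, params.width * sigma, missing.sum()
        )
    return ProteinMatrix(
        pd.DataFrame(vals, index=matrix.sample_ids, columns=matrix.protein_ids), matrix.scale
    )


def batch_adjust(
    matrix: ProteinMatrix, batches: pd.Series, report: QcReport | None = None
) -> ProteinMatrix:
    """Location/scale batch adjustment per protein.

    Within each batch the protein is standardized (batch mean/sd removed) and
    then mapped back onto the protein's grand mean and pooled sd, so that
    post-adjustment batch means coincide.  A zero batch sd degenerates to a
    location-only shift for that protein/batch (recorded).
    """
    if matrix.n_missing:
        raise ValueError("batch adjustment requires a fully observed matrix (impute first)")
    batches = batches.loc[matrix.sample_ids]
    levels = batches.unique()
    if len(levels) < 2:
        if report is not None:
            report.record("batch adjustment skipped: single batch")
        return matrix.copy()
    sizes = batches.value_counts()
    if (sizes < 3).any():
        small = list(sizes.index[sizes < 3])
        raise ValueError(f"batches with < 3 samples: {small}")

    vals = matrix.data.to_numpy(dtype=float).copy()
    grand_mean = vals.mean(axis=0)
    grand_sd = vals.std(axis=0, ddof=1)
    n_location_only = 0
    for level in levels:
        idx = (batches == level).to_numpy()
        m = vals[idx].mean(axis=0)
        s = vals[idx].std(axis=0, ddof=1)
        zero = s == 0
        n_location_only += int(zero.sum())
        s_safe = np.where(zero, 1.0, s)
        scale = np.where(zero, 1.0, grand_sd / s_safe)
        vals[idx] = (vals[idx] - m) * scale + grand_mean
    if report is not None:
        report.record(
            f"batch adjustment over {len(levels)} batches"
            + (f" ({n_location_only} location-only protein/batch cells)" if n_location_only else "")
        )
    return ProteinMatrix(
        pd.DataFrame(vals, index=matrix.sample_ids, columns=matrix.protein_ids), matrix.scale
    )


def run_qc_pipeline(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    blood_panel=DEFAULT_BLOOD_PANEL,
    min_valid_fraction: float = 0.7,
    impute_params: ImputeParams | None = None,
    do_batch_adjust: bool = False,
    group_column: str = "experimental_group",
) -> tuple[ProteinMatrix, pd.DataFrame, QcReport]:
    """Run the full fixed-order QC pipeline on a cohort matrix.

    Returns the cleaned, imputed (and optionally batch-adjusted) matrix of
    biological samples, the matching metadata, and the QC report.
    """
    report = QcReport()
    if matrix.scale == "linear":
        matrix = log2_transform(matrix)
        report.record("log2 transform applied")

    try:
        cv_report = pooled_cv(matrix, meta)
        report.cv_table = cv_report.cv_table
        report.median_pooled_cv = cv_report.median_pooled_cv
        report.log.extend(cv_report.log)
    except ValueError:
        report.record("pooled CV skipped: no pooled-QC replicates")

    bio = meta.index[~meta["is_pooled_qc"].astype(bool)].intersection(matrix.sample_ids)
    work = matrix.subset_samples(bio)
    work_meta = meta.loc[bio]

    blood = flag_blood_contamination(work, blood_panel, report=report)
    keep = work.sample_ids.difference(blood)
    work, work_meta = work.subset_samples(keep), work_meta.loc[keep]

    technical = flag_technical_outliers(work, work_meta, report=report)
    keep = work.sample_ids.difference(technical)
    work, work_meta = work.subset_samples(keep), work_meta.loc[keep]

    groups = {
        str(g): list(ids) for g, ids in work_meta.groupby(group_column).groups.items()
    }
    work = filter_valid_values(work, groups, min_valid_fraction, report=report)

    work = impute_shifted_gaussian(work, impute_params or ImputeParams())
    report.record("shifted-Gaussian imputation applied")

    if do_batch_adjust:
        work = batch_adjust(work, work_meta["plate"], report=report)
    return work, work_meta, report
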