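"""Genotype-proteome association mapping.

For every protein, an ordinary least-squares multiple regression of log2
intensity on standardized covariates (age, sex, and variant or locus dosages)
yields per-covariate coefficients, standard errors and two-sided t-test
p values; Benjamini-Hochberg q values are computed across proteins separately
within each covariate family.  Downstream helpers compare beta profiles
between variants, normalize betas for direction plots, take significant sets
and their cross-cohort Venn regions, and correlate proteins with clinical
severity scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .containers import GenotypeTable, ProteinMatrix

__all__ = [
    "AssociationResult",
    "aggregate_locus_dosage",
    "fit_protein_regressions",
    "bh_adjust",
    "beta_profile_correlation",
    "normalize_betas",
    "significant_set",
    "cross_cohort_venn",
    "severity_correlation",
]


@dataclass
class AssociationResult:
    """Long-format per-(protein, covariate) regression statistics.

    ``table`` columns: protein, covariate, beta (log2 units per standardized
    covariate unit), se, t, p, q, n, covariate_sd (the raw covariate's sd, so
    beta/covariate_sd is the effect per natural unit).
    """

    table: pd.DataFrame
    skipped: dict[str, str]

    def covariate_frame(self, covariate: str) -> pd.DataFrame:
        sub = self.table[self.table["covariate"] == covariate]
        return sub.set_index("protein")


def aggregate_locus_dosage(genotypes: GenotypeTable) -> GenotypeTable:
    """Sum variant dosages within each gene locus (0/1/2 encoding summed)."""
    loci = genotypes.loci
    data = {
        locus: genotypes.dosages[
            [v for v in genotypes.variant_ids if genotypes.variant_to_locus[v] == locus]
        ].sum(axis=1)
        for locus in loci
    }
    return GenotypeTable(
        pd.DataFrame(data, index=genotypes.dosages.index),
        variant_to_locus={locus: locus for locus in loci},
    )


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Column-standardize; constant columns are reported, not scaled."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = [j for j in range(X.shape[1]) if sd[j] == 0]
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd_safe, sd, constant


def fit_protein_regressions(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    genotypes: GenotypeTable | None = None,
    confounders: tuple[str, ...] = ("age", "sex"),
) -> AssociationResult:
    """Per-protein OLS of intensity on standardized confounders and dosages.

    Complete-case per protein when the matrix still carries missing values;
    after imputation the design is shared and the fit is vectorized.  Constant
    covariates are dropped (logged); rank-deficient designs skip the protein.
    """
    samples = matrix.sample_ids
    cov_frames = []
    if "age" in confounders:
        cov_frames.append(meta.loc[samples, "age"].astype(float).rename("age"))
    if "sex" in confounders:
        sex = meta.loc[samples, "sex"]
        cov_frames.append(sex.map({"F": 0.0, "M": 1.0}).astype(float).rename("sex"))
    for c in confounders:
        if c not in ("age", "sex"):
            cov_frames.append(meta.loc[samples, c].astype(float).rename(c))
    if genotypes is not None:
        dos = genotypes.dosages.reindex(samples)
        if dos.isna().any().any():
            missing = list(samples[dos.isna().any(axis=1)][:3])
            raise ValueError(f"samples without genotypes: {missing}...")
        for v in genotypes.variant_ids:
            cov_frames.append(dos[v].astype(float))
    if not cov_frames:
        raise ValueError("no covariates specified")
    design = pd.concat(cov_frames, axis=1)
    covariates = list(design.columns)

    skipped: dict[str, str] = {}
    Y = matrix.data.to_numpy(dtype=float)
    n_total, n_prot = Y.shape
    Xraw = design.to_numpy(dtype=float)

    records = []

    def _fit_block(X: np.ndarray, y_block: np.ndarray, proteins: list[str]) -> None:
        Z, sds, constant = _standardize(X)
        keep = [j for j in range(Z.shape[1]) if j not in constant]
        for j in constant:
            skipped.setdefault(f"covariate:{covariates[j]}", "constant covariate dropped")
        names = [covariates[j] for j in keep]
        Zk = np.column_stack([np.ones(len(Z))] + [Z[:, j] for j in keep])
        n, p = Zk.shape
        if n < p + 10:
            for prot in proteins:
                skipped[prot] = f"too few samples ({n}) for {p} parameters + 10"
            return
        XtX = Zk.T @ Zk
        if np.linalg.matrix_rank(XtX) < p:
            for prot in proteins:
                skipped[prot] = "rank-deficient design"
            return
        XtX_inv = np.linalg.inv(XtX)
        B = XtX_inv @ Zk.T @ y_block  # (p, n_prot_block)
        resid = y_block - Zk @ B
        dof = n - p
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = B / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        for b_idx, name in enumerate(names, start=1):
            sd_raw = sds[covariates.index(name)]
            for k, prot in enumerate(proteins):
                records.append(
                    {
                        "protein": prot,
                        "covariate": name,
                        "beta": B[b_idx, k],
                        "se": se[b_idx, k],
                        "t": tvals[b_idx, k],
                        "p": pvals[b_idx, k],
                        "n": n,
                        "covariate_sd": sd_raw,
                    }
                )

    fully_observed = not np.isnan(Y).any() and not np.isnan(Xraw).any()
    if fully_observed:
        _fit_block(Xraw, Y, list(matrix.protein_ids))
    else:
        for k, prot in enumerate(matrix.protein_ids):
            mask = ~np.isnan(Y[:, k]) & ~np.isnan(Xraw).any(axis=1)
            _fit_block(Xraw[mask], Y[mask, k][:, None], [prot])

    table = pd.DataFrame.from_records(records)
    if len(table):
        table["q"] = np.nan
        for cov in table["covariate"].unique():
            m = table["covariate"] == cov
            table.loc[m, "q"] = bh_adjust(table.loc[m, "p"].to_numpy())
    return AssociationResult(table=table, skipped=skipped)


@dataclass
class BetaProfileComparison:
    covariate_a: str
    covariate_b: str
    r: float
    p: float
    q: float
    n_proteins: int


def beta_profile_correlation(
    assoc: AssociationResult, pairs: list[tuple[str, str]]
) -> list[BetaProfileComparison]:
    """Pearson correlation of two covariates' beta profiles over shared proteins.

    One comparison per requested pair; p from the correlation t-test, q by
    BH across the requested pairs.
    """
    results = []
    for cov_a, cov_b in pairs:
        a = assoc.covariate_frame(cov_a)["beta"]
        b = assoc.covariate_frame(cov_b)["beta"]
        shared = a.index.intersection(b.index)
        if len(shared) < 10:
            raise ValueError(
                f"only {len(shared)} shared proteins for ({cov_a}, {cov_b}); need >= 10"
            )
        r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
        results.append(
            BetaProfileComparison(cov_a, cov_b, float(r), float(p), np.nan, len(shared))
        )
    qs = bh_adjust([res.p for res in results])
    for res, q in zip(results, qs):
        res.q = float(q)
    return results


def normalize_betas(assoc: AssociationResult, covariate: str) -> pd.Series:
    """Betas divided by the maximum absolute beta within the covariate.

    Output lies in [-1, 1] and preserves every beta's sign.
    """
    betas = assoc.covariate_frame(covariate)["beta"]
    finite = betas.dropna()
    if finite.empty:
        raise ValueError(f"no finite betas for covariate {covariate!r}")
    max_abs = finite.abs().max()
    if max_abs == 0:
        raise ValueError(f"all betas are zero for covariate {covariate!r}")
    return betas / max_abs


def significant_set(
    assoc: AssociationResult, covariate: str, q_threshold: float = 0.05
) -> set[str]:
    """Proteins with q < threshold for the given covariate."""
    frame = assoc.covariate_frame(covariate)
    return set(frame.index[frame["q"] < q_threshold])


def cross_cohort_venn(sets: dict[str, set]) -> dict[str, int]:
    """Exact Venn region cardinalities for 2-3 sets plus the 'in >= 2 sets' count.

    Region keys are '&'-joined sorted member names (elements in exactly those
    sets); ``__any2__`` counts elements present in at least two sets.
    """
    names = sorted(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("Venn regions are defined for 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set(universe)
            for m in members:
                inside &= sets[m]
            for other in names:
                if other not in members:
                    inside -= sets[other]
            regions["&".join(members)] = len(inside)
    regions["__any2__"] = len(
        {x for x in universe if sum(x in sets[n] for n in names) >= 2}
    )
    return regions


def severity_correlation(
    matrix: ProteinMatrix,
    scores: pd.Series,
    subgroup: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-protein Pearson correlation with a clinical severity score.

    Computed within the subgroup (e.g. mutation carriers with PD) over samples
    where both the protein and the score are observed; BH across proteins.
    """
    ids = matrix.sample_ids if subgroup is None else pd.Index(subgroup)
    ids = ids.intersection(scores.dropna().index)
    data = matrix.data.loc[ids]
    s = scores.loc[ids].astype(float)
    if s.nunique() <= 1:
        raise ValueError("severity score is constant in the subgroup")
    records = []
    for prot in data.columns:
        x = data[prot].dropna()
        common = x.index.intersection(s.index)
        if len(common) < 10:
            records.append({"protein": prot, "r": np.nan, "p": np.nan, "n": len(common)})
            continue
        r, p = stats.pearsonr(x.loc[common], s.loc[common])
        records.append({"protein": prot, "r": float(r), "p": float(p), "n": len(common)})
    out = pd.DataFrame.from_records(records).set_index("protein")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
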