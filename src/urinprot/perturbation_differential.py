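"""Perturbation-arm differential statistics and cross-species transfer.

Per-protein two-group contrasts use the unpaired two-tailed Student
(pooled-variance) t-test with BH correction within each contrast; downstream
helpers correlate fold-change vectors between contrasts, extract the
consensus signature (significant in every contrast), map a human protein set
onto rat homologs, and compare regulatory direction after normalizing each
vector by its maximum absolute entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .containers import ProteinMatrix

__all__ = [
    "Contrast",
    "DifferentialResult",
    "OrthologMap",
    "run_contrast",
    "contrast_correlation",
    "consensus_signature",
    "map_orthologs",
    "normalized_direction_compare",
    "normalize_vector",
    "case_normalize_match",
]


@dataclass
class Contrast:
    name: str
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError(f"contrast {self.name!r}: case and control overlap")
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError(f"contrast {self.name!r}: each side needs >= 2 samples")


@dataclass
class DifferentialResult:
    """Per-protein statistics for one contrast.

    ``table`` columns: log2fc (case mean - control mean), t, p, q, n_case,
    n_ctrl, degenerate (zero pooled variance with unequal means).
    """

    contrast: str
    table: pd.DataFrame

    def significant(self, threshold: float = 0.05, adjusted: bool = False) -> set[str]:
        col = "q" if adjusted else "p"
        sub = self.table[self.table[col] < threshold]
        return set(sub.index)


@dataclass
class OrthologMap:
    """One-to-one human <-> rat protein id pairs."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        humans = [h for h, _ in self.pairs]
        rats = [r for _, r in self.pairs]
        dup_h = {h for h in humans if humans.count(h) > 1}
        dup_r = {r for r in rats if rats.count(r) > 1}
        if dup_h or dup_r:
            raise ValueError(
                f"ambiguous many-to-many mapping: human {sorted(dup_h)}, rat {sorted(dup_r)}"
            )
        self.human_to_rat = dict(self.pairs)
        self.rat_to_human = {r: h for h, r in self.pairs}


def run_contrast(matrix: ProteinMatrix, contrast: Contrast) -> DifferentialResult:
    """Equal-variance two-sample t-test per protein with BH correction.

    Requires a fully observed (post-QC, imputed) matrix on the contrast's
    samples.  Zero pooled variance gives p = 1 when the means coincide and a
    degenerate flag otherwise.
    """
    case = matrix.data.loc[contrast.case_ids]
    ctrl = matrix.data.loc[contrast.control_ids]
    if case.isna().any().any() or ctrl.isna().any().any():
        raise ValueError("contrast requires an imputed (fully observed) matrix")
    a, b = case.to_numpy(dtype=float), ctrl.to_numpy(dtype=float)
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    degenerate = (pooled == 0) & (m1 != m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(np.abs(t), n1 + n2 - 2)
    zero_equal = (pooled == 0) & (m1 == m2)
    t = np.where(zero_equal, 0.0, t)
    p = np.where(zero_equal, 1.0, p)
    p = np.where(degenerate, np.nan, p)
    table = pd.DataFrame(
        {
            "log2fc": m1 - m2,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "n_case": n1,
            "n_ctrl": n2,
            "degenerate": degenerate,
        },
        index=matrix.protein_ids,
    )
    return DifferentialResult(contrast.name, table)


def contrast_correlation(
    result_a: DifferentialResult,
    result_b: DifferentialResult,
    scope: str = "all",
    threshold: float = 0.05,
) -> tuple[float, float, int]:
    """Pearson r of two contrasts' log2 fold-change vectors.

    ``scope`` = 'all' uses every shared protein; 'significant' restricts to
    proteins with p < ``threshold`` in both contrasts.  Returns (r, p, n).
    """
    shared = result_a.table.index.intersection(result_b.table.index)
    if scope == "significant":
        sig = result_a.significant(threshold) & result_b.significant(threshold)
        shared = shared.intersection(sig)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared proteins; need >= 10")
    r, p = stats.pearsonr(
        result_a.table.loc[shared, "log2fc"], result_b.table.loc[shared, "log2fc"]
    )
    return float(r), float(p), len(shared)


def consensus_signature(
    results: list[DifferentialResult],
    p_threshold: float = 0.05,
    adjusted: bool = False,
) -> dict:
    """Set algebra over per-contrast significant sets.

    Returns the all-contrast intersection (the consensus signature), the
    any-contrast union, and per-membership-pattern region counts.
    """
    if not results:
        raise ValueError("need >= 1 contrast")
    sig = {res.contrast: res.significant(p_threshold, adjusted) for res in results}
    names = list(sig)
    consensus = set.intersection(*sig.values())
    union = set.union(*sig.values())
    regions: dict[str, int] = {}
    for prot in union:
        pattern = "&".join(n for n in names if prot in sig[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    return {
        "per_contrast": sig,
        "consensus": consensus,
        "union": union,
        "region_counts": regions,
    }


def map_orthologs(
    human_set: set[str],
    rat_result: DifferentialResult,
    mapping: OrthologMap,
    p_threshold: float = 0.05,
    adjusted: bool = False,
) -> dict:
    """Transfer a human protein set onto rat homologs and test for overlap.

    Reports the human proteins whose rat homolog is detected in the rat
    results, the subset whose homolog is significant in the contrast, and the
    ids left unmapped by the table.
    """
    detected_rat = set(rat_result.table.index)
    significant_rat = rat_result.significant(p_threshold, adjusted)
    detected, significant, unmapped = [], [], []
    for h in sorted(human_set):
        r = mapping.human_to_rat.get(h)
        if r is None:
            unmapped.append(h)
        elif r in detected_rat:
            detected.append(h)
            if r in significant_rat:
                significant.append(h)
    return {
        "n_query": len(human_set),
        "detected": detected,
        "n_detected": len(detected),
        "significant": significant,
        "n_significant": len(significant),
        "unmapped": unmapped,
    }


def normalize_vector(values: pd.Series) -> pd.Series:
    """Divide by the maximum absolute entry; sign-preserving, idempotent."""
    max_abs = values.abs().max()
    if not np.isfinite(max_abs) or max_abs == 0:
        raise ValueError("cannot normalize an all-zero (or all-NaN) vector")
    return values / max_abs


def normalized_direction_compare(
    human_betas: pd.Series,
    rat_results: list[DifferentialResult],
    mapping: OrthologMap,
    panel: list[str],
) -> pd.DataFrame:
    """Compare regulatory direction of a shared panel across species.

    Human betas and each contrast's rat fold-changes are normalized by their
    maximum absolute value; per (protein, contrast), the table holds both
    normalized values and a sign-concordance flag, with the per-contrast
    concordant fraction in ``DataFrame.attrs['concordance']``.
    """
    if not panel:
        raise ValueError("shared panel is empty")
    rows = []
    human_norm = normalize_vector(human_betas.loc[panel])
    for res in rat_results:
        rat_ids = [mapping.human_to_rat.get(h) for h in panel]
        missing = [h for h, r in zip(panel, rat_ids) if r is None or r not in res.table.index]
        if missing:
            raise ValueError(f"panel proteins without detected rat homolog: {missing}")
        rat_fc = pd.Series(
            res.table.loc[rat_ids, "log2fc"].to_numpy(), index=panel
        )
        rat_norm = normalize_vector(rat_fc)
        for h in panel:
            rows.append(
                {
                    "protein": h,
                    "contrast": res.contrast,
                    "human_normalized": float(human_norm[h]),
                    "rat_normalized": float(rat_norm[h]),
                    "concordant": bool(np.sign(human_norm[h]) == np.sign(rat_norm[h])),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["concordance"] = (
        out.groupby("contrast")["concordant"].mean().to_dict()
    )
    return out


def case_normalize_match(human_ids, rat_ids) -> OrthologMap:
    """Heuristic symbol matcher: pairs ids equal up to letter case (HEXB~Hexb).

    Convenience only — a curated mapping table should be preferred; ambiguous
    multi-matches raise.
    """
    rat_by_lower: dict[str, list[str]] = {}
    for r in rat_ids:
        rat_by_lower.setdefault(str(r).lower(), []).append(str(r))
    pairs = []
    for h in human_ids:
        hits = rat_by_lower.get(str(h).lower(), [])
        if len(hits) > 1:
            raise ValueError(f"ambiguous case-insensitive match for {h!r}: {hits}")
        if hits:
            pairs.append((str(h), hits[0]))
    return OrthologMap(pairs)
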