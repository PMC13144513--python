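"""Core in-memory containers shared across the pipeline.

Intensity data travel as a :class:`ProteinMatrix` (samples x proteins,
log2 or linear scale), sample annotations as a plain :class:`pandas.DataFrame`
(one row per sample), and genotype dosages as a :class:`GenotypeTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ProteinMatrix", "GenotypeTable", "META_COLUMNS"]

#: canonical sample-metadata columns produced by the simulator and expected
#: by the QC / association stages (extra columns are carried through untouched)
META_COLUMNS = [
    "sample_id",
    "cohort",
    "diagnosis",
    "age",
    "sex",
    "plate",
    "is_pooled_qc",
    "mutation_label",
    "experimental_group",
]


@dataclass
class ProteinMatrix:
    """Sample x protein intensity table.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with protein ids as columns.  Missing
        entries are NaN; every stored (non-missing) value must be finite.
    scale
        ``"linear"`` (raw intensities, all positive) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicated sample ids in ProteinMatrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicated protein ids in ProteinMatrix")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("non-finite (inf) values in ProteinMatrix")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "ProteinMatrix":
        return ProteinMatrix(self.data.loc[list(sample_ids)], self.scale)

    def subset_proteins(self, protein_ids) -> "ProteinMatrix":
        return ProteinMatrix(self.data[list(protein_ids)], self.scale)

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.data.copy(), self.scale)


@dataclass
class GenotypeTable:
    """Per-sample variant dosages plus the variant -> locus mapping.

    ``dosages`` is indexed by sample id with variant ids as columns, entries
    in {0, 1, 2} (a locus-aggregated table may exceed 2).  ``variant_to_locus``
    maps every variant column to exactly one locus id.
    """

    dosages: pd.DataFrame
    variant_to_locus: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unmapped = [v for v in self.dosages.columns if v not in self.variant_to_locus]
        if unmapped:
            raise ValueError(f"variants without a locus mapping: {unmapped}")
        vals = self.dosages.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("missing dosage values are not supported")
        if (vals < 0).any():
            raise ValueError("negative dosages")

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def loci(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.dosages.columns:
            seen.setdefault(self.variant_to_locus[v], None)
        return list(seen)
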