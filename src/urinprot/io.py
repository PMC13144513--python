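"""Tab-delimited readers/writers for the pipeline's tables.

All on-disk formats are plain TSV with a header row and the sample id in the
first column (protein id for protein-keyed tables).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import GenotypeTable, ProteinMatrix

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_meta",
    "read_meta",
    "write_genotypes",
    "read_genotypes",
    "write_table",
    "read_table",
]


def write_matrix(matrix: ProteinMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path, scale: str = "log2") -> ProteinMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return ProteinMatrix(data, scale=scale)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    return meta.set_index("sample_id", drop=False)


def write_genotypes(genotypes: GenotypeTable, dosage_path, locus_map_path) -> None:
    genotypes.dosages.to_csv(dosage_path, sep="\t", index_label="sample_id")
    pd.DataFrame(
        {"variant_id": list(genotypes.variant_to_locus),
         "locus_id": list(genotypes.variant_to_locus.values())}
    ).to_csv(locus_map_path, sep="\t", index=False)


def read_genotypes(dosage_path, locus_map_path) -> GenotypeTable:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    lm = pd.read_csv(locus_map_path, sep="\t")
    return GenotypeTable(dosages, dict(zip(lm["variant_id"], lm["locus_id"])))


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
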