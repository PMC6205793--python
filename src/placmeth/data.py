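"""Core data containers: beta-value matrices, sample sheets, probe annotation.

Methylation at a CpG site is summarised as a beta value, the fraction of
methylated signal, constrained to [0, 1].  A study is a CpG-by-sample beta
matrix plus a sample sheet of phenotype and technical covariates (tissue,
case status, gestational age, fetal sex, ancestry coordinates, chip and chip
row) and an optional per-CpG annotation table (position, gene, quality
flags).  All three are thin, validated wrappers around pandas DataFrames so
that downstream code can rely on aligned, unique identifiers and in-range
values without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUES = ("chorionic_villi", "chorion", "amnion")
IMMUNE_CELL_TYPES = ("neutrophil", "eosinophil", "monocyte", "lymphoid")

#: required sample-sheet columns and the validation applied to each
SHEET_COLUMNS = (
    "sample_id",
    "tissue",
    "aca_status",
    "ga_weeks",
    "fetal_sex",
    "chip_id",
    "chip_row",
)


class DataError(ValueError):
    """Raised when an input violates the data model (dims, ids, ranges)."""


@dataclass
class BetaMatrix:
    """CpG-by-sample matrix of beta values in [0, 1], NaN marking missing.

    Parameters
    ----------
    frame
        DataFrame with CpG ids as the index and sample ids as the columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise DataError(f"duplicate CpG id: {dup!r}")
        if f.columns.has_duplicates:
            dup = f.columns[f.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        vals = f.to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise DataError(
                f"beta value {vals[i, j]!r} out of [0, 1] at CpG "
                f"{f.index[i]!r}, sample {f.columns[j]!r}"
            )
        f = f.astype(float)
        f.index.name = "cpg_id"
        f.columns.name = None
        self.frame = f

    # -- accessors ---------------------------------------------------------
    @property
    def cpg_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.columns

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean CpG-by-sample array, True where the value is missing."""
        return self.frame.isna().to_numpy()

    @property
    def n_cpg(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    # -- manipulation ------------------------------------------------------
    def select_cpgs(self, cpg_ids: Iterable[str]) -> "BetaMatrix":
        ids = pd.Index(cpg_ids)
        missing = ids.difference(self.frame.index)
        if len(missing):
            raise DataError(f"unknown CpG id(s): {list(missing[:5])}")
        return BetaMatrix(self.frame.loc[ids])

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.frame.columns)
        if len(missing):
            raise DataError(f"unknown sample id(s): {list(missing[:5])}")
        return BetaMatrix(self.frame.loc[:, ids])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="cpg_id", na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "BetaMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        return cls(frame)


@dataclass
class SampleSheet:
    """Per-sample phenotype and technical covariates.

    Required columns: ``sample_id``, ``tissue``, ``aca_status`` ("aCA",
    "non-aCA" or NA), ``ga_weeks``, ``fetal_sex`` ("M"/"F"), ``chip_id``,
    ``chip_row``.  Optional: ``replicate_group``, ``individual_id``, and any
    number of ``ancestry_coord_*`` columns (ancestry MDS coordinates).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame.reset_index(drop=True)
        for col in SHEET_COLUMNS:
            if col not in f.columns:
                raise DataError(f"sample sheet missing required column {col!r}")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataError(f"duplicate sample_id in sheet: {dup!r}")
        ga = pd.to_numeric(f["ga_weeks"], errors="coerce")
        if (ga.dropna() <= 0).any():
            raise DataError("ga_weeks must be > 0 when present")
        self.frame = f

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    @property
    def ancestry_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("ancestry_coord_")]

    def subset(self, mask) -> "SampleSheet":
        return SampleSheet(self.frame.loc[np.asarray(mask)].reset_index(drop=True))

    def aligned_to(self, matrix) -> "SampleSheet":
        """Reorder rows to the matrix column order; error on mismatch.

        ``matrix`` may be a BetaMatrix, a DataFrame (columns = samples) or a
        plain sequence of sample ids.
        """
        if isinstance(matrix, BetaMatrix):
            ids = list(matrix.sample_ids)
        elif isinstance(matrix, pd.DataFrame):
            ids = list(matrix.columns)
        else:
            ids = list(matrix)
        sheet_ids = set(self.frame["sample_id"])
        mat_ids = set(ids)
        only_sheet = sheet_ids - mat_ids
        only_mat = mat_ids - sheet_ids
        if only_sheet or only_mat:
            raise DataError(
                "sample sheet / matrix mismatch; only in sheet: "
                f"{sorted(only_sheet)[:5]}, only in matrix: {sorted(only_mat)[:5]}"
            )
        order = self.frame.set_index("sample_id").loc[ids]
        return SampleSheet(order.reset_index())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path))


@dataclass
class ProbeAnnotation:
    """Per-CpG annotation: genomic position (1-based), genes, quality flags."""

    frame: pd.DataFrame

    FLAG_COLUMNS = ("cross_reactive", "polymorphic", "sex_chromosome")

    def __post_init__(self) -> None:
        f = self.frame.reset_index(drop=True)
        if "cpg_id" not in f.columns:
            raise DataError("annotation missing 'cpg_id' column")
        if f["cpg_id"].duplicated().any():
            dup = f.loc[f["cpg_id"].duplicated(), "cpg_id"].iloc[0]
            raise DataError(f"duplicate cpg_id in annotation: {dup!r}")
        if "position" in f.columns:
            pos = pd.to_numeric(f["position"], errors="coerce")
            if (pos.dropna() < 1).any():
                raise DataError("positions are 1-based and must be >= 1")
        for col in self.FLAG_COLUMNS:
            if col not in f.columns:
                f[col] = False
            f[col] = f[col].astype(bool)
        self.frame = f

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index(self.frame["cpg_id"])

    def flagged(self, flag: str) -> pd.Index:
        if flag not in self.FLAG_COLUMNS:
            raise DataError(f"unknown flag {flag!r}")
        return pd.Index(self.frame.loc[self.frame[flag], "cpg_id"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, sep="\t"))
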