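"""Typed containers for methylation/expression matrices, sample annotations and
QMSP measurement tables, with tab-delimited readers/writers and validation.

All on-disk formats are plain TSV, UTF-8, Unix newlines, '.' decimal separator.
Missing values are written as empty cells and read back as NaN — never as 0,
because a level of exactly 0 is semantically meaningful downstream (QMSP calls
dichotomize at zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HPV_POSITIVE_COPY_THRESHOLD = 1.0


class Group(str, Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Specimen(str, Enum):
    TISSUE = "tissue"
    SALIVA = "saliva"


class HpvStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


@dataclass
class SampleAnnotation:
    """Per-sample annotation table.

    Columns: sample_id, patient_id, group, specimen, and optionally
    hpv_copy_number / hpv_status. sample_id is unique; tissue/saliva pairing
    is by patient_id.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "group", "specimen")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"annotation missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        bad_group = set(df["group"]) - {g.value for g in Group}
        if bad_group:
            raise ValidationError(f"unknown group label(s): {sorted(bad_group)}")
        bad_spec = set(df["specimen"]) - {s.value for s in Specimen}
        if bad_spec:
            raise ValidationError(f"unknown specimen label(s): {sorted(bad_spec)}")
        if "hpv_copy_number" not in df.columns:
            df["hpv_copy_number"] = np.nan
        df["hpv_copy_number"] = pd.to_numeric(df["hpv_copy_number"], errors="coerce")
        if (df["hpv_copy_number"].dropna() < 0).any():
            raise ValidationError("hpv_copy_number must be nonnegative")
        if "hpv_status" not in df.columns:
            df["hpv_status"] = HpvStatus.UNKNOWN.value
        df["hpv_status"] = df["hpv_status"].fillna(HpvStatus.UNKNOWN.value)
        # fill/verify status from copy number where available
        have_cn = df["hpv_copy_number"].notna()
        derived = np.where(
            df.loc[have_cn, "hpv_copy_number"] >= HPV_POSITIVE_COPY_THRESHOLD,
            HpvStatus.POSITIVE.value,
            HpvStatus.NEGATIVE.value,
        )
        stated = df.loc[have_cn, "hpv_status"].to_numpy()
        known = stated != HpvStatus.UNKNOWN.value
        if (stated[known] != derived[known]).any():
            raise ValidationError(
                "hpv_status inconsistent with hpv_copy_number (>=1 copy/genome/cell => positive)"
            )
        df.loc[have_cn, "hpv_status"] = derived
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_in_group(self, group: Union[str, Group]) -> list[str]:
        g = Group(group).value
        return self.table.loc[self.table["group"] == g, "sample_id"].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return SampleAnnotation(keep.copy())


@dataclass
class Matrix:
    """Feature x sample matrix backed by a pandas DataFrame (rows=features)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature id(s): {dups}")
        self.values = self.values.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MethylationMatrix(Matrix):
    """Gene- or probe-level beta values in [0, 1]; NaN marks missing."""

    level: str = "gene"  # "probe" or "gene"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.level not in ("probe", "gene"):
            raise ValidationError(f"unknown matrix level {self.level!r}")
        arr = self.values.to_numpy()
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta values must lie in [0, 1]")


@dataclass
class ExpressionMatrix(Matrix):
    """Normalized (log-scale) expression; all values must be finite or missing."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValidationError("expression values must be finite")


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene mapping."""

    mapping: Mapping[str, str]

    def gene_for(self, probe_id: str) -> str:
        try:
            return self.mapping[probe_id]
        except KeyError:
            raise ValidationError(f"probe {probe_id!r} has no gene mapping") from None

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    @classmethod
    def read(cls, path: Union[str, Path]) -> "ProbeGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("probe map needs two columns: probe_id, gene_id")
        probes, genes = df.iloc[:, 0], df.iloc[:, 1]
        if probes.duplicated().any():
            raise ValidationError("probe map is not many-to-one: duplicate probe ids")
        return cls(dict(zip(probes, genes)))

    def write(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"probe_id": list(self.mapping), "gene_id": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class QmspTable:
    """Long-format QMSP measurements, one row per (sample_id, gene).

    Carries Ct values (NaN = undetermined / no amplification) and, once
    quantified through a standard curve, interpolated quantities.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "gene", "ct_target", "ct_actin")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"QMSP table missing required column {col!r}")
        if df.duplicated(subset=["sample_id", "gene"]).any():
            raise ValidationError("duplicate (sample_id, gene) rows in QMSP table")
        for col in ("ct_target", "ct_actin", "quantity_target", "quantity_actin"):
            if col in df.columns:
                df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("quantity_target", "quantity_actin"):
            if col in df.columns and (df[col].dropna() < 0).any():
                raise ValidationError(f"{col} must be nonnegative")
        self.table = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(
    path: Union[str, Path], kind: str, level: str = "gene"
) -> Union[MethylationMatrix, ExpressionMatrix]:
    """Read a feature x sample TSV (first row sample ids, first column feature ids).

    Empty cells and "NA" become NaN (missing), never 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    if df.columns.duplicated().any():
        raise ValidationError("malformed header: duplicate sample ids")
    if df.shape[1] == 0:
        raise ValidationError("malformed header: no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if kind == "methylation":
        return MethylationMatrix(df, level=level)
    if kind == "expression":
        return ExpressionMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: Matrix, path: Union[str, Path]) -> None:
    matrix.values.to_csv(
        path, sep="\t", na_rep="", index_label="feature_id", lineterminator="\n"
    )


def read_annotation(path: Union[str, Path]) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path: Union[str, Path]) -> None:
    annotation.table.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")


def read_qmsp(path: Union[str, Path]) -> QmspTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene": str})
    return QmspTable(df)


def write_qmsp(qmsp: QmspTable, path: Union[str, Path]) -> None:
    qmsp.table.to_csv(path, sep="\t", index=False, na_rep="", lineterminator="\n")


def align_samples(
    matrix: Matrix,
    annotation: SampleAnnotation,
    group_filter: Optional[Union[str, Group]] = None,
) -> tuple[Matrix, list[str]]:
    """Restrict and order matrix columns to annotated samples.

    Returns the aligned matrix and the ordered sample-id mapping used.
    Column order follows annotation order. Raises on empty intersection.
    """
    wanted = (
        annotation.samples_in_group(group_filter)
        if group_filter is not None
        else annotation.sample_ids
    )
    present = [s for s in wanted if s in matrix.values.columns]
    if not present:
        raise ValidationError("no overlap between matrix columns and annotation")
    sub = matrix.values.loc[:, present]
    if isinstance(matrix, MethylationMatrix):
        aligned: Matrix = MethylationMatrix(sub, level=matrix.level)
    elif isinstance(matrix, ExpressionMatrix):
        aligned = ExpressionMatrix(sub)
    else:
        aligned = Matrix(sub)
    return aligned, present
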