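"""Data model, TSV I/O and preprocessing for staged proteomics matrices.

The single substrate of every downstream analysis is an :class:`ExpressionMatrix`
(proteins x samples, raw or log2 intensities, missing values allowed) together
with a :class:`StageDesign` mapping ordered disease stages and tissue
compartments (lesion ``L`` vs adjacent non-lesion ``N``) to sample groups.

Missing values are *never* imputed here; each downstream operation declares its
own pairwise-complete or complete-case policy.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default ordered stage vocabulary: esophagitis -> mild dysplasia ->
#: moderate dysplasia -> severe dysplasia -> carcinoma.
DEFAULT_STAGE_ORDER: tuple[str, ...] = ("ESO", "MID", "MOD", "SED", "ESCC")

COMPARTMENTS: tuple[str, ...] = ("L", "N")

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "na"}


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad cells, wrong columns)."""


class VocabularyError(ValueError):
    """A label outside the declared stage/compartment vocabulary."""


class DegenerateDataError(ValueError):
    """An operation met data it cannot meaningfully process."""


@dataclass(frozen=True)
class StageKey:
    """A stage label with its 0-based position in the ordered vocabulary."""

    label: str
    rank: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def stage_keys(stage_order: Sequence[str]) -> dict[str, StageKey]:
    """Map each label of a strict total order to its :class:`StageKey`."""
    if len(set(stage_order)) != len(stage_order):
        raise VocabularyError(f"stage order contains duplicates: {list(stage_order)}")
    return {lab: StageKey(lab, i) for i, lab in enumerate(stage_order)}


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    stage: StageKey
    compartment: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise VocabularyError(
                f"compartment {self.compartment!r} for sample {self.sample_id!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class ExpressionMatrix:
    """Proteins x samples intensity table.

    Parameters
    ----------
    values
        DataFrame indexed by unique protein ids with unique sample-id columns.
        ``NaN`` encodes a missing measurement.
    scale
        ``"raw"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dupes}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.scale == "raw":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                if (self.values.to_numpy() <= 0).any():
                    raise DegenerateDataError("raw intensities must be > 0")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale)


@dataclass
class StageDesign:
    """Ordered stages plus (stage, compartment) -> sample-id groups."""

    stage_order: list[str]
    groups: dict[tuple[str, str], list[str]]
    min_group_size: int = 2
    warnings_: list[str] = field(default_factory=list)

    def group(self, stage: str, compartment: str) -> list[str]:
        return self.groups.get((stage, compartment), [])

    def samples_in_compartment(self, compartment: str) -> list[str]:
        out: list[str] = []
        for stage in self.stage_order:
            out.extend(self.group(stage, compartment))
        return out

    def stages_with_samples(self, compartment: str) -> list[str]:
        return [s for s in self.stage_order if self.group(s, compartment)]

    def group_sizes(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.groups.items()}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    """Read a proteins x samples TSV (first column ``protein_id``).

    Empty cells, ``NA`` and ``NaN`` parse as missing. Duplicate protein or
    sample ids and non-numeric cells are rejected with coordinates.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
        na_values=[],
    )
    df.index = df.index.astype(str)
    parsed = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        missing = raw.isin(_MISSING_TOKENS) | raw.str.strip().isin(_MISSING_TOKENS)
        # detect bad cells first (coerce), then convert through numpy's
        # correctly-rounded strtod so values round-trip bitwise
        probe = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = (~missing) & probe.isna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"non-numeric cell at protein {row!r}, sample {col!r}: "
                f"{raw[bad].iloc[0]!r}"
            )
        parsed[col] = raw.where(~missing, "nan").to_numpy().astype(float)
    return ExpressionMatrix(parsed, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing cells become ``NA``. Deterministic order."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_sample_annotation(
    path: str | Path, stage_order: Sequence[str] = DEFAULT_STAGE_ORDER
) -> list[SampleAnnotation]:
    """Read sample annotations (columns sample_id, stage, compartment[, subject_id])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "compartment"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    keys = stage_keys(stage_order)
    out: list[SampleAnnotation] = []
    for rec in df.itertuples(index=False):
        if rec.stage not in keys:
            raise VocabularyError(
                f"unknown stage {rec.stage!r} for sample {rec.sample_id!r}; "
                f"vocabulary is {list(stage_order)}"
            )
        subject = getattr(rec, "subject_id", None)
        if subject is not None and (pd.isna(subject) or subject == ""):
            subject = None
        out.append(
            SampleAnnotation(rec.sample_id, keys[rec.stage], rec.compartment, subject)
        )
    return out


def write_sample_annotation(
    annotations: Iterable[SampleAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": a.sample_id,
            "stage": a.stage.label,
            "compartment": a.compartment,
            "subject_id": a.subject_id if a.subject_id is not None else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_stage_design(
    annotations: Sequence[SampleAnnotation],
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
    min_group_size: int = 2,
) -> StageDesign:
    """Group samples by (stage, compartment).

    Groups smaller than ``min_group_size`` are flagged with a warning record but
    retained — downstream operations decide whether they are usable.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    keys = stage_keys(stage_order)
    groups: dict[tuple[str, str], list[str]] = {}
    for a in annotations:
        if a.stage.label not in keys:
            raise VocabularyError(f"stage {a.stage.label!r} not in stage order")
        groups.setdefault((a.stage.label, a.compartment), []).append(a.sample_id)
    warn: list[str] = []
    for (stage, comp), ids in groups.items():
        if len(ids) < min_group_size:
            warn.append(
                f"group ({stage}, {comp}) has {len(ids)} sample(s), "
                f"below min_group_size={min_group_size}"
            )
    return StageDesign(list(stage_order), groups, min_group_size, warn)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize per-sample medians.

    On the log2 scale each column is shifted, on the raw scale rescaled, so that
    its median over non-missing values equals the global median of the
    pre-normalization column medians. Keeps values on the interpretable
    intensity scale (target is not zero) and leaves missingness untouched.
    """
    vals = matrix.values
    col_medians = vals.median(axis=0, skipna=True)
    if col_medians.isna().any():
        empty = col_medians.index[col_medians.isna()].tolist()
        raise DegenerateDataError(f"samples with all values missing: {empty}")
    target = float(np.median(col_medians.to_numpy()))
    if matrix.scale == "log2":
        out = vals.sub(col_medians - target, axis=1)
    else:
        out = vals.mul(target / col_medians, axis=1)
    return ExpressionMatrix(out, matrix.scale)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of raw intensities; missing values preserved."""
    if matrix.scale == "log2":
        raise DegenerateDataError("matrix is already on the log2 scale")
    return ExpressionMatrix(np.log2(matrix.values), "log2")


def filter_by_completeness(
    matrix: ExpressionMatrix, design: StageDesign, min_frac: float = 0.5
) -> ExpressionMatrix:
    """Keep proteins observed in >= ``min_frac`` of samples of >= 1 group.

    Row order of the retained proteins is preserved.
    """
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError(f"min_frac must be in [0, 1], got {min_frac}")
    if min_frac == 0.0:
        return matrix.copy()
    present = matrix.values.notna()
    keep = pd.Series(False, index=matrix.values.index)
    for ids in design.groups.values():
        ids = [s for s in ids if s in present.columns]
        if not ids:
            continue
        frac = present[ids].sum(axis=1) / len(ids)
        keep |= frac >= min_frac
    return ExpressionMatrix(matrix.values.loc[keep], matrix.scale)
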