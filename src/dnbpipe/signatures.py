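"""Set-based sample scoring: the EMT (epithelial-mesenchymal transition) score.

The score of a sample is the mean expression of a mesenchymal protein set
minus the mean expression of an epithelial set, on the log2 scale. Missing
set members are dropped per sample (never imputed) and the realized coverage
of each set is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexp import PhaseSplit, phase_samples, test_protein
from .io import ExpressionMatrix, StageDesign


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>id...``."""
    sets: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{line_no}: GMT line needs name, description and >= 1 id"
            )
        name, _desc, *ids = fields
        sets[name] = [i for i in ids if i]
    return sets


@dataclass
class SignatureScoreTable:
    scores: pd.Series                       # sample_id -> score (NaN undefined)
    mes_used: list[str]
    epi_used: list[str]
    coverage: dict[str, float]              # set name -> fraction present in matrix
    undefined: dict[str, str] = field(default_factory=dict)  # sample -> reason


def signature_score(
    matrix: ExpressionMatrix,
    mes_set: Sequence[str],
    epi_set: Sequence[str],
) -> SignatureScoreTable:
    """Per-sample mean(mesenchymal) - mean(epithelial), non-missing values only."""
    rows = set(matrix.protein_ids)
    mes = [p for p in mes_set if p in rows]
    epi = [p for p in epi_set if p in rows]
    if not mes:
        raise ValueError(
            f"no mesenchymal set member in matrix; missing: {sorted(mes_set)}"
        )
    if not epi:
        raise ValueError(
            f"no epithelial set member in matrix; missing: {sorted(epi_set)}"
        )
    mes_mean = matrix.values.loc[mes].mean(axis=0, skipna=True)
    epi_mean = matrix.values.loc[epi].mean(axis=0, skipna=True)
    scores = mes_mean - epi_mean
    undefined = {}
    for sid in matrix.sample_ids:
        if pd.isna(mes_mean[sid]):
            undefined[sid] = "all mesenchymal members missing"
        elif pd.isna(epi_mean[sid]):
            undefined[sid] = "all epithelial members missing"
    coverage = {
        "mesenchymal": len(mes) / len(list(mes_set)),
        "epithelial": len(epi) / len(list(epi_set)),
    }
    return SignatureScoreTable(scores, mes, epi, coverage, undefined)


@dataclass(frozen=True)
class PhaseComparison:
    mean_pre: float
    mean_post: float
    difference: float           # post - pre
    p_value: float
    test: str
    call: str
    n_pre: int
    n_post: int


def compare_phase_scores(
    table: SignatureScoreTable,
    split: PhaseSplit,
    design: StageDesign,
    compartment: str = "L",
) -> PhaseComparison:
    """Normality-gated two-sided test of post- vs pre-phase scores."""
    pre_ids, post_ids = phase_samples(design, split, compartment)
    pre = table.scores.reindex(pre_ids).dropna().to_numpy()
    post = table.scores.reindex(post_ids).dropna().to_numpy()
    if len(pre) < 3 or len(post) < 3:
        raise ValueError(
            f"need >= 3 scored samples per phase, got {len(pre)} and {len(post)}"
        )
    rec = test_protein(post, pre, protein_id="emt_score", fc_hi=0.0, fc_lo=0.0)
    return PhaseComparison(
        mean_pre=float(np.mean(pre)),
        mean_post=float(np.mean(post)),
        difference=float(np.mean(post) - np.mean(pre)),
        p_value=rec.p_value,
        test=rec.test,
        call="ns" if rec.p_value >= 0.05 else "significant",
        n_pre=len(pre),
        n_post=len(post),
    )
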