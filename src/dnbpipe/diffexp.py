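"""Differential expression with a normality-gated test choice.

Per protein: Shapiro-Wilk decides between Welch's t test (both groups
compatible with normality) and the Wilcoxon rank-sum test; significance is
p < alpha combined with a linear fold-change gate (strict FC > 1.20 for up,
FC < 0.83 for down, on the conventional thresholds). No multiple-testing
correction enters the calls — a Benjamini-Hochberg column is emitted for
information only.

Also hosts the phase split around a tipping stage and the stage-specific
protein presence rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, StageDesign, stage_keys

DEFAULT_ALPHA = 0.05
DEFAULT_FC_HI = 1.20
DEFAULT_FC_LO = 0.83
ALPHA_NORMALITY = 0.05
MIN_GROUP_VALUES = 3


class InsufficientDataError(ValueError):
    """A group has too few non-missing values for the requested test."""


@dataclass(frozen=True)
class DERecord:
    protein_id: str
    fc: float
    log2fc: float
    p_value: float
    test: str                   # "student_t" | "wilcoxon"
    call: str                   # "up" | "down" | "ns"
    n_a: int
    n_b: int
    p_adj: float | None = None  # BH, informational only


@dataclass(frozen=True)
class PhaseSplit:
    """Partition of the ordered stages around a tipping stage.

    Stages up to and including the tipping stage form the pre phase
    (pre-malignant analog); the remainder the post phase.
    """

    pre_stages: tuple[str, ...]
    post_stages: tuple[str, ...]


def normality_gate(
    group_a: np.ndarray, group_b: np.ndarray, alpha_norm: float = ALPHA_NORMALITY
) -> str:
    """Choose ``student_t`` iff Shapiro-Wilk keeps normality in both groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < MIN_GROUP_VALUES or len(b) < MIN_GROUP_VALUES:
        raise InsufficientDataError(
            f"normality gate needs >= {MIN_GROUP_VALUES} values per group, "
            f"got {len(a)} and {len(b)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in (a, b):
            if np.ptp(g) == 0:          # constant: Shapiro undefined, clearly non-normal fit
                return "wilcoxon"
            if stats.shapiro(g).pvalue < alpha_norm:
                return "wilcoxon"
    return "student_t"


def classify_call(
    p: float,
    fc: float,
    alpha: float = DEFAULT_ALPHA,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
) -> str:
    """Direction call from p and linear FC; both thresholds are strict."""
    if p < alpha and fc > fc_hi:
        return "up"
    if p < alpha and fc < fc_lo:
        return "down"
    return "ns"


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when min(n)<=10 and no ties, else asymptotic."""
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def test_protein(
    group_a: np.ndarray,
    group_b: np.ndarray,
    protein_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
    alpha_norm: float = ALPHA_NORMALITY,
) -> DERecord:
    """Test one protein (log2 values, A vs B); FC = 2^(mean_a - mean_b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    test = normality_gate(a, b, alpha_norm)
    log2fc = float(np.mean(a) - np.mean(b))
    fc = float(2.0 ** log2fc)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # degenerate: no variation anywhere, identical constants
        p = 1.0
    elif np.ptp(a) == 0 and np.ptp(b) == 0:
        # two distinct constants: rank test is still well defined
        test = "wilcoxon"
        p = _wilcoxon_rank_sum(a, b)
    elif test == "student_t":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = _wilcoxon_rank_sum(a, b)
    call = classify_call(p, fc, alpha, fc_hi, fc_lo)
    return DERecord(protein_id, fc, log2fc, p, test, call, len(a), len(b))


def resolve_group_spec(design: StageDesign, spec: str) -> list[str]:
    """Resolve ``"L:MOD+SED+ESCC"`` to its sample ids (union over stages)."""
    comp, _, stages = spec.partition(":")
    if not stages:
        raise ValueError(f"group spec {spec!r} must look like 'L:MOD+SED+ESCC'")
    out: list[str] = []
    for stage in stages.split("+"):
        ids = design.group(stage.strip(), comp.strip())
        if stage.strip() not in design.stage_order:
            raise ValueError(f"unknown stage {stage!r} in spec {spec!r}")
        out.extend(ids)
    return out


def de_table(
    matrix: ExpressionMatrix,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    fc_hi: float = DEFAULT_FC_HI,
    fc_lo: float = DEFAULT_FC_LO,
    alpha_norm: float = ALPHA_NORMALITY,
) -> tuple[list[DERecord], list[tuple[str, str]]]:
    """Per-protein tests of group A vs group B.

    Returns records sorted by p then \\|log2fc\\| descending, plus a
    (protein_id, reason) list of skipped proteins.
    """
    sa, sb = list(samples_a), list(samples_b)
    if not sa or not sb:
        raise ValueError("both contrast groups must be non-empty")
    if set(sa) & set(sb):
        raise ValueError("contrast groups must be disjoint")
    A = matrix.values[sa].to_numpy()
    B = matrix.values[sb].to_numpy()
    records: list[DERecord] = []
    skipped: list[tuple[str, str]] = []
    for i, pid in enumerate(matrix.protein_ids):
        a = A[i][~np.isnan(A[i])]
        b = B[i][~np.isnan(B[i])]
        if len(a) < MIN_GROUP_VALUES or len(b) < MIN_GROUP_VALUES:
            skipped.append(
                (pid, f"insufficient data: {len(a)} vs {len(b)} non-missing values")
            )
            continue
        records.append(test_protein(a, b, pid, alpha, fc_hi, fc_lo, alpha_norm))
    if records:
        p_adj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        records = [
            DERecord(r.protein_id, r.fc, r.log2fc, r.p_value, r.test, r.call,
                     r.n_a, r.n_b, float(q))
            for r, q in zip(records, p_adj)
        ]
    records.sort(key=lambda r: (r.p_value, -abs(r.log2fc), r.protein_id))
    return records, skipped


def de_records_to_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def split_phases(
    stage_order: Sequence[str], tipping_stage: str
) -> tuple[PhaseSplit, list[str]]:
    """Pre phase = stages with rank <= tipping rank; post phase = the rest."""
    keys = stage_keys(stage_order)
    if tipping_stage not in keys:
        raise ValueError(f"tipping stage {tipping_stage!r} not in {list(stage_order)}")
    cut = keys[tipping_stage].rank
    pre = tuple(s for s in stage_order if keys[s].rank <= cut)
    post = tuple(s for s in stage_order if keys[s].rank > cut)
    warn = []
    if not post:
        warn.append(
            "tipping stage is the last stage: post phase is empty, "
            "phase contrast impossible"
        )
    return PhaseSplit(pre, post), warn


def phase_samples(
    design: StageDesign, split: PhaseSplit, compartment: str
) -> tuple[list[str], list[str]]:
    """(pre-phase sample ids, post-phase sample ids) in one compartment."""
    pre = [s for stage in split.pre_stages for s in design.group(stage, compartment)]
    post = [s for stage in split.post_stages for s in design.group(stage, compartment)]
    return pre, post


def stage_specific_proteins(
    matrix: ExpressionMatrix,
    design: StageDesign,
    compartment: str,
    presence_frac: float = 0.6,
) -> dict[str, list[str]]:
    """Proteins observed in >= presence_frac of one stage and < in all others."""
    if not 0.0 < presence_frac <= 1.0:
        raise ValueError(f"presence_frac must be in (0, 1], got {presence_frac}")
    present = matrix.values.notna()
    stages = design.stages_with_samples(compartment)
    frac = pd.DataFrame(index=matrix.values.index, columns=stages, dtype=float)
    for stage in stages:
        ids = design.group(stage, compartment)
        frac[stage] = present[ids].sum(axis=1) / len(ids)
    hits = frac >= presence_frac
    out: dict[str, list[str]] = {}
    for stage in stages:
        only_here = hits[stage] & ~hits.drop(columns=stage).any(axis=1)
        out[stage] = list(frac.index[only_here])
    return out
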