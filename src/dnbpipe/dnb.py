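"""Dynamic-network-biomarker (DNB) tipping-stage detection.

DNB theory: approaching a critical transition, a small group of molecules (the
dominant group) shows (i) sharply increased within-group variance, (ii)
sharply increased within-group correlation, and (iii) decreased correlation
with the rest of the system. The three signals are combined into a composite
index per stage,

    CI = SD_in * PCC_in / max(PCC_out, eps),

where SD_in is the mean within-stage standard deviation of the module members,
PCC_in the mean absolute Pearson correlation over member pairs, and PCC_out
the mean absolute correlation between members and non-members. The ordered
stage maximizing CI is called the tipping stage.

Candidate modules are found per stage by average-linkage hierarchical
clustering on the distance 1 - |PCC| (the published DNB frameworks leave module
discovery open; the recipe and its knobs are exposed in :class:`DNBParams`).

Missing values are handled pairwise-complete: correlations use only samples
where both proteins are observed, and pairs with fewer than ``min_pairs``
shared observations are flagged undefined (excluded from means), never zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import DegenerateDataError, ExpressionMatrix, StageDesign


@dataclass(frozen=True)
class DNBParams:
    """Knobs of the DNB procedure (all config-exposed)."""

    min_obs_frac: float = 0.5     # per-stage completeness for a protein
    min_pairs: int = 3            # shared observations for a defined correlation
    min_module_size: int = 5
    linkage_cut: float = 0.5      # cut height on 1 - |PCC|
    epsilon: float = 0.01         # floor on PCC_out
    #: Candidate discovery runs on proteins above this within-stage SD quantile
    #: (the variance spike is the leading DNB signal); 0 disables the
    #: pre-selection. CI statistics always use the full retained universe.
    sd_quantile: float = 0.90
    #: Standardize each protein by the first stage's mean/SD before computing
    #: stage statistics (off by default: CI runs on normalized log2 data).
    reference_standardize: bool = False


@dataclass
class StageStats:
    """Per-stage variance and absolute-correlation statistics."""

    stage: str
    protein_ids: list[str]
    sd: np.ndarray                # per-protein SD (ddof=1)
    pcc: np.ndarray               # abs Pearson, NaN where undefined
    n_samples: int


@dataclass(frozen=True)
class DNBModule:
    stage: str
    members: tuple[str, ...]
    sd_in: float
    pcc_in: float
    pcc_out: float
    ci: float


@dataclass
class DNBResult:
    """Fit result: per-stage best modules, CI curve and the tipping call."""

    modules_by_stage: dict[str, DNBModule | None]
    ci_by_stage: dict[str, float]
    tipping_stage: str
    dnb_members: tuple[str, ...]
    compartment: str
    params: DNBParams
    permutation_p: dict[str, float] | None = None
    warnings_: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"DNB analysis, compartment {self.compartment}",
            f"  tipping stage: {self.tipping_stage}",
            f"  module size at tipping stage: {len(self.dnb_members)}",
            "",
            f"  {'stage':>6} {'CI':>10} {'SD_in':>8} {'PCC_in':>8} "
            f"{'PCC_out':>8} {'size':>5}" + ("   perm p" if self.permutation_p else ""),
        ]
        for stage, ci in self.ci_by_stage.items():
            mod = self.modules_by_stage.get(stage)
            if mod is None:
                row = f"  {stage:>6} {ci:>10.4f} {'-':>8} {'-':>8} {'-':>8} {'-':>5}"
            else:
                row = (
                    f"  {stage:>6} {ci:>10.4f} {mod.sd_in:>8.4f} "
                    f"{mod.pcc_in:>8.4f} {mod.pcc_out:>8.4f} {len(mod.members):>5}"
                )
            if self.permutation_p:
                row += f"   {self.permutation_p.get(stage, float('nan')):.4f}"
            lines.append(row)
        return "\n".join(lines)


def pairwise_complete_corr(
    X: np.ndarray, min_pairs: int = 3
) -> np.ndarray:
    """Absolute Pearson correlation over pairwise-complete observations.

    Rows are variables, columns samples; NaN marks missing. Entries backed by
    fewer than ``min_pairs`` shared observations, or with a degenerate
    variance, are NaN. The diagonal is 1 for rows with any variation.
    """
    M = (~np.isnan(X)).astype(float)
    X0 = np.where(np.isnan(X), 0.0, X)
    X0sq = X0 * X0
    n = M @ M.T
    Sxy = X0 @ X0.T
    Sx = X0 @ M.T          # Sx[i, j] = sum of x_i over samples shared with j
    Sxx = X0sq @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sx.T
        varx = n * Sxx - Sx**2
        vary = varx.T
        denom = np.sqrt(varx * vary)
        r = cov / denom
    r = np.abs(r)
    bad = (n < min_pairs) | ~np.isfinite(r)
    r[bad] = np.nan
    np.clip(r, 0.0, 1.0, out=r)
    # diagonal: defined wherever the protein varies at all
    d = np.diagonal(varx).copy()
    np.fill_diagonal(r, np.where(d > 0, 1.0, np.nan))
    np.fill_diagonal(r, np.where(np.diagonal(n) >= min_pairs, np.diagonal(r), np.nan))
    return r


def stagewise_stats(
    matrix: ExpressionMatrix,
    design: StageDesign,
    stage: str,
    compartment: str,
    min_obs_frac: float = 0.5,
    min_pairs: int = 3,
) -> StageStats:
    """SD (ddof=1) and pairwise-complete |PCC| within one (stage, compartment)."""
    ids = design.group(stage, compartment)
    if len(ids) < 3:
        raise DegenerateDataError(
            f"group ({stage}, {compartment}) has {len(ids)} samples; need >= 3"
        )
    sub = matrix.values[ids]
    obs_frac = sub.notna().sum(axis=1) / len(ids)
    kept = sub.loc[obs_frac >= min_obs_frac]
    X = kept.to_numpy()
    with np.errstate(invalid="ignore"):
        sd = np.array([np.nanstd(row, ddof=1) if (~np.isnan(row)).sum() > 1
                       else np.nan for row in X])
    pcc = pairwise_complete_corr(X, min_pairs)
    return StageStats(stage, list(kept.index), sd, pcc, len(ids))


def candidate_modules(
    stats: StageStats,
    min_size: int = 5,
    linkage_cut: float = 0.5,
    sd_quantile: float = 0.0,
) -> list[tuple[str, ...]]:
    """Average-linkage clusters on distance 1 - |PCC|, cut at ``linkage_cut``.

    Undefined correlations count as distance 1. Returns member tuples (sorted
    ids) of every flat-cut cluster with size >= ``min_size``.

    With ``sd_quantile > 0`` the tree is built only over proteins above that
    within-stage SD quantile: a variance pre-selection in the spirit of the
    DNB signal itself, which keeps thousands of flat noise proteins from
    scattering a genuine module. Composite-index statistics downstream are
    unaffected (they always see the full universe in ``stats``).
    """
    sub = np.arange(len(stats.protein_ids))
    if sd_quantile > 0:
        finite_sd = np.where(np.isnan(stats.sd), -np.inf, stats.sd)
        thresh = np.nanquantile(stats.sd, sd_quantile)
        sub = np.flatnonzero(finite_sd >= thresh)
    n = len(sub)
    if n < min_size:
        return []
    pcc = stats.pcc[np.ix_(sub, sub)]
    dist = 1.0 - np.where(np.isnan(pcc), 0.0, pcc)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=linkage_cut, criterion="distance")
    ids = np.asarray(stats.protein_ids)[sub]
    out: list[tuple[str, ...]] = []
    for lab in np.unique(labels):
        members = ids[labels == lab]
        if len(members) >= min_size:
            out.append(tuple(sorted(members)))
    return out


def composite_index(
    stats: StageStats, members: Sequence[str], epsilon: float = 0.01
) -> DNBModule:
    """CI = SD_in * PCC_in / max(PCC_out, eps) for one candidate module."""
    members = tuple(members)
    if len(members) < 2:
        raise ValueError("a module needs >= 2 members")
    index = {p: i for i, p in enumerate(stats.protein_ids)}
    missing = [p for p in members if p not in index]
    if missing:
        raise ValueError(f"members not in stage stats: {missing}")
    mi = np.array([index[p] for p in members])
    outside = np.setdiff1d(np.arange(len(stats.protein_ids)), mi)

    sd_in = float(np.nanmean(stats.sd[mi]))
    block = stats.pcc[np.ix_(mi, mi)]
    iu = np.triu_indices(len(mi), k=1)
    in_vals = block[iu]
    if np.all(np.isnan(in_vals)):
        raise DegenerateDataError(
            f"all member pairs of module at {stats.stage} are undefined"
        )
    pcc_in = float(np.nanmean(in_vals))
    if outside.size:
        out_vals = stats.pcc[np.ix_(mi, outside)]
        pcc_out = float(np.nanmean(out_vals)) if not np.all(np.isnan(out_vals)) else 0.0
    else:
        pcc_out = 0.0
    ci = sd_in * pcc_in / max(pcc_out, epsilon)
    return DNBModule(stats.stage, members, sd_in, pcc_in, pcc_out, ci)


def _best_module(
    stats: StageStats, params: DNBParams
) -> DNBModule | None:
    """Highest-CI candidate; ties -> larger module, then lexicographic members."""
    candidates = candidate_modules(
        stats, params.min_module_size, params.linkage_cut, params.sd_quantile
    )
    best: DNBModule | None = None
    for members in candidates:
        try:
            mod = composite_index(stats, members, params.epsilon)
        except DegenerateDataError:
            continue
        if best is None:
            best = mod
            continue
        if (mod.ci, len(mod.members)) > (best.ci, len(best.members)) or (
            mod.ci == best.ci
            and len(mod.members) == len(best.members)
            and mod.members < best.members
        ):
            best = mod
    return best


class DNBAnalysis:
    """Model object: DNB tipping-stage detection for one compartment.

    Parameters
    ----------
    matrix
        Normalized log2 expression.
    design
        Stage/compartment sample groups.
    compartment
        ``"L"`` or ``"N"``.
    params
        Procedure knobs; see :class:`DNBParams`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        design: StageDesign,
        compartment: str = "L",
        params: DNBParams = DNBParams(),
    ):
        if params.reference_standardize:
            matrix = self._reference_standardized(matrix, design, compartment)
        self.matrix = matrix
        self.design = design
        self.compartment = compartment
        self.params = params

    @staticmethod
    def _reference_standardized(
        matrix: ExpressionMatrix, design: StageDesign, compartment: str
    ) -> ExpressionMatrix:
        """Center/scale each protein by the first stage's mean and SD."""
        first = design.stage_order[0]
        ref_ids = design.group(first, compartment)
        if len(ref_ids) < 3:
            raise DegenerateDataError(
                f"reference stage ({first}, {compartment}) needs >= 3 samples"
            )
        ref = matrix.values[ref_ids]
        mu = ref.mean(axis=1, skipna=True)
        sd = ref.std(axis=1, ddof=1).replace(0.0, np.nan)
        return ExpressionMatrix(matrix.values.sub(mu, axis=0).div(sd, axis=0),
                                matrix.scale)

    def _stage_stats(self, design: StageDesign | None = None) -> dict[str, StageStats]:
        design = design or self.design
        out = {}
        for stage in design.stage_order:
            ids = design.group(stage, self.compartment)
            if len(ids) < 3:
                continue
            out[stage] = stagewise_stats(
                self.matrix, design, stage, self.compartment,
                self.params.min_obs_frac, self.params.min_pairs,
            )
        return out

    def fit(self) -> DNBResult:
        """Score every stage and call the tipping stage (argmax CI)."""
        stats = self._stage_stats()
        if len(stats) < 3:
            raise DegenerateDataError(
                f"need >= 3 stages with valid groups, got {len(stats)}"
            )
        warnings_: list[str] = []
        modules: dict[str, DNBModule | None] = {}
        ci: dict[str, float] = {}
        for stage in self.design.stage_order:
            if stage not in stats:
                warnings_.append(f"stage {stage} skipped (group < 3 samples)")
                continue
            mod = _best_module(stats[stage], self.params)
            modules[stage] = mod
            if mod is None:
                warnings_.append(f"no module of size >= "
                                 f"{self.params.min_module_size} at {stage}; CI = 0")
                ci[stage] = 0.0
            else:
                ci[stage] = mod.ci
        # argmax CI; ties resolved toward the earliest stage rank
        tipping = max(ci, key=lambda s: (ci[s], -self.design.stage_order.index(s)))
        members = modules[tipping].members if modules[tipping] else ()
        return DNBResult(
            modules_by_stage=modules,
            ci_by_stage=ci,
            tipping_stage=tipping,
            dnb_members=members,
            compartment=self.compartment,
            params=self.params,
            warnings_=warnings_,
        )

    def permutation_significance(
        self, result: DNBResult, n_permutations: int = 99, seed: int = 0
    ) -> dict[str, float]:
        """Empirical per-stage p-values by shuffling sample-stage assignment.

        The null shuffles the sample -> stage assignment within the
        compartment (group sizes preserved) and recomputes each stage's best
        CI; p(stage) = (1 + #{null CI >= observed CI}) / (B + 1).
        """
        if n_permutations < 19:
            raise ValueError("need at least 19 permutations")
        rng = np.random.default_rng(seed)
        samples = self.design.samples_in_compartment(self.compartment)
        sizes = [(s, len(self.design.group(s, self.compartment)))
                 for s in self.design.stage_order
                 if self.design.group(s, self.compartment)]
        exceed = {s: 0 for s in result.ci_by_stage}
        for _ in range(n_permutations):
            perm = list(np.array(samples)[rng.permutation(len(samples))])
            groups = dict(self.design.groups)
            pos = 0
            for stage, n in sizes:
                groups[(stage, self.compartment)] = perm[pos:pos + n]
                pos += n
            null_design = StageDesign(
                self.design.stage_order, groups, self.design.min_group_size
            )
            null_stats = self._stage_stats(null_design)
            for stage in exceed:
                if stage not in null_stats:
                    continue
                mod = _best_module(null_stats[stage], self.params)
                null_ci = mod.ci if mod else 0.0
                if null_ci >= result.ci_by_stage[stage]:
                    exceed[stage] += 1
        p = {s: (1 + k) / (n_permutations + 1) for s, k in exceed.items()}
        result.permutation_p = p
        return p
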