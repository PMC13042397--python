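"""Synthetic staged two-compartment proteomics with planted ground truth.

Emulates a 5-stage DIA-style cohort: two tissue compartments (lesion ``L`` and
adjacent non-lesion ``N``), ~2000 proteins, and planted structure that every
downstream analysis can be tested against without patient data:

* a variance + equicorrelation spike in a small protein module at one stage
  (the dynamic-network-biomarker signal and its tipping stage),
* four monotone/peaked trend-cluster templates,
* a discriminative panel shifted between the pre- and post-tipping phases,
* an epithelial-to-mesenchymal drift proportional to stage rank,
* per-sample median offsets and intensity-dependent missingness.

All planted effects live in the L compartment; the N compartment is
baseline-plus-noise and doubles as a negative control.

Generative model, per protein p and sample j in stage s:

    x_pj = b_p + t_p(s) + panel/EMT shifts + m_j + e_pj

with protein baseline b_p ~ N(mu_b, sigma_b^2), trend template t_p scaled to
amplitude delta, sample offset m_j ~ N(0, sample_median_sd^2), and noise
e_pj ~ N(0, sigma_p^2), sigma_p ~ U(sigma_lo, sigma_hi). For module members at
the tipping stage the noise is inflated and equicorrelated via a shared
factor: e_pj = kappa * sigma_p * (sqrt(rho*) z_j + sqrt(1-rho*) w_pj); at other
stages the same construction uses rho0 and multiplier 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_STAGE_ORDER,
    ExpressionMatrix,
    SampleAnnotation,
    StageDesign,
    build_stage_design,
    stage_keys,
)

#: Group sizes of the emulated cohort: (stage, compartment) -> n samples.
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("ESO", "L"): 10, ("MID", "L"): 19, ("MOD", "L"): 11,
    ("SED", "L"): 14, ("ESCC", "L"): 10,
    ("ESO", "N"): 8, ("MID", "N"): 17, ("MOD", "N"): 8,
    ("SED", "N"): 10, ("ESCC", "N"): 5,
}

TREND_TEMPLATES: tuple[str, ...] = ("up", "down", "peak_mid", "peak_tipping")


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_proteins: int = 2000
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    dnb_size: int = 15
    tipping_stage: str = "MID"
    rho_spike: float = 0.8
    rho_base: float = 0.1
    sd_multiplier: float = 3.0
    n_trend_proteins: int = 50      # per template
    trend_amplitude: float = 1.0    # log2 units
    panel_size: int = 7
    panel_shift: float = 1.0        # log2 units added post-phase
    emt_set_sizes: tuple[int, int] = (10, 10)   # (epithelial, mesenchymal)
    emt_drift: float = 0.15         # log2 units per stage rank
    baseline_mean: float = 20.0     # log2 DIA intensity scale
    baseline_sd: float = 2.0
    noise_sd_range: tuple[float, float] = (0.2, 0.6)
    sample_median_sd: float = 0.3
    missing_rate: float = 0.2
    missing_steepness: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.rho_base < 1 and 0 <= self.rho_spike < 1):
            raise ValueError("correlations must be in [0, 1)")
        if self.rho_spike < self.rho_base:
            raise ValueError("rho_spike must be >= rho_base")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.tipping_stage not in self.stage_order:
            raise ValueError(
                f"tipping stage {self.tipping_stage!r} not in {self.stage_order}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        n_planted = (
            self.dnb_size
            + self.panel_size
            + len(TREND_TEMPLATES) * self.n_trend_proteins
            + sum(self.emt_set_sizes)
        )
        if n_planted > self.n_proteins:
            raise ValueError(
                f"planted sets need {n_planted} proteins, only "
                f"{self.n_proteins} available"
            )
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 2")


@dataclass
class SyntheticTruth:
    """Planted ground truth; the oracle of every recovery test."""

    tipping_stage: str
    dnb_members: list[str]
    panel_members: list[str]
    trend_assignment: dict[str, str]        # id -> template or "null"
    phase_label: dict[str, str]             # sample id -> "pre" | "post"
    emt_sets: tuple[list[str], list[str]]   # (epithelial, mesenchymal)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tipping_stage": self.tipping_stage,
            "dnb_members": self.dnb_members,
            "panel_members": self.panel_members,
            "trend_assignment": self.trend_assignment,
            "phase_label": self.phase_label,
            "emt_sets": {"epithelial": self.emt_sets[0], "mesenchymal": self.emt_sets[1]},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _template_values(name: str, n_stages: int, tipping_rank: int) -> np.ndarray:
    ranks = np.arange(n_stages, dtype=float)
    if name == "up":
        return ranks / (n_stages - 1)
    if name == "down":
        return 1.0 - ranks / (n_stages - 1)
    if name == "peak_mid":
        mid = (n_stages - 1) / 2.0
        return 1.0 - np.abs(ranks - mid) / mid
    if name == "peak_tipping":
        return (ranks == tipping_rank).astype(float)
    raise ValueError(f"unknown template {name!r}")


def generate_staged_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Draw one cohort; deterministic given ``config.seed``.

    Returns the (possibly incomplete) log2 expression matrix, its sample
    annotations and the planted truth. Missingness is injected here when
    ``config.missing_rate > 0``.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    keys = stage_keys(cfg.stage_order)
    tip_rank = keys[cfg.tipping_stage].rank
    n_stages = len(cfg.stage_order)

    protein_ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = protein_ids[cursor:cursor + n]
        cursor += n
        return out

    dnb_members = take(cfg.dnb_size)
    panel_members = take(cfg.panel_size)
    trend_members = {t: take(cfg.n_trend_proteins) for t in TREND_TEMPLATES}
    epi_ids = take(cfg.emt_set_sizes[0])
    mes_ids = take(cfg.emt_set_sizes[1])

    # sample bookkeeping, ordered stage-major then compartment
    annotations: list[SampleAnnotation] = []
    for comp in ("L", "N"):
        for stage in cfg.stage_order:
            n = cfg.group_sizes.get((stage, comp), 0)
            for i in range(n):
                sid = f"{stage}_{comp}{i + 1:02d}"
                annotations.append(SampleAnnotation(sid, keys[stage], comp))
    sample_ids = [a.sample_id for a in annotations]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_proteins)
    sigma = rng.uniform(*cfg.noise_sd_range, cfg.n_proteins)

    idx = {p: i for i, p in enumerate(protein_ids)}
    dnb_idx = np.array([idx[p] for p in dnb_members])
    panel_idx = np.array([idx[p] for p in panel_members])
    epi_idx = np.array([idx[p] for p in epi_ids])
    mes_idx = np.array([idx[p] for p in mes_ids])

    trend_matrix = np.zeros((cfg.n_proteins, n_stages))
    trend_assignment = {p: "null" for p in protein_ids}
    for name, members in trend_members.items():
        tvals = _template_values(name, n_stages, tip_rank) * cfg.trend_amplitude
        for p in members:
            trend_matrix[idx[p]] = tvals
            trend_assignment[p] = name

    panel_shift_vec = np.zeros(cfg.n_proteins)
    panel_shift_vec[panel_idx] = cfg.panel_shift

    X = np.empty((cfg.n_proteins, len(sample_ids)))
    phase_label: dict[str, str] = {}
    col = 0
    for a in annotations:
        s_rank = a.stage.rank
        planted = a.compartment == "L"
        post = s_rank > tip_rank
        phase_label[a.sample_id] = "post" if post else "pre"

        x = baseline + rng.normal(0.0, cfg.sample_median_sd)  # m_j
        if planted:
            x = x + trend_matrix[:, s_rank]
            if post:
                x = x + panel_shift_vec
            x[mes_idx] += cfg.emt_drift * s_rank
            x[epi_idx] -= cfg.emt_drift * s_rank

        e = rng.normal(0.0, 1.0, cfg.n_proteins) * sigma
        # equicorrelated DNB noise: shared factor z_j across module members
        at_tip = planted and s_rank == tip_rank
        rho = cfg.rho_spike if at_tip else cfg.rho_base
        mult = cfg.sd_multiplier if at_tip else 1.0
        z = rng.normal()
        w = rng.normal(0.0, 1.0, len(dnb_idx))
        e[dnb_idx] = mult * sigma[dnb_idx] * (
            np.sqrt(rho) * z + np.sqrt(1.0 - rho) * w
        )
        X[:, col] = x + e
        col += 1

    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=protein_ids, columns=sample_ids), "log2"
    )
    if cfg.missing_rate > 0:
        matrix = inject_missingness(
            matrix, cfg.missing_rate, cfg.missing_steepness,
            seed=int(rng.integers(2**31)),
        )

    truth = SyntheticTruth(
        tipping_stage=cfg.tipping_stage,
        dnb_members=dnb_members,
        panel_members=panel_members,
        trend_assignment=trend_assignment,
        phase_label=phase_label,
        emt_sets=(epi_ids, mes_ids),
    )
    return matrix, annotations, truth


def inject_missingness(
    matrix: ExpressionMatrix,
    missing_rate: float,
    steepness: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Intensity-dependent dropout typical of DIA proteomics.

    Each cell goes missing independently with probability proportional to
    ``logistic(-steepness * (x - q))`` (``q`` = global median), rescaled so the
    expected overall rate equals ``missing_rate``. ``steepness=0`` gives
    uniform dropout.
    """
    if missing_rate >= 1.0:
        raise ValueError(f"missing_rate must be < 1, got {missing_rate}")
    if missing_rate < 0.0:
        raise ValueError(f"missing_rate must be >= 0, got {missing_rate}")
    if missing_rate == 0.0:
        return matrix.copy()
    if matrix.scale != "log2":
        raise ValueError("inject_missingness expects a log2-scale matrix")
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy()
    obs = ~np.isnan(vals)
    q = np.nanmedian(vals)
    with np.errstate(over="ignore"):
        p0 = 1.0 / (1.0 + np.exp(steepness * (vals - q)))
    p0 = np.where(obs, p0, 0.0)
    scale = missing_rate * obs.sum() / p0.sum()
    p = np.clip(p0 * scale, 0.0, 1.0)
    drop = (rng.random(vals.shape) < p) & obs
    out = vals.copy()
    out[drop] = np.nan
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "log2",
    )


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with every planted effect switched off.

    Used for type-I-error and permutation-level checks: no trends, no panel
    shift, no EMT drift, no variance/correlation spike.
    """
    cfg = SyntheticConfig(
        trend_amplitude=0.0,
        panel_shift=0.0,
        emt_drift=0.0,
        sd_multiplier=1.0,
        rho_spike=0.1,
        rho_base=0.1,
    )
    return dataclasses.replace(cfg, **overrides)
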