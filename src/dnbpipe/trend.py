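"""Soft clustering of per-stage mean trajectories (fuzzy c-means).

Each protein is reduced to its per-stage mean log2 expression in one
compartment, row-standardized, and softly clustered into ``c`` trend shapes
(default 4: rising, falling, mid-peaked, late/tipping-peaked) with a fuzzy
c-means model. The fuzzifier ``m > 1`` controls how soft memberships are; the
objective sum_i sum_c u_ic^m ||x_i - v_c||^2 is non-increasing under the
alternating updates, which is asserted at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, StageDesign


@dataclass
class StageProfileMatrix:
    """Per-(protein, stage) mean expression, optionally row-standardized."""

    values: pd.DataFrame          # proteins x stages
    standardized: bool = False
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stage_order(self) -> list[str]:
        return list(self.values.columns)


def stage_mean_profiles(
    matrix: ExpressionMatrix, design: StageDesign, compartment: str
) -> StageProfileMatrix:
    """Mean over non-missing values per (protein, stage).

    Proteins with no observation at some stage cannot form a full trajectory
    and are excluded with a reason.
    """
    stages = design.stage_order
    empty = [s for s in stages if not design.group(s, compartment)]
    if empty:
        raise ValueError(
            f"stage(s) {empty} have no samples in compartment {compartment!r}"
        )
    cols = {}
    for stage in stages:
        ids = design.group(stage, compartment)
        cols[stage] = matrix.values[ids].mean(axis=1, skipna=True)
    prof = pd.DataFrame(cols)[stages]
    excluded = []
    bad = prof.isna().any(axis=1)
    for pid in prof.index[bad]:
        missing_at = [s for s in stages if pd.isna(prof.at[pid, s])]
        excluded.append((pid, f"no data at {','.join(missing_at)}"))
    return StageProfileMatrix(prof.loc[~bad], False, excluded)


def standardize_profiles(profiles: StageProfileMatrix) -> StageProfileMatrix:
    """Row z-scores; zero-variance rows are removed and reported."""
    vals = profiles.values
    sd = vals.std(axis=1, ddof=1)
    flat = sd == 0
    excluded = list(profiles.excluded) + [
        (pid, "constant trajectory") for pid in vals.index[flat]
    ]
    kept = vals.loc[~flat]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~flat], axis=0)
    return StageProfileMatrix(z, True, excluded)


def estimate_fuzzifier(n_rows: int, n_cols: int) -> float:
    """Data-size-driven fuzzifier heuristic for standardized profiles.

    Uses the published minimum-fuzzifier relation for clustering of
    standardized short expression profiles, which grows the fuzzifier for
    small datasets and approaches 1 for large ones:

        m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    with N profiles of dimension D. Offered as an alternative to the fixed
    default; not a bit-for-bit port of any package's estimator.
    """
    N, D = float(n_rows), float(n_cols)
    if N < 2 or D < 2:
        raise ValueError("need at least 2 rows and 2 dimensions")
    return 1.0 + (1418.0 / N + 22.05) * D**-2.0 + (
        12.33 / N + 0.243
    ) * D ** (-0.0406 * np.log(N) - 0.1134)


@dataclass
class FuzzyCMeansResult:
    """Fitted soft-clustering state."""

    centers: pd.DataFrame         # c x stages
    membership: pd.DataFrame      # proteins x c, rows sum to 1
    objective: float
    n_iter: int
    m: float
    seed: int
    objective_path: list[float] = field(default_factory=list)

    @property
    def c(self) -> int:
        return self.centers.shape[0]

    def hard_labels(self) -> pd.Series:
        """Argmax cluster per protein."""
        return self.membership.idxmax(axis=1)

    def core_members(self, threshold: float = 0.5) -> dict[str, list[str]]:
        """Cluster -> proteins with membership >= threshold there.

        Proteins below threshold in every cluster appear under
        ``"unassigned"``.
        """
        if not 0.0 < threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {threshold}")
        out: dict[str, list[str]] = {c: [] for c in self.membership.columns}
        out["unassigned"] = []
        hit = self.membership >= threshold
        for pid in self.membership.index:
            row = hit.loc[pid]
            if row.any():
                for c in self.membership.columns[row]:
                    out[c].append(pid)
            else:
                out["unassigned"].append(pid)
        return out

    def summary(self) -> str:
        sizes = self.hard_labels().value_counts().sort_index()
        lines = [
            "Fuzzy c-means trend clustering",
            f"  clusters: {self.c}   fuzzifier m: {self.m}   iterations: {self.n_iter}",
            f"  objective: {self.objective:.6g}",
            "  hard-assignment sizes:",
        ]
        for c, n in sizes.items():
            lines.append(f"    {c}: {n}")
        return "\n".join(lines)


class FuzzyCMeans:
    """Fuzzy c-means on standardized stage profiles.

    ``fit()`` runs ``n_restarts`` seeded initializations (centers drawn from
    distinct data rows) and keeps the lowest-objective solution.
    """

    def __init__(
        self,
        profiles: StageProfileMatrix,
        c: int = 4,
        m: float = 1.25,
        max_iter: int = 300,
        tol: float = 1e-6,
        n_restarts: int = 5,
    ):
        if not profiles.standardized:
            profiles = standardize_profiles(profiles)
        if c < 1:
            raise ValueError("c must be >= 1")
        if c > profiles.values.shape[0]:
            raise ValueError(
                f"c={c} exceeds the {profiles.values.shape[0]} available rows"
            )
        if m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        self.profiles = profiles
        self.c, self.m = c, m
        self.max_iter, self.tol = max_iter, tol
        self.n_restarts = n_restarts

    @staticmethod
    def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
        # d2[i, c] = squared Euclidean distance to center c
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        exp = 1.0 / (m - 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exp)
            u = inv / inv.sum(axis=1, keepdims=True)
        # coincident with a center: full membership there (split over exact ties)
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        return u

    @staticmethod
    def _objective(X: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return float((u ** m * d2).sum())

    def _fit_once(self, seed: int) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
        X = self.profiles.values.to_numpy()
        rng = np.random.default_rng(seed)
        init_rows = rng.choice(X.shape[0], size=self.c, replace=False)
        centers = X[init_rows].copy()
        path: list[float] = []
        u = self._memberships(X, centers, self.m)
        prev_obj = self._objective(X, centers, u, self.m)
        path.append(prev_obj)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            um = u ** self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            u = self._memberships(X, centers, self.m)
            assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9), (
                "membership rows must stay normalized at every iteration"
            )
            obj = self._objective(X, centers, u, self.m)
            # alternating minimization: objective may not increase
            assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), (
                f"fuzzy c-means objective increased: {prev_obj} -> {obj}"
            )
            path.append(obj)
            prev_obj = obj
            if shift < self.tol:
                break
        return centers, u, prev_obj, n_iter, path

    def fit(self, seed: int = 0) -> FuzzyCMeansResult:
        sub_seeds = np.random.default_rng(seed).integers(2**31, size=self.n_restarts)
        best = None
        best_seed = int(sub_seeds[0])
        for s in sub_seeds:
            res = self._fit_once(int(s))
            if best is None or res[2] < best[2]:
                best, best_seed = res, int(s)
        centers, u, obj, n_iter, path = best
        cluster_ids = [f"cluster_{i + 1}" for i in range(self.c)]
        return FuzzyCMeansResult(
            centers=pd.DataFrame(
                centers, index=cluster_ids, columns=self.profiles.stage_order
            ),
            membership=pd.DataFrame(
                u, index=self.profiles.protein_ids, columns=cluster_ids
            ),
            objective=obj,
            n_iter=n_iter,
            m=self.m,
            seed=best_seed,
            objective_path=path,
        )
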