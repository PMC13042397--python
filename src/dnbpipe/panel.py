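"""Phase-classifier construction: learner benchmarking, SVM-RFE, panel CV.

Labels are the two progression phases (post-tipping = positive class). The
workflow mirrors common biomarker-panel practice:

1. benchmark several learners under identical stratified CV folds (AUC),
2. rank features by linear-SVM recursive feature elimination (SVM-RFE):
   repeatedly fit, score features by squared weight, drop the weakest,
3. pick a panel size, with the honest CV curve re-running RFE inside every
   training fold so feature selection never sees held-out samples.

AUC is the Mann-Whitney statistic (midranks for ties): the probability that a
random positive outscores a random negative, plus half the tie probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum identity, midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def _decision_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def default_learners(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Factory map of the benchmarked learners (extensible via config)."""
    return {
        "svm_linear": lambda: SVC(kernel="linear", C=1.0, random_state=seed),
        "svm_rbf": lambda: SVC(kernel="rbf", C=1.0, random_state=seed),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, random_state=seed
        ),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
    }


@dataclass
class BenchmarkTable:
    """Mean/SD of fold AUCs per learner, identical folds across learners."""

    results: pd.DataFrame       # index learner, columns mean_auc, sd_auc
    k_folds: int
    repeats: int
    seed: int

    def summary(self) -> str:
        lines = [
            f"Learner benchmark ({self.k_folds}-fold x {self.repeats} repeats, "
            f"seed {self.seed})",
        ]
        for name, row in self.results.sort_values(
            "mean_auc", ascending=False
        ).iterrows():
            lines.append(f"  {name:<22} AUC = {row.mean_auc:.3f} +/- {row.sd_auc:.3f}")
        return "\n".join(lines)


def _fold_plan(
    y: np.ndarray, k_folds: int, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    plan = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed + r)
        plan.extend(skf.split(np.zeros(len(y)), y))
    return plan


def benchmark_learners(
    X: np.ndarray,
    y: np.ndarray,
    learners: Mapping[str, Callable[[], object]] | None = None,
    k_folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> BenchmarkTable:
    """Cross-validated AUC per learner on one shared fold plan.

    Features are standardized inside each training fold only (no leakage).
    """
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {k_folds} folds"
        )
    learners = learners or default_learners(seed)
    plan = _fold_plan(y, k_folds, repeats, seed)
    rows = {}
    for name, make in learners.items():
        aucs = []
        for train, test in plan:
            scaler = StandardScaler().fit(X[train])
            clf = make()
            clf.fit(scaler.transform(X[train]), y[train])
            s = _decision_scores(clf, scaler.transform(X[test]))
            aucs.append(auc_mann_whitney(s, y[test]))
        rows[name] = {"mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs))}
    return BenchmarkTable(pd.DataFrame(rows).T, k_folds, repeats, seed)


def svm_rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    drop_frac: float = 0.1,
    C: float = 1.0,
) -> list[str]:
    """SVM-RFE importance ranking (most informative first).

    Iteratively fits a linear SVM on the surviving features (standardized),
    scores each by its squared weight, and eliminates the weakest
    ``ceil(drop_frac * surviving)`` (at least one). The reversed elimination
    order is the ranking; within one round, weaker weights rank lower.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("SVM-RFE needs binary labels")
    if not 0.0 < drop_frac < 1.0:
        raise ValueError(f"drop_frac must be in (0, 1), got {drop_frac}")
    surviving = list(range(X.shape[1]))
    eliminated: list[int] = []
    while surviving:
        if len(surviving) == 1:
            eliminated.append(surviving.pop())
            break
        Xs = StandardScaler().fit_transform(X[:, surviving])
        clf = SVC(kernel="linear", C=C).fit(Xs, y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        n_drop = max(1, int(np.ceil(drop_frac * len(surviving))))
        # weakest first so the reversed order ranks them lowest
        order = np.argsort(w2, kind="stable")
        for j in order[:n_drop]:
            eliminated.append(surviving[j])
        drop_set = {surviving[j] for j in order[:n_drop]}
        surviving = [f for f in surviving if f not in drop_set]
    ranked_idx = list(reversed(eliminated))
    ids = list(feature_ids)
    return [ids[i] for i in ranked_idx]


@dataclass
class PanelResult:
    """Selected biomarker panel with its honest CV-AUC trajectory."""

    ranked_features: list[str]
    selected_panel: list[str]
    cv_auc_by_size: pd.DataFrame    # index size, columns mean_auc, sd_auc
    final_auc: float                # mean CV AUC at the selected size
    learner: str
    rule: str
    seed: int

    def summary(self) -> str:
        lines = [
            "SVM-RFE panel selection",
            f"  learner: {self.learner}   rule: {self.rule}   seed: {self.seed}",
            f"  panel ({len(self.selected_panel)} proteins): "
            + ", ".join(self.selected_panel),
            f"  cross-validated AUC at this size: {self.final_auc:.3f}",
        ]
        return "\n".join(lines)


class SVMRFEPanel:
    """Model object: phase-discriminating panel via SVM-RFE.

    ``fit()`` ranks features on the full data (the reported importance order)
    and builds the CV-AUC-by-size curve with RFE re-run inside each training
    fold, then applies the selection rule (``fixed_k`` or ``one_se``).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_ids: Sequence[str],
        drop_frac: float = 0.1,
        C: float = 1.0,
        k_folds: int = 5,
        max_size: int = 20,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(int)
        self.feature_ids = list(feature_ids)
        self.drop_frac = drop_frac
        self.C = C
        self.k_folds = k_folds
        self.max_size = min(max_size, len(self.feature_ids))

    def _cv_curve(self, seed: int) -> pd.DataFrame:
        sizes = range(1, self.max_size + 1)
        fold_aucs: dict[int, list[float]] = {s: [] for s in sizes}
        skf = StratifiedKFold(n_splits=self.k_folds, shuffle=True, random_state=seed)
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        for train, test in skf.split(self.X, self.y):
            ranking = svm_rfe_rank(
                self.X[train], self.y[train], self.feature_ids,
                self.drop_frac, self.C,
            )
            for s in sizes:
                cols = [idx[f] for f in ranking[:s]]
                scaler = StandardScaler().fit(self.X[np.ix_(train, cols)])
                clf = SVC(kernel="linear", C=self.C).fit(
                    scaler.transform(self.X[np.ix_(train, cols)]), self.y[train]
                )
                scores = clf.decision_function(
                    scaler.transform(self.X[np.ix_(test, cols)])
                )
                fold_aucs[s].append(auc_mann_whitney(scores, self.y[test]))
        return pd.DataFrame(
            {
                "mean_auc": [float(np.mean(fold_aucs[s])) for s in sizes],
                "sd_auc": [float(np.std(fold_aucs[s])) for s in sizes],
            },
            index=pd.Index(sizes, name="size"),
        )

    def fit(self, rule: str = "fixed_k", k: int = 7, seed: int = 0) -> PanelResult:
        if rule not in ("fixed_k", "one_se"):
            raise ValueError(f"rule must be 'fixed_k' or 'one_se', got {rule!r}")
        if rule == "fixed_k" and not 1 <= k <= len(self.feature_ids):
            raise ValueError(
                f"k={k} out of range for {len(self.feature_ids)} features"
            )
        ranked = svm_rfe_rank(self.X, self.y, self.feature_ids, self.drop_frac, self.C)
        curve = self._cv_curve(seed)
        if rule == "fixed_k":
            size = k
            rule_desc = f"fixed_k({k})"
        else:
            best = curve["mean_auc"].max()
            sd_at_best = float(curve.loc[curve["mean_auc"].idxmax(), "sd_auc"])
            ok = curve.index[curve["mean_auc"] >= best - sd_at_best]
            size = int(ok.min())
            rule_desc = "one_se"
        size = min(size, len(ranked))
        final = float(curve.loc[size, "mean_auc"]) if size in curve.index else float("nan")
        return PanelResult(
            ranked_features=ranked,
            selected_panel=ranked[:size],
            cv_auc_by_size=curve,
            final_auc=final,
            learner=f"SVC(kernel='linear', C={self.C})",
            rule=rule_desc,
            seed=seed,
        )


def phase_feature_matrix(
    matrix, design, split, compartment: str = "L",
    min_obs_frac: float = 1.0, impute: bool = False,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Feature matrix (samples x proteins) and phase labels for the classifier.

    Default policy is complete-case: proteins with any missing value across
    the analyzed samples are dropped. With ``min_obs_frac < 1`` and
    ``impute=True``, proteins observed in at least that fraction of samples
    are kept and their gaps filled with the per-protein median (a pragmatic
    fill; the classifier CV still standardizes per training fold). Returns
    (X, y, feature_ids, sample_ids) with post-phase = 1.
    """
    from .diffexp import phase_samples

    pre_ids, post_ids = phase_samples(design, split, compartment)
    samples = pre_ids + post_ids
    sub = matrix.values[samples]
    if min_obs_frac >= 1.0:
        kept = sub.dropna(axis=0)
    else:
        frac = sub.notna().sum(axis=1) / sub.shape[1]
        kept = sub.loc[frac >= min_obs_frac]
        if not impute:
            kept = kept.dropna(axis=0)
    if impute:
        kept = kept.apply(lambda row: row.fillna(row.median()), axis=1)
    X = kept.to_numpy().T
    y = np.array([0] * len(pre_ids) + [1] * len(post_ids))
    return X, y, list(kept.index), samples
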