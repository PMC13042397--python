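"""End-to-end orchestration: one config in, one report out.

Order of stages mirrors the analysis logic: preprocess -> trend clusters ->
DNB tipping call -> phase split -> phase DE -> EMT scoring -> panel ->
crosstalk. The tipping stage used for phase splitting defaults to the
L-compartment DNB call and can be overridden in the config (the two
compartments' calls are both reported, the choice stays with the user).

A run is a pure function of its config: the report JSON is byte-identical
across repeated runs (sorted keys, no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import crosstalk as ct
from . import diffexp as de
from . import signatures as sig
from .dnb import DNBAnalysis, DNBParams
from .io import (
    DEFAULT_STAGE_ORDER,
    ExpressionMatrix,
    StageDesign,
    build_stage_design,
    filter_by_completeness,
    log2_transform,
    median_normalize,
    read_expression_matrix,
    read_sample_annotation,
    write_expression_matrix,
    write_sample_annotation,
)
from .panel import SVMRFEPanel, benchmark_learners, phase_feature_matrix
from .simulate import SyntheticConfig, generate_staged_dataset
from .trend import FuzzyCMeans, stage_mean_profiles, standardize_profiles


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    output_dir: str = "dnbpipe_out"
    seed: int = 0
    stage_order: list[str] = field(default_factory=lambda: list(DEFAULT_STAGE_ORDER))
    # input: file paths, or a synthetic block (dict of SyntheticConfig overrides)
    expression_path: str | None = None
    annotation_path: str | None = None
    scale: str = "log2"
    synthetic: dict[str, Any] | None = None
    # preprocessing
    min_frac_complete: float = 0.5
    compartment: str = "L"
    # differential expression
    alpha: float = 0.05
    fc_hi: float = 1.20
    fc_lo: float = 0.83
    # trend clustering
    n_clusters: int = 4
    fuzzifier: float = 1.25
    membership_threshold: float = 0.5
    # DNB
    dnb_min_obs_frac: float = 0.5
    dnb_min_pairs: int = 3
    dnb_min_module_size: int = 5
    dnb_linkage_cut: float = 0.5
    dnb_epsilon: float = 0.01
    dnb_sd_quantile: float = 0.90
    permutations: int = 0
    tipping_override: str | None = None
    # signatures
    gmt_path: str | None = None
    # panel
    panel_k: int = 7
    panel_folds: int = 5
    panel_drop_frac: float = 0.1
    panel_max_size: int = 20
    benchmark_repeats: int = 2
    # crosstalk
    pair_table_path: str | None = None
    crosstalk_stage: str = "MOD"
    min_detect_frac: float = 0.5
    crosstalk_top_n: int = 50

    def dnb_params(self) -> DNBParams:
        return DNBParams(
            self.dnb_min_obs_frac, self.dnb_min_pairs, self.dnb_min_module_size,
            self.dnb_linkage_cut, self.dnb_epsilon, self.dnb_sd_quantile,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _synthetic_config(cfg: RunConfig) -> SyntheticConfig:
    overrides = dict(cfg.synthetic or {})
    overrides.setdefault("seed", cfg.seed)
    if "group_sizes" in overrides:  # YAML keys are "STAGE:COMP" strings
        overrides["group_sizes"] = {
            tuple(k.split(":")): v for k, v in overrides["group_sizes"].items()
        }
    if "stage_order" not in overrides:
        overrides["stage_order"] = tuple(cfg.stage_order)
    return SyntheticConfig(**overrides)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the report dict (also written as JSON)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    report: dict[str, Any] = {
        "config": dataclasses.asdict(cfg),
        "versions": {
            "dnbpipe": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": [],
    }

    # --- input -------------------------------------------------------------
    truth = None
    if cfg.expression_path and cfg.annotation_path:
        matrix = read_expression_matrix(cfg.expression_path, cfg.scale)
        annotations = read_sample_annotation(cfg.annotation_path, cfg.stage_order)
    else:
        sim_cfg = _synthetic_config(cfg)
        matrix, annotations, truth = generate_staged_dataset(sim_cfg)
        write_expression_matrix(matrix, out / "expression.tsv")
        write_sample_annotation(annotations, out / "annotation.tsv")
        truth.to_json(out / "truth.json")
    design = build_stage_design(annotations, cfg.stage_order)
    report["warnings"] += design.warnings_

    # --- preprocessing -----------------------------------------------------
    if matrix.scale == "raw":
        matrix = log2_transform(matrix)
    matrix = median_normalize(matrix)
    matrix = filter_by_completeness(matrix, design, cfg.min_frac_complete)
    report["n_proteins_after_filter"] = matrix.shape[0]
    report["n_samples"] = matrix.shape[1]

    # --- trend clustering --------------------------------------------------
    profiles = standardize_profiles(
        stage_mean_profiles(matrix, design, cfg.compartment)
    )
    fcm = FuzzyCMeans(profiles, c=cfg.n_clusters, m=cfg.fuzzifier).fit(seed=cfg.seed)
    fcm.membership.to_csv(out / "trend_membership.tsv", sep="\t")
    fcm.centers.to_csv(out / "trend_centers.tsv", sep="\t")
    report["trend"] = {
        "n_clustered": int(fcm.membership.shape[0]),
        "objective": fcm.objective,
        "cluster_sizes": {
            k: len(v)
            for k, v in fcm.core_members(cfg.membership_threshold).items()
        },
    }

    # --- DNB ---------------------------------------------------------------
    dnb_results = {}
    for comp in ("L", "N"):
        if not design.samples_in_compartment(comp):
            continue
        analysis = DNBAnalysis(matrix, design, comp, cfg.dnb_params())
        res = analysis.fit()
        if cfg.permutations:
            analysis.permutation_significance(res, cfg.permutations, cfg.seed)
        dnb_results[comp] = res
        report.setdefault("dnb", {})[comp] = {
            "tipping_stage": res.tipping_stage,
            "ci_by_stage": res.ci_by_stage,
            "n_members": len(res.dnb_members),
            "members": sorted(res.dnb_members),
            "permutation_p": res.permutation_p,
        }
        (out / f"dnb_{comp}.json").write_text(
            json.dumps(report["dnb"][comp], indent=2, sort_keys=True)
        )

    tipping = cfg.tipping_override or dnb_results[cfg.compartment].tipping_stage
    split, warn = de.split_phases(cfg.stage_order, tipping)
    report["warnings"] += warn
    report["phase_split"] = {
        "tipping_stage": tipping,
        "pre": list(split.pre_stages),
        "post": list(split.post_stages),
    }
    if not split.post_stages:
        report["report_path"] = str(out / "report.json")
        _write_report(report, out)
        return report

    # --- phase differential expression --------------------------------------
    pre_ids, post_ids = de.phase_samples(design, split, cfg.compartment)
    records, skipped = de.de_table(
        matrix, post_ids, pre_ids, cfg.alpha, cfg.fc_hi, cfg.fc_lo
    )
    de.de_records_to_frame(records).to_csv(out / "de_phase.tsv", sep="\t", index=False)
    pd.DataFrame(skipped, columns=["protein_id", "reason"]).to_csv(
        out / "de_skipped.tsv", sep="\t", index=False
    )
    report["de"] = {
        "n_tested": len(records),
        "n_skipped": len(skipped),
        "n_up": sum(r.call == "up" for r in records),
        "n_down": sum(r.call == "down" for r in records),
    }

    specific = de.stage_specific_proteins(matrix, design, cfg.compartment, 0.6)
    report["stage_specific_counts"] = {s: len(v) for s, v in specific.items()}

    # --- EMT score ----------------------------------------------------------
    emt_sets = None
    if cfg.gmt_path:
        sets = sig.read_gmt(cfg.gmt_path)
        emt_sets = (sets.get("epithelial", []), sets.get("mesenchymal", []))
    elif truth is not None:
        emt_sets = truth.emt_sets
    if emt_sets and emt_sets[0] and emt_sets[1]:
        epi, mes = emt_sets
        table = sig.signature_score(matrix, mes, epi)
        table.scores.rename("emt_score").to_csv(out / "emt_scores.tsv", sep="\t")
        comparison = sig.compare_phase_scores(table, split, design, cfg.compartment)
        report["emt"] = {
            "coverage": table.coverage,
            "mean_pre": comparison.mean_pre,
            "mean_post": comparison.mean_post,
            "difference": comparison.difference,
            "p_value": comparison.p_value,
            "test": comparison.test,
        }

    # --- panel --------------------------------------------------------------
    X, y, feat_ids, _ = phase_feature_matrix(
        matrix, design, split, cfg.compartment, min_obs_frac=0.8, impute=True
    )
    bench = benchmark_learners(
        X, y, k_folds=cfg.panel_folds, repeats=cfg.benchmark_repeats, seed=cfg.seed
    )
    bench.results.to_csv(out / "benchmark.tsv", sep="\t")
    model = SVMRFEPanel(
        X, y, feat_ids, drop_frac=cfg.panel_drop_frac,
        k_folds=cfg.panel_folds, max_size=cfg.panel_max_size,
    )
    panel_res = model.fit(rule="fixed_k", k=cfg.panel_k, seed=cfg.seed)
    panel_res.cv_auc_by_size.to_csv(out / "panel_auc_by_size.tsv", sep="\t")
    pd.Series(panel_res.ranked_features, name="protein_id").to_csv(
        out / "panel_ranking.tsv", sep="\t", index_label="rank"
    )
    report["panel"] = {
        "selected": panel_res.selected_panel,
        "cv_auc": panel_res.final_auc,
        "benchmark_best": bench.results["mean_auc"].idxmax(),
        "n_features_used": len(feat_ids),
    }

    # --- crosstalk ----------------------------------------------------------
    pair_table = None
    if cfg.pair_table_path:
        pair_table = ct.read_pair_table(cfg.pair_table_path)
    elif truth is not None:
        pair_table = _toy_pair_table(matrix, cfg.seed)
        pair_table.to_csv(out / "pair_table_synthetic.tsv", sep="\t", index=False)
    stage_ok = all(
        design.group(cfg.crosstalk_stage, c) for c in ("L", "N")
    )
    if pair_table is not None and stage_ok:
        edges = ct.crosstalk_network(
            matrix, design, pair_table, cfg.crosstalk_stage,
            cfg.min_detect_frac, cfg.crosstalk_top_n,
        )
        ct.edges_to_frame(edges).to_csv(out / "crosstalk_edges.tsv", sep="\t",
                                        index=False)
        report["crosstalk"] = {
            "stage": cfg.crosstalk_stage,
            "n_edges": len(edges),
            "top_edge": (
                {"ligand": edges[0].ligand, "receptor": edges[0].receptor,
                 "direction": edges[0].direction, "score": edges[0].score}
                if edges else None
            ),
        }

    _write_report(report, out)
    return report


def _toy_pair_table(matrix: ExpressionMatrix, seed: int) -> pd.DataFrame:
    """Synthetic ligand-receptor annotation over the matrix's own proteins."""
    rng = np.random.default_rng(seed)
    ids = matrix.protein_ids
    n_pairs = min(50, len(ids) // 2)
    chosen = rng.choice(len(ids), size=2 * n_pairs, replace=False)
    return pd.DataFrame(
        {
            "ligand": [ids[i] for i in chosen[:n_pairs]],
            "receptor": [ids[i] for i in chosen[n_pairs:]],
        }
    )


def _write_report(report: dict[str, Any], out: Path) -> None:
    report["report_path"] = str(out / "report.json")
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
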