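"""Ligand-receptor crosstalk ranking between the two tissue compartments.

A deterministic, rank-based reimplementation of the iTALK-style network: at a
chosen stage, a ligand-receptor pair scores the product of the ligand's
expression rank in the source compartment and the receptor's rank in the
target compartment (ranks rescaled to (0, 1], so 1.0 means both are the
top-expressed proteins). Both directions (L -> N and N -> L) are evaluated.
This captures the ranking role of the original tool without porting its
internals; scores are invariant under any strictly increasing transform of
expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, StageDesign


@dataclass(frozen=True)
class LREdge:
    ligand: str
    receptor: str
    direction: str              # "L->N" | "N->L"
    score: float
    ligand_mean: float
    receptor_mean: float


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Ligand-receptor pair TSV with columns ``ligand`` and ``receptor``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ligand", "receptor"}.issubset(df.columns):
        raise ValueError(
            f"pair table needs columns ligand, receptor; got {list(df.columns)}"
        )
    return df


def expressed_proteins(
    matrix: ExpressionMatrix,
    design: StageDesign,
    compartment: str,
    stage: str,
    min_detect_frac: float = 0.5,
) -> pd.Series:
    """Proteins observed in >= min_detect_frac of the group; mean expression.

    Returns a Series (protein id -> mean over non-missing values) restricted
    to the expressed set.
    """
    ids = design.group(stage, compartment)
    if not ids:
        raise ValueError(f"no samples for ({stage}, {compartment})")
    sub = matrix.values[ids]
    frac = sub.notna().sum(axis=1) / len(ids)
    expressed = frac >= min_detect_frac
    return sub.loc[expressed].mean(axis=1, skipna=True)


def score_lr_pairs(
    expr_source: pd.Series,
    expr_target: pd.Series,
    pair_table: pd.DataFrame,
    direction: str,
    top_n: int = 50,
) -> list[LREdge]:
    """Rank-product scores for pairs expressed in source (ligand) and target
    (receptor); sorted by score descending, ties broken lexicographically."""
    if pair_table.empty:
        raise ValueError("empty ligand-receptor pair table")
    src_rank = pd.Series(
        rankdata(expr_source.to_numpy()) / len(expr_source), index=expr_source.index
    )
    tgt_rank = pd.Series(
        rankdata(expr_target.to_numpy()) / len(expr_target), index=expr_target.index
    )
    edges: list[LREdge] = []
    for lig, rec in pair_table[["ligand", "receptor"]].itertuples(index=False):
        if lig in src_rank.index and rec in tgt_rank.index:
            edges.append(
                LREdge(
                    ligand=lig,
                    receptor=rec,
                    direction=direction,
                    score=float(src_rank[lig] * tgt_rank[rec]),
                    ligand_mean=float(expr_source[lig]),
                    receptor_mean=float(expr_target[rec]),
                )
            )
    edges.sort(key=lambda e: (-e.score, e.ligand, e.receptor))
    return edges[:top_n]


def crosstalk_network(
    matrix: ExpressionMatrix,
    design: StageDesign,
    pair_table: pd.DataFrame,
    stage: str = "MOD",
    min_detect_frac: float = 0.5,
    top_n: int = 50,
) -> list[LREdge]:
    """Both-direction L/N crosstalk edges at one stage."""
    expr = {
        c: expressed_proteins(matrix, design, c, stage, min_detect_frac)
        for c in ("L", "N")
    }
    edges = score_lr_pairs(expr["L"], expr["N"], pair_table, "L->N", top_n)
    edges += score_lr_pairs(expr["N"], expr["L"], pair_table, "N->L", top_n)
    return edges


def edges_to_frame(edges: Sequence[LREdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges])


def graph_export(edges: Sequence[LREdge]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge table) for downstream graph tooling.

    Nodes carry their role(s) and compartment; an edge's source compartment is
    the first letter of its direction.
    """
    nodes: dict[tuple[str, str], set[str]] = {}
    for e in edges:
        src, tgt = e.direction.split("->")
        nodes.setdefault((e.ligand, src), set()).add("ligand")
        nodes.setdefault((e.receptor, tgt), set()).add("receptor")
    node_df = pd.DataFrame(
        [
            {"protein_id": pid, "compartment": comp,
             "roles": "+".join(sorted(roles))}
            for (pid, comp), roles in sorted(nodes.items())
        ]
    )
    return node_df, edges_to_frame(edges)
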