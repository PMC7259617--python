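"""Differentiation-tree transcription-factor prioritization.

Each internal node of a rooted differentiation tree is a cell-fate decision:
for every child, the cell types under that child form the fate set and the
cell types under its siblings the contrast set. A TF is a candidate driver of
a fate when, on mean raw read counts per cell type, (1) the average over fate
cell types is at least ``fold_avg`` times the average over contrast cell
types, (2) every fate cell type's mean exceeds ``min_count`` reads (guarding
against low-count noise), and (3) the lowest fate cell type is at least
``fold_minmax`` times the highest contrast cell type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "FateDecision",
    "TFCandidate",
    "read_tree",
    "enumerate_fate_decisions",
    "mean_counts_by_celltype",
    "candidate_tfs",
    "prioritize_tfs",
]


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class FateDecision:
    decision_id: str
    fate: frozenset[str]
    contrast: frozenset[str]


@dataclass
class TFCandidate:
    tf: str
    decision_id: str
    avg_fold: float            # mean-of-fate-means / mean-of-contrast-means
    min_fate_mean: float
    max_contrast_mean: float
    pass_avg_fold: bool
    pass_min_count: bool
    pass_minmax_fold: bool

    @property
    def is_candidate(self) -> bool:
        return self.pass_avg_fold and self.pass_min_count and self.pass_minmax_fold


def _parse(node: dict) -> TreeNode:
    name = node.get("name", "")
    children = [_parse(c) for c in node.get("children", [])]
    # deterministic traversal: order children by their smallest leaf label
    children.sort(key=lambda c: min(c.leaves()))
    if len(children) == 1:
        raise ValueError(f"unary internal node {name!r}")
    return TreeNode(name=name, children=children)


def read_tree(path_or_dict) -> TreeNode:
    """Load a differentiation tree from JSON ({"name": ..., "children": [...]})."""
    if isinstance(path_or_dict, dict):
        return _parse(path_or_dict)
    with open(path_or_dict) as fh:
        return _parse(json.load(fh))


def enumerate_fate_decisions(tree: TreeNode) -> list[FateDecision]:
    """One decision per (internal node, child): fate = child's leaves,
    contrast = the sibling children's leaves. Pre-order, children sorted."""
    if tree.is_leaf:
        raise ValueError("tree has no branch point")
    decisions: list[FateDecision] = []

    def visit(node: TreeNode) -> None:
        if node.is_leaf:
            return
        for child in node.children:
            fate = frozenset(child.leaves())
            contrast = frozenset(
                l for sib in node.children if sib is not child for l in sib.leaves()
            )
            label = child.name or "+".join(sorted(fate))
            parent = node.name or "node"
            decisions.append(
                FateDecision(
                    decision_id=f"{parent}:{label}", fate=fate, contrast=contrast
                )
            )
        for child in node.children:
            visit(child)

    visit(tree)
    return decisions


def mean_counts_by_celltype(cm) -> pd.DataFrame:
    """Gene x cell-type matrix of mean raw read counts over each type's samples."""
    ct = cm.metadata["cell_type"]
    return cm.counts.T.groupby(ct).mean().T


def candidate_tfs(
    mean_table: pd.DataFrame,
    tf_list,
    decision: FateDecision,
    fold_avg: float = 15.0,
    min_count: float = 100.0,
    fold_minmax: float = 4.0,
    avg_mode: str = "of-means",
    celltype_sizes: pd.Series | None = None,
) -> list[TFCandidate]:
    """Evaluate the three fate criteria for each TF at one decision.

    ``avg_mode='of-means'`` (default) averages the per-cell-type means on each
    side before taking the ratio; ``'pooled'`` weights cell types by their
    sample counts (requires ``celltype_sizes``). A contrast mean of zero with
    a positive fate mean passes the ratio criteria; both zero fails.
    Returns the full per-TF table; candidates are rows passing all three.
    """
    tf_list = list(tf_list)
    if not tf_list:
        raise ValueError("empty tf_list")
    missing = [t for t in tf_list if t not in mean_table.index]
    if missing:
        raise KeyError(f"TF {missing[0]!r} not in the mean-count table")
    for ct in decision.fate | decision.contrast:
        if ct not in mean_table.columns:
            raise KeyError(f"cell type {ct!r} absent from the mean-count table")
    fate_cols = sorted(decision.fate)
    contrast_cols = sorted(decision.contrast)

    def side_avg(sub: pd.DataFrame, cols: list[str]) -> pd.Series:
        if avg_mode == "of-means":
            return sub[cols].mean(axis=1)
        if avg_mode == "pooled":
            if celltype_sizes is None:
                raise ValueError("pooled averaging needs celltype_sizes")
            w = celltype_sizes.loc[cols].to_numpy(dtype=float)
            return (sub[cols] * w).sum(axis=1) / w.sum()
        raise ValueError("avg_mode must be 'of-means' or 'pooled'")

    sub = mean_table.loc[tf_list]
    fate_avg = side_avg(sub, fate_cols)
    contrast_avg = side_avg(sub, contrast_cols)
    min_fate = sub[fate_cols].min(axis=1)
    max_contrast = sub[contrast_cols].max(axis=1)

    out: list[TFCandidate] = []
    for tf in tf_list:
        fa, ca = float(fate_avg[tf]), float(contrast_avg[tf])
        mf, mc = float(min_fate[tf]), float(max_contrast[tf])
        if ca == 0:
            pass1 = fa > 0
            ratio = np.inf if fa > 0 else 0.0
        else:
            ratio = fa / ca
            pass1 = ratio >= fold_avg
        pass2 = bool((sub.loc[tf, fate_cols] > min_count).all())
        pass3 = (mf > 0) if mc == 0 else (mf >= fold_minmax * mc)
        out.append(
            TFCandidate(
                tf=tf, decision_id=decision.decision_id, avg_fold=ratio,
                min_fate_mean=mf, max_contrast_mean=mc,
                pass_avg_fold=bool(pass1), pass_min_count=pass2,
                pass_minmax_fold=bool(pass3),
            )
        )
    return out


def prioritize_tfs(
    mean_table: pd.DataFrame,
    tf_list,
    tree: TreeNode,
    fold_avg: float = 15.0,
    min_count: float = 100.0,
    fold_minmax: float = 4.0,
    avg_mode: str = "of-means",
) -> pd.DataFrame:
    """Candidate table over all fate decisions of a tree (candidates only)."""
    rows = []
    for decision in enumerate_fate_decisions(tree):
        for cand in candidate_tfs(
            mean_table, tf_list, decision, fold_avg=fold_avg,
            min_count=min_count, fold_minmax=fold_minmax, avg_mode=avg_mode,
        ):
            if cand.is_candidate:
                rows.append(
                    {"decision": cand.decision_id, "tf": cand.tf,
                     "avg_fold": cand.avg_fold,
                     "min_fate_mean": cand.min_fate_mean,
                     "max_contrast_mean": cand.max_contrast_mean}
                )
    return pd.DataFrame(
        rows, columns=["decision", "tf", "avg_fold", "min_fate_mean",
                       "max_contrast_mean"]
    )
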