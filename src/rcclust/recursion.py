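"""Recursive divisive driver.

Starting from all samples, each node re-selects variant features within its
own samples, z-scales them, runs the eight-process consensus vote over
k = 2..maxK, and either splits into the voted number of children or becomes
a leaf.  A branch terminates when it holds fewer than ``min_samples``
samples or when no k is admissible (vote = 0).  Leaves define the final
clusters; a sample's final label is the dot-joined path of its per-level
cluster indices (e.g. ``"2.1.3"``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config_io import ExpressionMatrix, RCCConfig
from .consensus import parameter_grid
from .kselect import compute_maxK, select_optimal_k
from .preprocess import select_variant_features, zscore_rows

__all__ = [
    "ClusterNode",
    "ClusterTree",
    "rcc_run",
    "evaluate_split",
    "should_terminate",
    "final_labels",
    "apply_cutoff",
]

logger = logging.getLogger(__name__)

TERMINATION_REASONS = ("none", "too_few_samples", "k_zero", "cutoff")


@dataclass
class ClusterNode:
    level: int  # depth; root = 0, first split produces level-1 nodes
    path_label: str  # dotted label, "" for the root
    sample_ids: np.ndarray
    optimal_k: int = 0
    children: List["ClusterNode"] = field(default_factory=list)
    termination_reason: str = "none"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "path_label": self.path_label,
            "sample_ids": list(map(str, self.sample_ids)),
            "optimal_k": self.optimal_k,
            "termination_reason": self.termination_reason,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterNode":
        node = cls(
            level=d["level"],
            path_label=d["path_label"],
            sample_ids=np.asarray(d["sample_ids"], dtype=object),
            optimal_k=d["optimal_k"],
            termination_reason=d["termination_reason"],
        )
        node.children = [cls.from_dict(c) for c in d["children"]]
        return node


@dataclass
class ClusterTree:
    root: ClusterNode
    config: Optional[RCCConfig] = None

    @property
    def depth(self) -> int:
        def _d(node: ClusterNode) -> int:
            if node.is_leaf:
                return node.level
            return max(_d(c) for c in node.children)

        return _d(self.root)

    def leaves(self) -> List[ClusterNode]:
        out: List[ClusterNode] = []

        def _walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                _walk(c)

        _walk(self.root)
        return out

    def final_labels(self) -> pd.Series:
        return final_labels(self)

    def assignments_frame(self) -> pd.DataFrame:
        """Per-level assignment table: one row per sample, one column per
        level (blank where the branch terminated earlier) plus ``final``."""
        depth = max(self.depth, 1)
        samples = pd.Index(self.root.sample_ids)
        data = {f"level{lv}": pd.Series("", index=samples, dtype=object)
                for lv in range(1, depth + 1)}

        def _walk(node: ClusterNode) -> None:
            if node.level >= 1:
                parts = node.path_label.split(".")
                for lv in range(1, node.level + 1):
                    col = data[f"level{lv}"]
                    col.loc[list(node.sample_ids)] = ".".join(parts[:lv])
            for c in node.children:
                _walk(c)

        _walk(self.root)
        frame = pd.DataFrame(data, index=samples)
        finals = self.final_labels()
        frame["final"] = finals.reindex(samples)
        if depth == 0 or self.root.is_leaf:
            frame["final"] = "1"
        return frame

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.root.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path, config: Optional[RCCConfig] = None) -> "ClusterTree":
        with open(path) as fh:
            return cls(root=ClusterNode.from_dict(json.load(fh)), config=config)


def should_terminate(n_samples: int, optimal_k: Optional[int], config: RCCConfig) -> str:
    """Termination reason for a node, or ``"none"``.

    A node with fewer than ``min_samples`` samples (strict) is not
    clustered; a vote of 0 (including maxK < 2) terminates the branch.
    """
    if n_samples < config.min_samples:
        return "too_few_samples"
    if optimal_k is not None and optimal_k == 0:
        return "k_zero"
    return "none"


def _order_children(sample_ids: np.ndarray, labels: np.ndarray) -> List[np.ndarray]:
    """Child sample sets ordered by size descending, ties by smallest id."""
    groups = []
    for lab in np.unique(labels):
        members = sample_ids[labels == lab]
        groups.append(members)
    groups.sort(key=lambda m: (-len(m), min(map(str, m))))
    return groups


def _cluster_node(
    X: ExpressionMatrix,
    node: ClusterNode,
    config: RCCConfig,
    node_seed: Optional[int],
) -> None:
    n = len(node.sample_ids)
    reason = should_terminate(n, None, config)
    if reason != "none":
        node.termination_reason = reason
        logger.info("node %s: N=%d -> %s", node.path_label or "<root>", n, reason)
        return
    max_k = compute_maxK(n)
    if max_k < 2:
        node.termination_reason = "k_zero"
        logger.info("node %s: N=%d, maxK=%d -> k_zero", node.path_label or "<root>", n, max_k)
        return
    X_node = X.subset(sample_ids=node.sample_ids)
    sel = select_variant_features(
        X_node,
        pct=config.resolved_pct(),
        data_type=config.data_type,
        bulk_min_features=config.bulk_min_features,
    )
    X_sel = X_node.subset(gene_ids=sel.selected_gene_ids)
    Z = zscore_rows(X_sel).values.T  # samples x features
    settings = parameter_grid(node_seed, repeats=config.repeats_per_process)
    decision, labels, _ = select_optimal_k(Z, X_sel, settings, config, max_k)
    node.optimal_k = decision.optimal_k
    logger.info(
        "node %s: N=%d, maxK=%d, vote=%d",
        node.path_label or "<root>", n, max_k, decision.optimal_k,
    )
    if decision.optimal_k == 0:
        node.termination_reason = "k_zero"
        return
    groups = _order_children(node.sample_ids, labels)
    ss = np.random.SeedSequence(node_seed)
    child_seeds = ss.generate_state(len(groups) + 1)[1:] % (2**31)
    for i, members in enumerate(groups, start=1):
        label = f"{node.path_label}.{i}" if node.path_label else str(i)
        child = ClusterNode(
            level=node.level + 1, path_label=label, sample_ids=members
        )
        node.children.append(child)
        _cluster_node(X, child, config, int(child_seeds[i - 1]))


def evaluate_split(X: ExpressionMatrix, config: RCCConfig, seed: Optional[int] = None):
    """One level of the pipeline without recursing: feature selection,
    scaling, the eight-process consensus vote.

    Returns ``(decision, labels)`` where ``labels`` is the realizing
    consensus partition at the voted k (None when the vote is 0).  Useful
    for diagnosing what the first split of a dataset would be.
    """
    if seed is None:
        seed = config.seed
    node_seed = None
    if seed is not None:
        node_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    max_k = compute_maxK(X.n_samples)
    from .kselect import KDecision

    if X.n_samples < config.min_samples or max_k < 2:
        return KDecision(best_ks_per_process=[], optimal_k=0), None
    sel = select_variant_features(
        X,
        pct=config.resolved_pct(),
        data_type=config.data_type,
        bulk_min_features=config.bulk_min_features,
    )
    X_sel = X.subset(gene_ids=sel.selected_gene_ids)
    Z = zscore_rows(X_sel).values.T
    settings = parameter_grid(node_seed, repeats=config.repeats_per_process)
    decision, labels, _ = select_optimal_k(Z, X_sel, settings, config, max_k)
    return decision, labels


def rcc_run(X: ExpressionMatrix, config: RCCConfig) -> ClusterTree:
    """Run the full recursive consensus clustering on an expression matrix.

    Deterministic given ``config.seed``; per-node seeds are derived from it
    along the tree structure so that sibling subtrees are independent.
    """
    root = ClusterNode(level=0, path_label="", sample_ids=np.asarray(X.sample_ids))
    root_seed = None
    if config.seed is not None:
        root_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
    _cluster_node(X, root, config, root_seed)
    tree = ClusterTree(root=root, config=config)
    if config.cutoff_level is not None:
        tree = apply_cutoff(tree, config.cutoff_level)
    return tree


def final_labels(tree: ClusterTree) -> pd.Series:
    """Sample -> dotted leaf label; a tree that never split labels all "1"."""
    labels: Dict[str, str] = {}
    for leaf in tree.leaves():
        lab = leaf.path_label or "1"
        for s in leaf.sample_ids:
            labels[s] = lab
    series = pd.Series(labels, name="final")
    return series.reindex(pd.Index(tree.root.sample_ids))


def apply_cutoff(tree: ClusterTree, level: int) -> ClusterTree:
    """Truncate the tree below ``level``; deeper splits are discarded."""
    if level < 1:
        raise ValueError("cutoff level must be >= 1")

    def _copy(node: ClusterNode) -> ClusterNode:
        new = ClusterNode(
            level=node.level,
            path_label=node.path_label,
            sample_ids=node.sample_ids,
            optimal_k=node.optimal_k,
            termination_reason=node.termination_reason,
        )
        if node.level >= level:
            if not node.is_leaf:
                new.termination_reason = "cutoff"
                new.optimal_k = 0
            return new
        new.children = [_copy(c) for c in node.children]
        return new

    return ClusterTree(root=_copy(tree.root), config=tree.config)
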