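"""Per-node feature selection and scaling.

At every recursion level the pipeline re-selects the top n% most variant
genes *within the node's samples* and z-scales each selected gene.  Feature
sets therefore change between a parent and its children, which is what lets
the recursion uncover sub-structure that globally variant genes miss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config_io import ExpressionMatrix, InputError

__all__ = ["FeatureSelection", "select_variant_features", "zscore_rows", "apply_gene_filter"]


@dataclass
class FeatureSelection:
    """Outcome of variance-based feature selection."""

    selected_gene_ids: np.ndarray  # ordered by descending variance
    variance_rank: pd.Series  # rank (1 = most variant) per input gene
    pct_used: float
    floor_applied: bool


def apply_gene_filter(X: ExpressionMatrix, gene_ids: Sequence[str]) -> ExpressionMatrix:
    """Restrict the matrix to a user-supplied gene list (e.g. protein-coding).

    Genes in the list but absent from the matrix are ignored; matrix order
    is preserved.
    """
    keep = pd.Index(X.gene_ids).isin(set(gene_ids))
    if keep.sum() < 2:
        raise InputError("gene filter leaves fewer than 2 genes")
    return ExpressionMatrix(
        X.values[keep, :].copy(), X.gene_ids[keep], X.sample_ids
    )


def select_variant_features(
    X: ExpressionMatrix,
    pct: float,
    data_type: str = "bulk",
    bulk_min_features: int = 500,
) -> FeatureSelection:
    """Select the top ``pct`` % most variant genes of the current subset.

    Genes are ranked by sample variance (ddof=1) across the matrix columns,
    descending, ties broken lexicographically by gene id.  For bulk data the
    selection is floored at ``bulk_min_features`` genes (or all genes if the
    matrix is smaller); for single-cell data no floor applies.  Genes with
    zero variance are never selected.
    """
    if not (0 < pct <= 100):
        raise InputError("pct must be in (0, 100]")
    variances = X.values.var(axis=1, ddof=1)
    # stable ordering: descending variance, ties by gene id
    order = np.lexsort((X.gene_ids.astype(str), -variances))
    rank = pd.Series(
        np.empty(len(order), dtype=int), index=pd.Index(X.gene_ids), name="rank"
    )
    rank.iloc[order] = np.arange(1, len(order) + 1)

    n_nonzero = int((variances > 0).sum())
    if n_nonzero < 2:
        raise InputError("fewer than 2 genes with nonzero variance")
    n_sel = math.ceil(pct / 100.0 * X.n_genes)
    floor_applied = False
    if data_type == "bulk" and n_sel < bulk_min_features:
        n_sel = min(bulk_min_features, X.n_genes)
        floor_applied = True
    n_sel = min(n_sel, n_nonzero)
    selected = X.gene_ids[order[:n_sel]]
    return FeatureSelection(
        selected_gene_ids=np.asarray(selected, dtype=object),
        variance_rank=rank,
        pct_used=pct,
        floor_applied=floor_applied,
    )


def zscore_rows(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene (row) to mean 0, sd 1 (sample sd, ddof=1)."""
    mu = X.values.mean(axis=1, keepdims=True)
    sigma = X.values.std(axis=1, ddof=1, keepdims=True)
    if (sigma == 0).any():
        bad = X.gene_ids[(sigma == 0).ravel()]
        raise InputError(f"zero-variance gene reached scaling: {list(bad[:5])}")
    return ExpressionMatrix((X.values - mu) / sigma, X.gene_ids, X.sample_ids)
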