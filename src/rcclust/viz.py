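"""Diagnostic plots: tracking plot, annotation overlap, marker heatmap,
consensus-of-runs heatmap.

Every plot function first builds its underlying numeric matrix and writes
it as a CSV sidecar next to the PDF, so tests (and users) can assert on
data rather than pixels.  Styling follows the published figure legends:
white-to-red proportion/count scales with grey marking branches that were
not subdivided further.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

from .config_io import ExpressionMatrix
from .recursion import ClusterTree

__all__ = [
    "tracking_plot_model",
    "tracking_plot",
    "cluster_annotation_matrix",
    "cluster_annotation_plot",
    "gene_marker_heatmap",
    "runs_consensus_matrix",
    "runs_consensus_heatmap",
]

WHITE_RED = LinearSegmentedColormap.from_list("white_red", ["white", "red"])
GREY = (0.6, 0.6, 0.6)


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(".csv")


def _sample_order(tree: ClusterTree) -> List[str]:
    frame = tree.assignments_frame()
    return list(frame.sort_values("final", kind="stable").index)


def tracking_plot_model(
    tree: ClusterTree,
    markers: pd.DataFrame,
    annotation: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Data behind the tracking plot, on a shared sample order.

    Returns ``marker_panel`` (levels x samples marker counts, NaN where the
    sample's branch was not subdivided at that level), ``level_panel``
    (levels x samples cluster labels, "" once terminated) and
    ``annotation_panel`` (attributes x samples), all with identical
    columns.
    """
    order = _sample_order(tree)
    frame = tree.assignments_frame().loc[order]
    depth = max(tree.depth, 1)
    counts = (
        markers.groupby(["level", "cluster_label"]).size()
        if len(markers)
        else pd.Series(dtype=int)
    )
    marker_panel = pd.DataFrame(
        np.nan, index=[f"level{lv}" for lv in range(1, depth + 1)], columns=order
    )
    level_panel = pd.DataFrame(
        "", index=[f"level{lv}" for lv in range(1, depth + 1)], columns=order
    )
    for lv in range(1, depth + 1):
        col = frame[f"level{lv}"]
        level_panel.loc[f"level{lv}"] = col.to_numpy()
        for sample, lab in col.items():
            if lab == "":
                continue  # grey: branch not subdivided at this level
            n = counts.get((lv, lab), 0) if len(counts) else 0
            marker_panel.loc[f"level{lv}", sample] = float(n)
    panels = {"marker_panel": marker_panel, "level_panel": level_panel}
    if annotation is not None:
        panels["annotation_panel"] = annotation.reindex(order).T
    return panels


def tracking_plot(
    tree: ClusterTree,
    markers: pd.DataFrame,
    annotation: Optional[pd.DataFrame],
    path,
) -> Dict[str, pd.DataFrame]:
    """Render the stacked tracking plot; writes PDF + marker-panel CSV."""
    panels = tracking_plot_model(tree, markers, annotation)
    marker_panel = panels["marker_panel"]
    level_panel = panels["level_panel"]
    n_rows = len(marker_panel) + len(level_panel) + (
        len(panels.get("annotation_panel", [])) if annotation is not None else 0
    )
    fig, axes = plt.subplots(
        3 if annotation is not None else 2,
        1,
        figsize=(10, 1.2 + 0.45 * n_rows),
        gridspec_kw={
            "height_ratios": [len(marker_panel), len(level_panel)]
            + ([len(panels["annotation_panel"])] if annotation is not None else [])
        },
    )
    axes = np.atleast_1d(axes)

    vmax = np.nanmax(marker_panel.to_numpy()) if np.isfinite(
        np.nanmax(marker_panel.to_numpy(), initial=np.nan)
    ) else 1.0
    cmap = WHITE_RED.copy()
    cmap.set_bad(GREY)
    axes[0].imshow(
        np.ma.masked_invalid(marker_panel.to_numpy(dtype=float)),
        aspect="auto",
        cmap=cmap,
        vmin=0,
        vmax=max(vmax, 1.0),
        interpolation="nearest",
    )
    axes[0].set_yticks(range(len(marker_panel)), marker_panel.index)
    axes[0].set_xticks([])
    axes[0].set_title("marker counts per cluster (grey = not subdivided)")

    codes = np.zeros(level_panel.shape, dtype=float)
    for i, (_, row) in enumerate(level_panel.iterrows()):
        cats = {lab: j for j, lab in enumerate(sorted(set(row) - {""}))}
        codes[i] = [cats.get(lab, np.nan) for lab in row]
    cmap2 = plt.get_cmap("tab20").copy()
    cmap2.set_bad(GREY)
    axes[1].imshow(
        np.ma.masked_invalid(codes), aspect="auto", cmap=cmap2, interpolation="nearest"
    )
    axes[1].set_yticks(range(len(level_panel)), level_panel.index)
    axes[1].set_xticks([])
    axes[1].set_title("cluster assignment per level")

    if annotation is not None:
        ann = panels["annotation_panel"]
        codes = np.zeros(ann.shape, dtype=float)
        for i, (_, row) in enumerate(ann.iterrows()):
            cats = {lab: j for j, lab in enumerate(sorted(set(row)))}
            codes[i] = [cats[lab] for lab in row]
        axes[2].imshow(codes, aspect="auto", cmap="tab20", interpolation="nearest")
        axes[2].set_yticks(range(len(ann)), ann.index)
        axes[2].set_xticks([])
        axes[2].set_title("annotation")
    plt.tight_layout()
    plt.savefig(path)
    plt.close(fig)
    marker_panel.to_csv(_sidecar(path))
    return panels


def cluster_annotation_matrix(
    labels: pd.Series, attribute: pd.Series
) -> pd.DataFrame:
    """P(attribute value | cluster): rows = clusters, columns = values."""
    labels = pd.Series(labels).astype(str)
    attribute = pd.Series(attribute).astype(str).reindex(labels.index)
    table = pd.crosstab(labels, attribute)
    return table.div(table.sum(axis=1), axis=0)


def cluster_annotation_plot(
    labels: pd.Series,
    annotation: pd.DataFrame,
    path,
) -> Dict[str, pd.DataFrame]:
    """White-to-red heatmap of attribute proportions per cluster, one panel
    per attribute column; writes PDF + one CSV sidecar per attribute."""
    if annotation is None or annotation.shape[1] == 0:
        raise ValueError("annotation required for the cluster annotation plot")
    matrices = {}
    n_attr = annotation.shape[1]
    fig, axes = plt.subplots(
        1, n_attr, figsize=(4.5 * n_attr, 3.5), squeeze=False
    )
    for i, col in enumerate(annotation.columns):
        mat = cluster_annotation_matrix(labels, annotation[col])
        matrices[col] = mat
        ax = axes[0, i]
        im = ax.imshow(
            mat.to_numpy(), cmap=WHITE_RED, vmin=0, vmax=1, aspect="auto",
            interpolation="nearest",
        )
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90)
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_title(col)
        fig.colorbar(im, ax=ax, fraction=0.046)
    plt.tight_layout()
    plt.savefig(path)
    plt.close(fig)
    combined = pd.concat(matrices, names=["attribute", "cluster"])
    combined.to_csv(_sidecar(path))
    return matrices


def gene_marker_heatmap(
    X: ExpressionMatrix,
    markers: pd.DataFrame,
    labels: pd.Series,
    path,
) -> Optional[pd.DataFrame]:
    """Z-scored expression of marker genes, rows/columns grouped by cluster.

    Writes PDF + CSV of the plotted matrix; with no markers, an
    empty-notice plot is emitted and None returned.
    """
    labels = pd.Series(labels).astype(str)
    if markers is None or len(markers) == 0:
        fig, ax = plt.subplots(figsize=(5, 2))
        ax.text(0.5, 0.5, "no marker genes found", ha="center", va="center")
        ax.axis("off")
        plt.savefig(path)
        plt.close(fig)
        return None
    m = markers.sort_values(["cluster_label", "fdr"]).drop_duplicates("gene_id")
    sample_order = list(labels.sort_values(kind="stable").index)
    sub = X.subset(
        gene_ids=m["gene_id"].to_numpy(object),
        sample_ids=np.asarray(sample_order, dtype=object),
    )
    vals = sub.values
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    frame = pd.DataFrame(z, index=sub.gene_ids, columns=sub.sample_ids)
    fig, ax = plt.subplots(figsize=(8, max(3, 0.1 * len(frame))))
    im = ax.imshow(
        frame.to_numpy(), aspect="auto", cmap="RdBu_r",
        vmin=-3, vmax=3, interpolation="nearest",
    )
    # cluster boundary bars
    lab_arr = labels.loc[sample_order].to_numpy()
    bounds = np.nonzero(lab_arr[1:] != lab_arr[:-1])[0]
    for b in bounds:
        ax.axvline(b + 0.5, color="black", lw=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlabel("samples (grouped by cluster)")
    ax.set_ylabel("marker genes (grouped by owning cluster)")
    fig.colorbar(im, ax=ax, fraction=0.03)
    plt.tight_layout()
    plt.savefig(path)
    plt.close(fig)
    frame.to_csv(_sidecar(path))
    return frame


def runs_consensus_matrix(label_sets: Sequence[pd.Series]) -> pd.DataFrame:
    """Fraction of runs in which each sample pair shares a final cluster."""
    if len(label_sets) < 2:
        raise ValueError("need >= 2 runs")
    series = [pd.Series(s).astype(str) for s in label_sets]
    index = series[0].index
    for s in series[1:]:
        if not index.equals(s.index):
            raise ValueError("runs cover different sample sets")
    n = len(index)
    acc = np.zeros((n, n))
    for s in series:
        arr = s.to_numpy()
        acc += (arr[:, None] == arr[None, :]).astype(float)
    return pd.DataFrame(acc / len(series), index=index, columns=index)


def runs_consensus_heatmap(label_sets: Sequence[pd.Series], path) -> pd.DataFrame:
    """Heatmap of the consensus-of-runs matrix; writes PDF + CSV."""
    mat = runs_consensus_matrix(label_sets)
    order = list(pd.Series(label_sets[0]).astype(str).sort_values(kind="stable").index)
    mat = mat.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat.to_numpy(), cmap=WHITE_RED, vmin=0, vmax=1,
                   interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("consensus of repeated runs")
    fig.colorbar(im, ax=ax, fraction=0.046)
    plt.tight_layout()
    plt.savefig(path)
    plt.close(fig)
    mat.to_csv(_sidecar(path))
    return mat
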