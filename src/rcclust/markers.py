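"""Post-clustering statistics: markers, ssGSEA, enrichment, ARI, survival.

Marker genes are found per cluster per level by a one-vs-rest two-sided
Wilcoxon rank-sum test on the (log2-scale, unscaled) expression values with
Benjamini-Hochberg correction within each comparison; a marker must pass
FDR < 0.01 and show a mean log2 difference > 1.  ssGSEA scores summarize
named gene sets per sample with the weighted running-sum statistic.
Cluster-attribute association uses Fisher's exact test; partition agreement
uses the adjusted Rand index; survival differences between clusters use
Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import itertools
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .config_io import ExpressionMatrix
from .recursion import ClusterTree

__all__ = [
    "find_markers",
    "tree_markers",
    "ssgsea_scores",
    "fisher_enrichment",
    "adjusted_rand_index",
    "cluster_survival",
]

MARKER_COLUMNS = ["gene_id", "cluster_label", "level", "log2_fold_change", "p_value", "fdr"]


def find_markers(
    X: ExpressionMatrix,
    labels: pd.Series,
    level: int = 1,
    fdr: float = 0.01,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Upregulated marker genes per cluster (one-vs-rest rank-sum + BH).

    ``X`` must hold log2-scale (not z-scored) values so the mean difference
    is a log2 fold change.  Returns a table with columns
    ``gene_id, cluster_label, level, log2_fold_change, p_value, fdr``
    sorted by fdr then descending fold change.
    """
    labels = pd.Series(labels).astype(str)
    labels = labels.reindex(pd.Index(X.sample_ids))
    uniq = sorted(labels.dropna().unique())
    if len(uniq) < 2:
        raise ValueError("marker detection needs >= 2 clusters")
    rows = []
    values = X.values
    lab_arr = labels.to_numpy()
    for cl in uniq:
        mask = lab_arr == cl
        if mask.sum() < 2 or (~mask).sum() < 2:
            continue
        a = values[:, mask]
        b = values[:, ~mask]
        degenerate = (
            (a.min(axis=1) == a.max(axis=1))
            & (a.min(axis=1) == b.min(axis=1))
            & (b.min(axis=1) == b.max(axis=1))
        )
        with np.errstate(all="ignore"):
            stat = mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        pvals = np.where(degenerate, 1.0, np.nan_to_num(stat.pvalue, nan=1.0))
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        diff = a.mean(axis=1) - b.mean(axis=1)
        keep = (adjusted < fdr) & (diff > lfc)
        for i in np.nonzero(keep)[0]:
            rows.append(
                (X.gene_ids[i], cl, level, float(diff[i]), float(pvals[i]), float(adjusted[i]))
            )
    out = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    return out.sort_values(
        ["fdr", "log2_fold_change"], ascending=[True, False]
    ).reset_index(drop=True)


def tree_markers(
    X: ExpressionMatrix,
    tree: ClusterTree,
    fdr: float = 0.01,
    lfc: float = 1.0,
) -> pd.DataFrame:
    """Markers for every split in the tree (child vs siblings, per level)."""
    frames = []

    def _walk(node):
        if node.children:
            labels = pd.Series(
                {
                    s: child.path_label
                    for child in node.children
                    for s in child.sample_ids
                }
            )
            level = node.level + 1
            sub = X.subset(sample_ids=np.asarray(labels.index, dtype=object))
            frames.append(find_markers(sub, labels, level=level, fdr=fdr, lfc=lfc))
            for child in node.children:
                _walk(child)

    _walk(tree.root)
    if not frames:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _ssgsea_one(expr: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    # rank genes by expression, highest first; weight set members by rank^alpha
    order = np.argsort(-expr, kind="stable")
    ind = in_set[order]
    ranks = np.arange(len(expr), 0, -1, dtype=float)  # highest expression -> G
    w = ranks**exponent
    hit = np.where(ind, w, 0.0)
    p_in = np.cumsum(hit) / hit.sum()
    miss = (~ind).astype(float)
    p_out = np.cumsum(miss) / miss.sum()
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    X: ExpressionMatrix,
    gene_sets: Dict[str, Sequence[str]],
    exponent: float = 0.25,
) -> pd.DataFrame:
    """Single-sample gene-set enrichment scores (weighted running sum).

    Per sample, genes are ranked by expression (descending; ties keep the
    matrix gene order, so scores are deterministic); the score is the summed difference between the weighted
    cumulative fraction of set members (weight = rank value ** exponent)
    and the uniform cumulative fraction of non-members.  Genes absent from
    the matrix are dropped with a warning; an empty set is an error.
    Returns a long table ``sample_id, gene_set_name, enrichment_score``.
    """
    import warnings

    gene_index = pd.Index(X.gene_ids)
    rows = []
    for name, genes in gene_sets.items():
        present = gene_index.isin(set(map(str, genes)))
        missing = len(set(map(str, genes))) - int(present.sum())
        if present.sum() == 0:
            raise ValueError(f"gene set {name!r} has no genes in the matrix")
        if missing:
            warnings.warn(f"gene set {name!r}: {missing} gene(s) not in matrix", stacklevel=2)
        if present.sum() == X.n_genes:
            raise ValueError(f"gene set {name!r} covers every gene; no complement")
        for j, sample in enumerate(X.sample_ids):
            score = _ssgsea_one(X.values[:, j], present, exponent)
            rows.append((sample, name, score))
    return pd.DataFrame(rows, columns=["sample_id", "gene_set_name", "enrichment_score"])


def fisher_enrichment(labels: pd.Series, attribute: pd.Series) -> pd.DataFrame:
    """Fisher's exact association of every (cluster, attribute value) pair.

    For each pair, a 2x2 table {in/out of cluster} x {has/lacks value} is
    tested (two-sided); BH-adjusted p-values are reported alongside raw p.
    """
    labels = pd.Series(labels).astype(str)
    attribute = pd.Series(attribute).astype(str).reindex(labels.index)
    values = sorted(attribute.dropna().unique())
    clusters = sorted(labels.unique())
    if len(values) < 2:
        raise ValueError("attribute must have at least 2 levels")
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for cl in clusters:
        in_cl = labels == cl
        for val in values:
            has = attribute == val
            a = int((in_cl & has).sum())
            b = int((in_cl & ~has).sum())
            c = int((~in_cl & has).sum())
            d = int((~in_cl & ~has).sum())
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((cl, val, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "cluster_label",
            "attribute_value",
            "count_in_with",
            "count_in_without",
            "count_out_with",
            "count_out_without",
            "odds_ratio",
            "p_value",
        ],
    )
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def adjusted_rand_index(a: Sequence, b: Sequence) -> float:
    """Chance-corrected agreement of two partitions (1 = identical)."""
    a = np.asarray(list(a))
    b = np.asarray(list(b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def cluster_survival(
    labels: pd.Series,
    survival: pd.DataFrame,
    plot_path: Optional[str] = None,
):
    """Kaplan-Meier per cluster plus overall and pairwise log-rank tests.

    ``survival`` needs columns ``time`` and ``event`` indexed by sample.
    Returns ``(overall_p, pairwise_frame, km_curves)`` where ``km_curves``
    maps cluster label -> survival-function DataFrame.  Optionally writes
    a KM plot to ``plot_path``.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    labels = pd.Series(labels).astype(str)
    df = survival.loc[labels.index].copy()
    df["cluster"] = labels
    for cl, grp in df.groupby("cluster"):
        if int(grp["event"].sum()) < 2:
            raise ValueError(f"cluster {cl!r} has fewer than 2 observed events")
    overall = multivariate_logrank_test(df["time"], df["cluster"], df["event"])
    pairs = []
    clusters = sorted(df["cluster"].unique())
    for x, y in itertools.combinations(clusters, 2):
        gx = df[df["cluster"] == x]
        gy = df[df["cluster"] == y]
        res = logrank_test(gx["time"], gy["time"], gx["event"], gy["event"])
        pairs.append((x, y, float(res.p_value)))
    pairwise = pd.DataFrame(pairs, columns=["cluster_a", "cluster_b", "p_value"])
    curves = {}
    kmf = KaplanMeierFitter()
    ax = None
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(6, 4))
    for cl in clusters:
        grp = df[df["cluster"] == cl]
        kmf.fit(grp["time"], grp["event"], label=str(cl))
        curves[cl] = kmf.survival_function_.copy()
        if ax is not None:
            kmf.plot_survival_function(ax=ax)
    if ax is not None:
        import matplotlib.pyplot as plt

        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_title(f"log-rank p = {overall.p_value:.3g}")
        plt.tight_layout()
        plt.savefig(plot_path)
        plt.close()
    return float(overall.p_value), pairwise, curves
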