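"""K-means co-occupancy clustering of promoters by histone-mark signal.

Features are log2(x + 1)-transformed promoter intensities per mark,
z-scored per feature; clustering uses k-means++ with multiple restarts,
keeping the assignment with the smallest inertia.  Cluster labels are
re-ordered by descending mean of the first feature so reports are stable
across runs.  Association of gene sets with clusters is summarized by the
fraction of the set per cluster, its fold over the cluster's share of the
universe, and a BH-adjusted hypergeometric upper-tail p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionTable

__all__ = [
    "ClusterAssignment",
    "build_feature_matrix",
    "kmeans_promoters",
    "cluster_expression_summary",
    "geneset_cluster_enrichment",
]


@dataclass
class ClusterAssignment:
    k: int
    feature_names: list[str]
    labels: pd.Series          # per gene, values in 1..k
    centroids: pd.DataFrame    # k rows, standardized feature space
    inertia: float
    seed: int
    restarts: int

    def members(self, cluster: int) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels == cluster])


def build_feature_matrix(
    signals: Mapping[str, pd.Series],
    log_transform: bool = True,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble per-gene mark signals into a standardized feature matrix.

    `signals` maps feature name (e.g. 'H3K4me3_GV') to a per-gene Series;
    all series must share the same gene universe.
    """
    if not signals:
        raise ValueError("no features given")
    names = list(signals)
    universe = signals[names[0]].index
    for name in names[1:]:
        if not signals[name].index.equals(universe):
            raise ValueError(f"feature {name!r} is on a different gene universe")
    mat = pd.DataFrame({n: signals[n].astype(float) for n in names})
    if (mat.to_numpy() < 0).any():
        raise ValueError("signals must be non-negative")
    if log_transform:
        mat = np.log2(mat + 1.0)
    if standardize:
        sd = mat.std(axis=0, ddof=0)
        flat = sd[sd == 0].index.tolist()
        if flat:
            raise ValueError(f"constant feature(s): {flat}")
        mat = (mat - mat.mean(axis=0)) / sd
    return mat


def kmeans_promoters(
    features: pd.DataFrame,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """K-means++ with `restarts` initializations; labels ordered by the
    first feature's cluster mean (descending)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = len(np.unique(features.to_numpy(), axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct feature rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(features.to_numpy())
    raw = km.labels_
    order = np.argsort(-km.cluster_centers_[:, 0], kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=features.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[order],
        index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=features.columns,
    )
    return ClusterAssignment(
        k=k,
        feature_names=list(features.columns),
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def cluster_expression_summary(
    assignment: ClusterAssignment,
    table: ExpressionTable,
    condition: str,
) -> pd.DataFrame:
    """Per-cluster n / median / quartiles of log2 FPKM at one condition."""
    expr = table.condition_values(condition)
    common = assignment.labels.index.intersection(expr.index)
    if common.empty:
        raise ValueError("cluster assignment and expression table share no genes")
    logx = np.log2(expr.loc[common].clip(lower=1.0))
    labels = assignment.labels.loc[common]
    rows = []
    for c in range(1, assignment.k + 1):
        vals = logx[labels == c]
        if len(vals) == 0:
            rows.append({"cluster": c, "n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan})
        else:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"cluster": c, "n": len(vals), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows).set_index("cluster")


def geneset_cluster_enrichment(
    assignment: ClusterAssignment,
    gene_set: frozenset[str] | set[str],
    universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set across clusters.

    fraction: share of the set in each cluster; fold: fraction over the
    cluster's share of the universe; p: upper-tail hypergeometric,
    BH-adjusted across the k clusters.
    """
    if not gene_set:
        raise ValueError("gene_set is empty")
    labels = assignment.labels
    universe = list(universe) if universe is not None else list(labels.index)
    uni = set(universe)
    if not set(gene_set) <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    labels = labels.loc[[g for g in universe if g in labels.index]]
    N = len(labels)
    K = sum(1 for g in gene_set if g in labels.index)
    rows = []
    for c in range(1, assignment.k + 1):
        members = set(labels.index[labels == c])
        n_c = len(members)
        x = len(members & set(gene_set))
        fraction = x / K if K else 0.0
        share = n_c / N if N else 0.0
        fold = fraction / share if share > 0 else np.nan
        p = stats.hypergeom.sf(x - 1, N, K, n_c) if n_c else 1.0
        rows.append({"cluster": c, "n_cluster": n_c, "n_overlap": x,
                     "fraction": fraction, "fold": fold, "p_value": p})
    out = pd.DataFrame(rows).set_index("cluster")
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
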