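"""Hierarchical clustering of L2FC/NES matrices, nearest-neighbor pairing of
assay duplicates, and the cluster-difference test with discriminating-set
selection."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    assignment: pd.Series  # column -> 1..k, labelled by first appearance
    distance: str = "euclidean"
    method: str = "ward"


def ward_cluster(matrix: pd.DataFrame, k: int) -> ClusterResult:
    """Ward clustering of matrix *columns* on Euclidean distances.

    Uses the ward.D2 convention: the criterion operates on squared Euclidean
    distances internally while the caller supplies unsquared observations.
    Cluster labels are renumbered by first appearance in column order so the
    partition is deterministic.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute or drop first")
    if matrix.shape[1] < k:
        raise ValueError(f"cannot form {k} clusters from {matrix.shape[1]} columns")
    X = matrix.to_numpy(dtype=float).T  # observations = columns
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for value in raw:
        if value not in relabel:
            relabel[value] = len(relabel) + 1
        labels.append(relabel[value])
    assignment = pd.Series(labels, index=matrix.columns, name="cluster")
    return ClusterResult(linkage=Z, assignment=assignment)


def linkage_to_newick(result: ClusterResult, labels=None) -> str:
    """Serialize the dendrogram as a newick string with merge-height branch lengths."""
    tree = hierarchy.to_tree(result.linkage)
    names = list(labels) if labels is not None else list(result.assignment.index)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def nearest_neighbor_pairing(matrix: pd.DataFrame, treatment_of: dict[str, str],
                             assay_of: dict[str, str]) -> dict:
    """Check whether each treatment's two assay columns are mutual neighbors.

    For every treatment (which must contribute exactly two columns, one per
    assay), test whether the Euclidean nearest neighbor of its first-assay
    column (self excluded) is its other-assay column. Returns the fraction
    paired and the failures.
    """
    columns = list(matrix.columns)
    by_treatment: dict[str, list[str]] = {}
    for col in columns:
        by_treatment.setdefault(treatment_of[col], []).append(col)
    bad = {t: cols for t, cols in by_treatment.items() if len(cols) != 2}
    if bad:
        raise ValueError(f"treatments without exactly two columns: {sorted(bad)}")

    dist = squareform(pdist(matrix.to_numpy(dtype=float).T))
    index = {c: i for i, c in enumerate(columns)}
    unpaired = []
    for treatment, (first, second) in sorted(by_treatment.items()):
        row = dist[index[first]].copy()
        row[index[first]] = np.inf
        nearest = columns[int(np.argmin(row))]
        if nearest != second:
            unpaired.append(treatment)
    n = len(by_treatment)
    return {
        "fraction_paired": (n - len(unpaired)) / n,
        "unpaired": unpaired,
        "n_treatments": n,
    }


def cluster_difference_test(
    nes: pd.DataFrame,
    labels: pd.Series,
    cluster_a,
    cluster_b,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-gene-set two-sample test of NES between two clusters.

    Welch's t-test by default (Mann-Whitney behind ``test='mannwhitney'``),
    BH-adjusted across sets. Returns mean NES per cluster, the absolute mean
    difference ``delta``, the statistic, raw and adjusted p-values.
    """
    cols_a = labels.index[labels == cluster_a]
    cols_b = labels.index[labels == cluster_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each cluster needs at least two columns")
    A = nes[cols_a].to_numpy(dtype=float)
    B = nes[cols_b].to_numpy(dtype=float)
    rows = []
    for i, gene_set in enumerate(nes.index):
        a_vals, b_vals = A[i], B[i]
        mean_a, mean_b = a_vals.mean(), b_vals.mean()
        if np.std(a_vals) == 0 and np.std(b_vals) == 0:
            stat, pval = np.nan, np.nan
        elif test == "welch":
            stat, pval = stats.ttest_ind(a_vals, b_vals, equal_var=False)
        elif test == "mannwhitney":
            stat, pval = stats.mannwhitneyu(a_vals, b_vals, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"set": gene_set, "mean_NES_A": mean_a, "mean_NES_B": mean_b,
             "delta": abs(mean_a - mean_b), "stat": stat, "pval": pval}
        )
    report = pd.DataFrame(rows).set_index("set")
    testable = report["pval"].notna()
    fdr = pd.Series(np.nan, index=report.index)
    if testable.any():
        fdr[testable] = benjamini_hochberg_safe(report.loc[testable, "pval"].to_numpy())
    report["fdr"] = fdr
    report["significant"] = report["fdr"] < alpha
    return report


def benjamini_hochberg_safe(p: np.ndarray) -> np.ndarray:
    from .diffexpr import benjamini_hochberg

    return benjamini_hochberg(p)


def select_discriminating_sets(
    report: pd.DataFrame, delta_min: float = 2.5, fdr_max: float = 5e-4
) -> list[str]:
    """Sets with delta strictly above ``delta_min`` and fdr strictly below
    ``fdr_max``, ordered by descending delta."""
    mask = (report["delta"] > delta_min) & (report["fdr"] < fdr_max)
    return list(report[mask].sort_values("delta", ascending=False).index)
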