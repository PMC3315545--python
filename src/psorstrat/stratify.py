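"""Subject stratification from signature-score matrices.

Scores (log2 ratios, subjects x signatures) are standardized per
signature to mean 0 / sd 1, subjects are clustered by complete-linkage
agglomeration on Euclidean distance, and the tree is cut into a fixed
number of tiers (3 inflammatory: strong/moderate/weak; 2 cytokine:
IL-13-strong/IL-13-weak). Tier labels are ordered by descending cluster
mean of the standardized row sums, so "strong" is always the cluster with
the highest overall scores. Per-signature average silhouette widths
quantify how well each single signature separates the chosen tiers.
Susceptibility loci are clustered the same way but with Manhattan
distance on risk-allele-count vectors (pairwise-complete over missing
genotypes, rescaled to the full subject count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import GenotypeTable

INFLAMMATORY_TIERS = ("strong", "moderate", "weak")
CYTOKINE_TIERS = ("il13_strong", "il13_weak")


@dataclass
class ScoreMatrix:
    """Subjects x signatures score matrix with standardization state."""

    values: pd.DataFrame
    standardized: bool = False
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def signatures(self) -> pd.Index:
        return self.values.columns


def standardize(matrix: ScoreMatrix | pd.DataFrame) -> ScoreMatrix:
    """Column-wise z-scores (ddof=1); original means/sds retained."""
    df = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("standardization needs >=2 subjects")
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    flat = sds[sds == 0].index.tolist()
    if flat:
        raise ValueError(f"constant signature column(s): {flat}")
    z = (df - means) / sds
    return ScoreMatrix(z, standardized=True, feature_means=means,
                       feature_sds=sds)


_METRIC = {"euclidean": "euclidean", "manhattan": "cityblock"}


def hier_cluster(
    matrix: ScoreMatrix | pd.DataFrame,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative merge tree over rows (scipy linkage matrix)."""
    df = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    if df.shape[0] < 2:
        raise ValueError("clustering needs >=2 rows")
    X = df.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("score matrix contains NaN")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    return hierarchy.linkage(X, method=linkage, metric=_METRIC[metric])


def cut_k(
    dendrogram: np.ndarray,
    k: int,
    matrix: ScoreMatrix | pd.DataFrame | None = None,
) -> np.ndarray:
    """Cut the tree into k clusters; labels 0..k-1 by descending mean score.

    When ``matrix`` is given, cluster ids are relabeled so that cluster 0
    has the largest mean row-sum (the "strongest" tier) and so on;
    otherwise scipy's leaf-order ids (zero-based) are returned.
    """
    n = dendrogram.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = hierarchy.fcluster(dendrogram, t=k, criterion="maxclust") - 1
    if len(np.unique(raw)) != k:
        warnings.warn(
            f"tie in merge heights: maxclust returned "
            f"{len(np.unique(raw))} clusters for k={k}", stacklevel=2,
        )
    if matrix is None:
        return raw
    df = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    rowsum = df.sum(axis=1).to_numpy(float)
    order = sorted(
        np.unique(raw), key=lambda c: -rowsum[raw == c].mean()
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw])


def tier_labels(cluster_ids: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    """Map ordered cluster ids (0 = strongest) to tier names."""
    if len(np.unique(cluster_ids)) > len(names):
        raise ValueError("more clusters than tier names")
    return np.array([names[c] for c in cluster_ids])


def silhouette_by_feature(
    matrix: ScoreMatrix | pd.DataFrame, labels
) -> pd.Series:
    """Average silhouette width of the given partition, per single feature.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) on the 1-D distance |x_i - x_j|
    per feature column; members of singleton clusters take s(i) = 0.
    """
    df = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs >=2 clusters")
    out = {}
    for feat in df.columns:
        x = df[feat].to_numpy(float)
        D = np.abs(x[:, None] - x[None, :])
        s = np.zeros(len(x))
        for i in range(len(x)):
            same = labels == labels[i]
            n_same = same.sum()
            if n_same == 1:
                s[i] = 0.0
                continue
            a = D[i, same].sum() / (n_same - 1)
            b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
            denom = max(a, b)
            s[i] = 0.0 if denom == 0 else (b - a) / denom
        out[feat] = s.mean()
    return pd.Series(out, name="avg_silhouette_width")


def manhattan_pairwise_complete(counts: pd.DataFrame) -> np.ndarray:
    """Condensed Manhattan distance over columns, pairwise-complete on NaN.

    Each pairwise sum over complete observations is rescaled by
    n_subjects / n_complete so distances stay comparable across loci with
    different missingness.
    """
    X = counts.to_numpy(float)
    n_sub, n_loc = X.shape
    D = np.zeros((n_loc, n_loc))
    for i in range(n_loc):
        for j in range(i + 1, n_loc):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            n_ok = ok.sum()
            if n_ok == 0:
                raise ValueError(
                    f"loci {counts.columns[i]!r} and {counts.columns[j]!r} "
                    "share no complete observations"
                )
            d = np.abs(X[ok, i] - X[ok, j]).sum() * n_sub / n_ok
            D[i, j] = D[j, i] = d
    return squareform(D, checks=False)


def cluster_loci(genotypes: GenotypeTable,
                 linkage: str = "complete") -> tuple[np.ndarray, list]:
    """Complete-linkage Manhattan tree over loci; returns (tree, loci kept).

    Loci with all genotypes missing are excluded with a warning.
    """
    counts = genotypes.counts
    all_missing = counts.columns[counts.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(
            f"loci with all genotypes missing excluded: {list(all_missing)}",
            stacklevel=2,
        )
        counts = counts.drop(columns=all_missing)
    if counts.shape[1] < 2:
        raise ValueError("need >=2 loci with data to cluster")
    cond = manhattan_pairwise_complete(counts)
    tree = hierarchy.linkage(cond, method=linkage)
    return tree, list(counts.columns)


def loci_ordering(genotypes: GenotypeTable) -> list:
    """Leaf order of the loci dendrogram (display ordering)."""
    tree, kept = cluster_loci(genotypes)
    return [kept[i] for i in hierarchy.leaves_list(tree)]


@dataclass
class SubgroupAssignment:
    """Per-subject tier labels plus dendrogram metadata."""

    inflammatory_tier: pd.Series
    cytokine_tier: pd.Series | None
    dendrogram_inflammatory: np.ndarray | None = None
    dendrogram_cytokine: np.ndarray | None = None
    k_inflammatory: int = 3
    k_cytokine: int = 2


def assign_subgroups(
    inflammatory_scores: pd.DataFrame,
    cytokine_scores: pd.DataFrame | None = None,
    k_inflammatory: int = 3,
    k_cytokine: int = 2,
    linkage: str = "complete",
    metric: str = "euclidean",
) -> SubgroupAssignment:
    """Standardize, cluster and cut both score matrices into tiers."""
    z_inf = standardize(inflammatory_scores)
    tree_inf = hier_cluster(z_inf, linkage, metric)
    ids_inf = cut_k(tree_inf, k_inflammatory, z_inf)
    inf = pd.Series(
        tier_labels(ids_inf, INFLAMMATORY_TIERS[:k_inflammatory])
        if k_inflammatory <= 3 else ids_inf.astype(str),
        index=inflammatory_scores.index, name="inflammatory_tier",
    )
    cyt = None
    tree_cyt = None
    if cytokine_scores is not None:
        z_cyt = standardize(cytokine_scores)
        tree_cyt = hier_cluster(z_cyt, linkage, metric)
        ids_cyt = cut_k(tree_cyt, k_cytokine, z_cyt)
        cyt = pd.Series(
            tier_labels(ids_cyt, CYTOKINE_TIERS[:k_cytokine])
            if k_cytokine <= 2 else ids_cyt.astype(str),
            index=cytokine_scores.index, name="cytokine_tier",
        )
    return SubgroupAssignment(
        inflammatory_tier=inf,
        cytokine_tier=cyt,
        dendrogram_inflammatory=tree_inf,
        dendrogram_cytokine=tree_cyt,
        k_inflammatory=k_inflammatory,
        k_cytokine=k_cytokine,
    )


def to_newick(tree: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    root = hierarchy.to_tree(tree)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(root) + ";"
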