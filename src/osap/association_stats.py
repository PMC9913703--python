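"""Downstream statistics on score vectors and expression matrices.

Two-group and k-group rank tests, Spearman correlation, agglomerative
clustering on correlation distance, and PCA.  Rank tests are two-sided;
the Mann-Whitney test enumerates the exact null when the pooled sample is
small and tie-free, otherwise it uses the tie- and continuity-corrected
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

EXACT_CUTOVER = 20  # total n at or below which the exact MW null is enumerated


@dataclass
class GroupComparisonResult:
    group_labels: list[str]
    group_sizes: list[int]
    statistic: float  # U for two groups, H for k groups
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group needs >=2 values")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.rho) or abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"invalid correlation coefficient: {self.rho}")


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_cutover: int = EXACT_CUTOVER
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test of x versus y.

    Exact enumeration when ``len(x)+len(y) <= exact_cutover`` and the pooled
    data are tie-free; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("mann_whitney needs >=2 values per group")
    pooled = np.concatenate([x, y])
    ties = _has_ties(pooled)
    if len(np.unique(pooled)) == 1:
        # every value identical: no separation, U at its null mean
        return GroupComparisonResult(
            ["x", "y"], [len(x), len(y)], len(x) * len(y) / 2.0, 1.0,
            "degenerate (all values tied)",
        )
    if len(pooled) <= exact_cutover and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "normal-approximation, tie-corrected" if ties else "normal-approximation"
    p = min(float(res.pvalue), 1.0)
    if p == 0.0:  # guard against underflow to keep p in (0, 1]
        p = np.nextafter(0.0, 1.0)
    return GroupComparisonResult(
        group_labels=["x", "y"],
        group_sizes=[len(x), len(y)],
        statistic=float(res.statistic),
        p_value=p,
        method=method,
    )


def kruskal_wallis(groups: list[np.ndarray], labels: list[str] | None = None) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H test; p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >=2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has <2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    if len(np.unique(pooled)) == 1:
        # all values identical: H = 0 by definition, no separation
        return GroupComparisonResult(labels, [len(g) for g in arrays], 0.0, 1.0,
                                     "chi-square, degenerate (all values tied)")
    h, p = sps.kruskal(*arrays)
    p = min(float(p), 1.0)
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return GroupComparisonResult(
        group_labels=list(labels),
        group_sizes=[len(g) for g in arrays],
        statistic=float(h),
        p_value=p,
        method="chi-square, tie-corrected",
    )


def spearman(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation: Pearson on midranks, t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman needs >=3 pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    p = min(float(res.pvalue), 1.0)
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return CorrelationResult(rho=float(res.statistic), p_value=p, n=len(x))


@dataclass
class ClusterResult:
    item_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    leaf_order: list[str]


def hierarchical_cluster(
    matrix_values: np.ndarray,
    item_ids: list[str],
    metric: str = "correlation",
    linkage_method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows with 1 - Pearson distance, average linkage.

    Rows are the clustered items (transpose beforehand to cluster samples).
    Items are pre-sorted by ID so equal-distance merges resolve
    deterministically.
    """
    values = np.asarray(matrix_values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(item_ids):
        raise ValueError("matrix rows must match item_ids")
    if len(item_ids) < 2:
        raise ValueError("clustering needs >=2 items")
    if metric == "correlation":
        sds = values.std(axis=1)
        flat = [item_ids[i] for i in np.flatnonzero(sds == 0)]
        if flat:
            raise ValueError(
                f"constant item(s) under correlation distance: {', '.join(flat)}"
            )
    order0 = np.argsort(np.array(item_ids, dtype=object))
    sorted_ids = [item_ids[i] for i in order0]
    z = hierarchy.linkage(values[order0], method=linkage_method, metric=metric)
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(
        item_ids=sorted_ids,
        linkage=z,
        leaf_order=[sorted_ids[i] for i in leaves],
    )


@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x k
    explained_variance_fraction: np.ndarray
    components: np.ndarray  # k x genes loadings


def pca(matrix_values: np.ndarray, sample_ids: list[str], k: int) -> PcaResult:
    """PCA of samples on gene-centered (unscaled) expression.

    ``matrix_values`` is genes x samples.  Coordinates are projections onto
    the top-k principal axes; each axis is sign-fixed so its
    largest-magnitude gene loading is positive.
    """
    values = np.asarray(matrix_values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(sample_ids):
        raise ValueError("matrix columns must match sample_ids")
    centered = values - values.mean(axis=1, keepdims=True)
    # samples x genes for SVD: rows are observations
    x = centered.T
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    total_var = float((s ** 2).sum())
    coords = u[:, :k] * s[:k]
    comps = vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            coords[:, i] = -coords[:, i]
    return PcaResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        explained_variance_fraction=(s[:k] ** 2) / total_var,
        components=comps,
    )
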