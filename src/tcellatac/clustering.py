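"""k-means site clustering with gap-statistic model selection.

Differentially accessible sites are clustered on row-z-scored accessibility
(so the heat-map geometry drives the partition) and, for the lineage
comparison, on raw per-subset log2 fold differences.  The number of clusters
is chosen by the gap statistic: within-cluster dispersion W_k is compared
against reference datasets drawn uniformly over the per-dimension min-max box
of the data, and the smallest k with gap(k) >= gap(k+1) - s(k+1) wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterResult:
    assignments: pd.Series          # feature -> 1..k
    chosen_k: int
    gap_curve: pd.DataFrame | None  # columns k, gap, s, log_w
    seed: int
    restarts: int
    inertia: float = float("nan")


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, population SD 1 (constant rows -> 0)."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns to z-score")
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((X - mu) / sd, index=matrix.index, columns=matrix.columns)


def kmeans_assign(
    matrix: pd.DataFrame, k: int, seed: int = 0, restarts: int = 25
) -> ClusterResult:
    """Best-of-restarts k-means++ partition of the rows."""
    X = matrix.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({X.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    labels = pd.Series(km.labels_ + 1, index=matrix.index, name="cluster")
    return ClusterResult(labels, k, None, seed, restarts, float(km.inertia_))


def _wk(X: np.ndarray, k: int, seed: int, restarts: int) -> float:
    """Within-cluster dispersion: sum over clusters of pairwise D_r / (2 n_r),
    which equals the k-means inertia at the fitted centroids."""
    if k == 1:
        mu = X.mean(axis=0)
        return float(((X - mu) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    return float(km.inertia_)


def choose_k_gap(
    matrix: pd.DataFrame,
    k_range: range | list[int],
    B: int = 50,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterResult:
    """Gap-statistic selection of k, then a final k-means at the chosen k.

    gap(k) = mean_b log W_k(ref_b) - log W_k(data); references are uniform on
    the per-dimension min-max box; s(k) = sd_b(log W_k(ref)) * sqrt(1 + 1/B).
    Chosen k: the smallest k with gap(k) >= gap(k+1) - s(k+1), else max(k).
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 2:
        raise ValueError("k range must contain at least two values")
    X = matrix.to_numpy(dtype=float)
    if max(ks) > X.shape[0]:
        raise ValueError("k range exceeds the number of rows")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = np.array([np.log(_wk(X, k, seed, restarts)) for k in ks])
    ref_log_w = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for j, k in enumerate(ks):
            ref_log_w[b, j] = np.log(_wk(ref, k, ref_seed, restarts))
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0) * np.sqrt(1.0 + 1.0 / B)
    chosen = ks[-1]
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            chosen = ks[j]
            break
    curve = pd.DataFrame({"k": ks, "gap": gap, "s": s, "log_w": log_w})
    final = kmeans_assign(matrix, chosen, seed=seed, restarts=max(restarts, 25))
    return ClusterResult(final.assignments, chosen, curve, seed, restarts, final.inertia)


def fold_change_groups(
    logfc: pd.DataFrame, k: int = 4, seed: int = 0, restarts: int = 25
) -> ClusterResult:
    """Cluster peaks on their young-vs-old log2 fold differences across
    lineage/subset columns (default four groups)."""
    if np.allclose(logfc.to_numpy(), 0):
        raise ValueError("all fold differences are zero; clustering is degenerate")
    return kmeans_assign(logfc, k, seed=seed, restarts=restarts)
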