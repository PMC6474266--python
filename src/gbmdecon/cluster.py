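"""Unsupervised structure: HCPC for reference cell lines, Ward + gap for patients.

Two clustering jobs occur in the analysis.  Reference cell lines are
clustered by hierarchical clustering on principal-component scores (HCPC):
Ward linkage on Euclidean distance over the first few PCs, with the number
of clusters chosen automatically as the cut with the highest *relative*
loss of within-cluster inertia.  Patients are clustered on their estimated
tumour-group fractions with Ward linkage, the number of clusters chosen
between 2 and 6 by the gap statistic with a uniform reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .exprio import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "pca_scores",
    "hcpc_cluster",
    "ward_cluster",
    "gap_statistic",
]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample -> 1..k
    k: int
    method_tag: str  # "hcpc" | "ward_gap" | "ward"
    linkage_heights: np.ndarray = field(default_factory=lambda: np.array([]))
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        found = set(self.labels.unique())
        if found != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, found {sorted(found)}")


def pca_scores(m: ExpressionMatrix | pd.DataFrame, n_components: int = 5) -> pd.DataFrame:
    """Centered (not gene-scaled) PCA scores of the samples.

    Rows of the result are samples, columns PC1..PCn ordered by decreasing
    explained variance.
    """
    X = m.values.T if isinstance(m, ExpressionMatrix) else m
    limit = min(X.shape[0] - 1, X.shape[1])
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds {limit}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy(dtype=float))
    return pd.DataFrame(
        scores, index=X.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )


def _within_inertia(X: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def _relabel_by_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Deterministic 1..k labels in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def hcpc_cluster(
    scores: pd.DataFrame, k_max: int = 10, force_k: int | None = None
) -> ClusterAssignment:
    """Ward tree over PC scores with automatic cut by relative inertia loss.

    For k in 2..k_max, let W(k) be the total within-cluster inertia of the
    k-cluster cut and Delta(k) = W(k-1) - W(k) the inertia freed by going
    from k-1 to k clusters.  The chosen k maximises Delta(k)/Delta(k+1):
    the last cut that still buys a disproportionate drop in inertia.
    """
    X = scores.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical; clustering undefined")
    Z = linkage(X, method="ward")
    if force_k is not None:
        raw = fcluster(Z, t=force_k, criterion="maxclust")
        labels = _relabel_by_first_occurrence(raw)
        return ClusterAssignment(
            pd.Series(labels, index=scores.index), force_k, "hcpc", Z[:, 2]
        )
    k_hi = min(k_max, X.shape[0] - 1)
    ks = np.arange(1, k_hi + 2)
    W = np.array(
        [
            _within_inertia(X, fcluster(Z, t=k, criterion="maxclust"))
            for k in ks
        ]
    )
    # W[i] is the inertia of the (i+1)-cluster cut; Delta(k) = W(k-1) - W(k)
    ratios = {}
    for k in range(2, k_hi + 1):
        d_k = W[k - 2] - W[k - 1]
        d_k1 = W[k - 1] - W[k]
        ratios[k] = d_k / d_k1 if d_k1 > 1e-12 else np.inf
    best_k = max(ratios, key=lambda k: (ratios[k], -k))
    raw = fcluster(Z, t=best_k, criterion="maxclust")
    labels = _relabel_by_first_occurrence(raw)
    return ClusterAssignment(
        pd.Series(labels, index=scores.index),
        best_k,
        "hcpc",
        Z[:, 2],
        extras={"inertia": dict(zip(ks.tolist(), W.tolist())), "ratios": ratios},
    )


def ward_cluster(data: pd.DataFrame, k: int) -> ClusterAssignment:
    """Agglomerative Ward clustering on Euclidean distance, cut at k."""
    X = data.to_numpy(dtype=float)
    if k < 2 or k > X.shape[0]:
        raise ValueError(f"k={k} outside 2..{X.shape[0]}")
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _relabel_by_first_occurrence(raw)
    return ClusterAssignment(pd.Series(labels, index=data.index), k, "ward", Z[:, 2])


def gap_statistic(
    data: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    b_refs: int = 50,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of Ward clusters by the gap statistic.

    Gap(k) = mean_b log W*_kb - log W_k, with W from Ward clustering and
    reference datasets drawn uniformly over the bounding box of the data.
    The chosen k is the smallest one satisfying the one-standard-error rule
    Gap(k) >= Gap(k+1) - s_{k+1}; if none qualifies, the k with the largest
    gap is returned.  Deterministic given the seed.
    """
    if b_refs < 10:
        raise ValueError("b_refs must be >= 10")
    X = data.to_numpy(dtype=float)
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi > X.shape[0] - 1 or k_lo > k_hi:
        raise ValueError(f"k_range {k_range} outside 2..{X.shape[0] - 1}")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = list(range(k_lo, k_hi + 1))

    def log_w(Y: np.ndarray) -> np.ndarray:
        Z = linkage(Y, method="ward")
        return np.array(
            [
                np.log(max(_within_inertia(Y, fcluster(Z, t=k, criterion="maxclust")), 1e-300))
                for k in ks
            ]
        )

    log_w_data = log_w(X)
    ref = np.empty((b_refs, len(ks)))
    for b in range(b_refs):
        Y = rng.uniform(lo, hi, size=X.shape)
        ref[b] = log_w(Y)
    gap = ref.mean(axis=0) - log_w_data
    sk = ref.std(axis=0, ddof=0) * np.sqrt(1 + 1.0 / b_refs)
    chosen = None
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            chosen = ks[i]
            break
    if chosen is None:
        chosen = ks[int(np.argmax(gap))]
    curve = pd.DataFrame({"k": ks, "gap": gap, "sk": sk, "log_w": log_w_data})
    return chosen, curve
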