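"""Supervised label transfer between cohorts.

Two classifiers move labels from the discovery cohort to the validation
cohort.  The published four-subtype molecular classification travels via
nearest shrunken centroids (the PAM microarray classifier) trained on a
fixed discriminating gene list; the new fraction-based patient
classification travels via a random forest on the deconvolved fractions.

Nearest shrunken centroids: per class k and gene g, the standardised
centroid deviation d_kg = (xbar_kg - xbar_g) / (m_k (s_g + s0)) with
m_k = sqrt(1/n_k - 1/n) is soft-thresholded at Delta,
d'_kg = sign(d_kg) max(|d_kg| - Delta, 0), and the shrunken centroid is
xbar'_kg = xbar_g + m_k (s_g + s0) d'_kg.  A sample x is assigned to the
class minimising sum_g (x_g - xbar'_kg)^2 / (s_g + s0)^2 - 2 log pi_k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .exprio import ExpressionMatrix

__all__ = [
    "CentroidModel",
    "train_nsc",
    "predict_nsc",
    "crossvalidate_nsc",
    "rf_transfer",
]


@dataclass
class CentroidModel:
    genes: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # per gene
    shrunken_centroids: np.ndarray  # classes x genes
    pooled_sd: np.ndarray  # per gene, s_g + s0 included separately
    s0: float
    delta: float
    priors: np.ndarray  # per class
    mk: np.ndarray = field(default_factory=lambda: np.array([]))


def _class_stats(X: np.ndarray, y: np.ndarray, classes: list[str]):
    n = X.shape[1]
    xbar = X.mean(axis=1)
    cents, nk = [], []
    ss = np.zeros(X.shape[0])
    for c in classes:
        mask = y == c
        nk.append(int(mask.sum()))
        cent = X[:, mask].mean(axis=1)
        cents.append(cent)
        ss += ((X[:, mask] - cent[:, None]) ** 2).sum(axis=1)
    nk = np.array(nk)
    s2 = ss / (n - len(classes))
    return xbar, np.array(cents), nk, np.sqrt(s2)


def train_nsc(
    m: ExpressionMatrix,
    labels: dict[str, str] | pd.Series,
    gene_list: list[str],
    delta: float = 0.0,
) -> CentroidModel:
    """Fit shrunken class centroids on the intersection with ``gene_list``.

    Class priors are the empirical class frequencies; s0 is the median of
    the pooled within-class standard deviations (the PAM fudge constant).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    labels = pd.Series(labels).loc[m.samples].astype(str)
    counts = labels.value_counts()
    small = list(counts.index[counts < 2])
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    genes = [g for g in gene_list if g in set(m.genes)]
    if not genes:
        raise ValueError("gene_list shares no genes with the matrix")
    classes = sorted(labels.unique())
    X = m.values.loc[genes].to_numpy(dtype=float)
    y = labels.to_numpy()
    n = X.shape[1]
    xbar, cents, nk, s = _class_stats(X, y, classes)
    s0 = float(np.median(s))
    mk = np.sqrt(np.clip(1.0 / nk - 1.0 / n, 1e-12, None))
    denom = s + s0
    d = (cents - xbar[None, :]) / (mk[:, None] * denom[None, :])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = xbar[None, :] + mk[:, None] * denom[None, :] * d_shrunk
    return CentroidModel(
        genes=genes,
        classes=classes,
        overall_centroid=xbar,
        shrunken_centroids=shrunken,
        pooled_sd=denom,
        s0=s0,
        delta=delta,
        priors=nk / n,
        mk=mk,
    )


def predict_nsc(
    model: CentroidModel, m: ExpressionMatrix, max_missing: float = 0.2
) -> pd.DataFrame:
    """Assign each sample to the nearest shrunken centroid.

    Returns a frame indexed by sample with the predicted ``label`` and one
    discriminant-score column per class (lower = closer).  Ties go to the
    lowest class index and are flagged in the ``tie`` column.
    """
    present = [g for g in model.genes if g in set(m.genes)]
    missing_frac = 1 - len(present) / len(model.genes)
    if missing_frac > max_missing:
        raise ValueError(
            f"{missing_frac:.0%} of model genes missing (limit {max_missing:.0%})"
        )
    idx = [model.genes.index(g) for g in present]
    X = m.values.loc[present].to_numpy(dtype=float)
    cents = model.shrunken_centroids[:, idx]
    denom2 = model.pooled_sd[idx] ** 2
    scores = np.empty((X.shape[1], len(model.classes)))
    for k in range(len(model.classes)):
        diff = X - cents[k][:, None]
        scores[:, k] = (diff**2 / denom2[:, None]).sum(axis=0) - 2 * np.log(
            model.priors[k]
        )
    best = np.argmin(scores, axis=1)
    ties = (scores == scores[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    out = pd.DataFrame(scores, index=m.samples, columns=model.classes)
    out.insert(0, "label", [model.classes[b] for b in best])
    out["tie"] = ties
    return out


def crossvalidate_nsc(
    m: ExpressionMatrix,
    labels: dict[str, str] | pd.Series,
    gene_list: list[str],
    delta_grid: list[float],
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Stratified k-fold accuracy per shrinkage threshold.

    Returns (table with columns delta, accuracy; chosen delta).  The chosen
    delta maximises accuracy, with ties broken toward the smallest delta.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = pd.Series(labels).loc[m.samples].astype(str)
    if labels.value_counts().min() < folds:
        raise ValueError("smallest class has fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sample_arr = np.array(m.samples)
    acc = {d: 0.0 for d in delta_grid}
    for train_idx, test_idx in skf.split(sample_arr, labels.to_numpy()):
        train_m = ExpressionMatrix(m.values.iloc[:, train_idx], m.scale)
        test_m = ExpressionMatrix(m.values.iloc[:, test_idx], m.scale)
        y_test = labels.iloc[test_idx]
        for d in delta_grid:
            model = train_nsc(train_m, labels.iloc[train_idx], gene_list, d)
            pred = predict_nsc(model, test_m)["label"]
            acc[d] += (pred.to_numpy() == y_test.to_numpy()).sum()
    n = len(sample_arr)
    table = pd.DataFrame(
        {"delta": list(delta_grid), "accuracy": [acc[d] / n for d in delta_grid]}
    )
    best = table.sort_values(["accuracy", "delta"], ascending=[False, True], kind="stable")
    return table, float(best["delta"].iloc[0])


def rf_transfer(
    train_fracs: pd.DataFrame,
    train_labels: pd.Series,
    test_fracs: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Transfer discovery-cohort cluster labels to a validation cohort.

    A random forest on the deconvolved fraction columns; deterministic
    given the seed and invariant to test-row order.
    """
    if list(train_fracs.columns) != list(test_fracs.columns):
        raise ValueError("train and test fraction columns differ")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(train_fracs.to_numpy(), pd.Series(train_labels).loc[train_fracs.index])
    pred = rf.predict(test_fracs.to_numpy())
    return pd.Series(pred, index=test_fracs.index, name="label")
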