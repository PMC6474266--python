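"""Expression-matrix IO, gene-space harmonisation and batch correction.

Expression data travel through the pipeline as :class:`ExpressionMatrix`, a
genes x samples table of log2 intensities (or linear intensities when
explicitly tagged).  Loaders are strict: malformed input raises
:class:`FormatError` instead of being silently coerced, because every
downstream stage assumes a complete numeric matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_annotations",
    "collapse_duplicates",
    "intersect_genes",
    "correct_batch",
    "to_linear",
    "to_log2",
]

LOG2 = "log2"
LINEAR = "linear"


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table.

    Parameters
    ----------
    values
        DataFrame indexed by uppercase gene symbol, one column per sample.
    scale
        Either ``"log2"`` (storage convention) or ``"linear"`` (the scale in
        which cell populations mix additively).
    """

    values: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LOG2, LINEAR):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        self.values.index = self.values.index.astype(str).str.upper()
        self.values.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.scale)


def read_expression(path: str | Path, scale: str = LOG2) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (first column = gene symbol).

    The loader is strict: ragged rows, non-numeric cells, duplicated sample
    headers or an empty file raise :class:`FormatError` naming the offending
    line.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    rows = [r for r in rows if r]  # drop fully blank lines
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise FormatError(f"{path}: line 1: header must name at least one sample")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dup = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"{path}: line 1: duplicated sample header {dup}")
    genes: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        genes.append(row[0])
        try:
            data.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    values = pd.DataFrame(data, index=genes, columns=samples, dtype=float)
    if values.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed")
    return ExpressionMatrix(values, scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a tab-separated matrix readable by :func:`read_expression`."""
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation CSV (sample_id plus arbitrary columns)."""
    ann = pd.read_csv(path)
    if "sample_id" not in ann.columns:
        raise FormatError(f"{path}: annotation table must contain a sample_id column")
    if ann["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated sample_id values")
    if "age" in ann.columns and (ann["age"].dropna() < 0).any():
        raise FormatError(f"{path}: negative age")
    return ann.set_index("sample_id")


def collapse_duplicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Resolve duplicated gene symbols, keeping the row with highest mean.

    Probe-to-symbol maps on expression arrays are many-to-one; the
    conventional resolution keeps, per symbol, the probe with the largest
    average signal across samples.
    """
    if not m.values.index.duplicated().any():
        return m.copy()
    means = m.values.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    deduped = m.values.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    # restore the original relative order of the surviving symbols
    keep = [g for g in dict.fromkeys(m.values.index) if g in deduped.index]
    return ExpressionMatrix(deduped.loc[keep], m.scale)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes, in sorted order.

    Mirrors cross-platform harmonisation: only symbols measured on both
    platforms are kept.
    """
    common = sorted(set(a.genes) & set(b.genes))
    if not common:
        raise ValueError("gene intersection is empty")
    return (
        ExpressionMatrix(a.values.loc[common].copy(), a.scale),
        ExpressionMatrix(b.values.loc[common].copy(), b.scale),
    )


def correct_batch(
    m: ExpressionMatrix,
    batches: dict[str, str] | pd.Series,
    mean_only: bool = False,
) -> ExpressionMatrix:
    """Remove additive/multiplicative batch effects (ComBat-style).

    The default mode applies the parametric empirical-Bayes location/scale
    adjustment: per-gene batch means and variances are shrunk toward priors
    estimated across genes before removal.  With ``mean_only=True`` the
    per-gene per-batch means are aligned exactly (no shrinkage, no variance
    adjustment), which is appropriate when batches are known to differ by a
    pure location shift.

    Dimensions and gene order are never changed.
    """
    batches = pd.Series(batches)
    missing = [s for s in m.samples if s not in batches.index]
    if missing:
        raise ValueError(f"samples without batch label: {missing[:5]}")
    batches = batches.loc[m.samples]
    levels = batches.unique()
    if len(levels) < 2:
        raise ValueError("batch correction needs at least two batches")
    counts = batches.value_counts()
    if (counts < 2).any():
        singles = list(counts.index[counts < 2])
        raise ValueError(f"singleton batches (variance undefined): {singles}")

    X = m.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    masks = {b: (batches == b).to_numpy() for b in levels}

    grand_mean = X.mean(axis=1, keepdims=True)
    # pooled variance around batch-specific means (the standardising variance)
    resid = np.empty_like(X)
    for b, mask in masks.items():
        resid[:, mask] = X[:, mask] - X[:, mask].mean(axis=1, keepdims=True)
    pooled_var = (resid**2).sum(axis=1) / n_samples
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)
    sd = np.sqrt(pooled_var)[:, None]
    Z = (X - grand_mean) / sd

    adjusted = np.empty_like(Z)
    for b, mask in masks.items():
        Zb = Z[:, mask]
        nb = mask.sum()
        gamma_hat = Zb.mean(axis=1)
        if mean_only:
            gamma_star = gamma_hat
            delta_star = np.ones(n_genes)
        else:
            delta_hat = Zb.var(axis=1, ddof=1)
            delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)
            # hyper-parameters by method of moments across genes
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            d_bar = delta_hat.mean()
            s2 = delta_hat.var(ddof=1)
            lam = (d_bar**2 + 2 * s2) / s2 if s2 > 0 else 1e12
            theta = (d_bar**3 + d_bar * s2) / s2 if s2 > 0 else d_bar
            gamma_star = gamma_hat
            delta_star = delta_hat
            for _ in range(30):
                g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * tau2 + delta_star
                )
                sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * sse) / (nb / 2 + lam - 1)
                if np.max(np.abs(g_new - gamma_star)) < 1e-8 and np.max(
                    np.abs(d_new - delta_star)
                ) < 1e-8:
                    gamma_star, delta_star = g_new, d_new
                    break
                gamma_star, delta_star = g_new, d_new
            delta_star = np.where(delta_star <= 0, 1e-12, delta_star)
        adjusted[:, mask] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = adjusted * sd + grand_mean
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index.copy(), columns=m.values.columns.copy()),
        m.scale,
    )


def to_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map log2 storage to the linear scale in which populations mix: 2**x - 1."""
    if m.scale != LOG2:
        raise ValueError(f"to_linear expects a log2 matrix, got {m.scale!r}")
    return ExpressionMatrix(np.exp2(m.values) - 1.0, LINEAR)


def to_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`to_linear`: log2(x + 1)."""
    if m.scale != LINEAR:
        raise ValueError(f"to_log2 expects a linear matrix, got {m.scale!r}")
    return ExpressionMatrix(np.log2(m.values + 1.0), LOG2)
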