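"""Differential expression between reference groups and signature assembly.

The deconvolution basis is built from genes that discriminate the reference
populations.  Discrimination is assessed with a moderated one-vs-rest
*t*-statistic: the per-gene residual variance is shrunk toward a prior
estimated from all genes by empirical Bayes (the standard remedy for
unstable per-gene variances at small n), and p-values are adjusted by
Benjamini-Hochberg within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exprio import ExpressionMatrix

__all__ = [
    "SignatureMatrix",
    "moderated_t_one_vs_rest",
    "benjamini_hochberg",
    "select_signature_genes",
    "build_signature",
    "read_signature",
    "write_signature",
]

ROLES = ("tumour-group", "stromal", "lymphoid", "myeloid")


@dataclass
class SignatureMatrix:
    """Genes x reference-populations basis matrix, linear scale.

    ``roles`` tags each population column as tumour-group / stromal /
    lymphoid / myeloid, the four compartments whose fractions are required
    to account for 100% of the cells in a tumour.
    """

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = {r for r in self.roles.values()} - set(ROLES)
        if unknown:
            raise ValueError(f"unknown role tags {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values.to_numpy()))

    def full_column_rank(self) -> bool:
        a = self.values.to_numpy()
        return np.linalg.matrix_rank(a) == a.shape[1]


def _fit_var_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Returns (prior_df, prior_s2).  Uses the distribution of log(s2): for
    s2 ~ s0^2 * chi2_df/df scaled by F fluctuations, E[log s2] and
    Var[log s2] involve digamma/trigamma terms; prior df solves the
    trigamma equation by Newton iteration.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = z.var(ddof=1)
    target = e_var - special.polygamma(1, df / 2)
    if target <= 0:
        return np.inf, float(np.exp(e_mean))
    # solve trigamma(d0/2) = target for d0
    x = 0.5 + 1.0 / target  # good starting point (trigamma(y) ~ 1/y for large y)
    for _ in range(50):
        f = special.polygamma(1, x) - target
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < 1e-10:
            x = x_new
            break
        x = x_new
    d0 = 2 * x
    s02 = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return d0, s02


def moderated_t_one_vs_rest(
    m: ExpressionMatrix,
    labels: dict[str, str] | pd.Series,
    prior_df: float | None = None,
    moderated: bool = True,
) -> pd.DataFrame:
    """One-vs-rest differential expression for every reference group.

    For each group g and gene, tests whether mean expression in g differs
    from the mean over all other samples (two-sample pooled-variance t).
    With ``moderated=True`` the pooled variance is shrunk toward an
    empirical-Bayes prior fitted across genes; ``prior_df`` overrides the
    fitted prior degrees of freedom (0 recovers the ordinary t exactly).
    Setting ``moderated=False`` gives Welch's t instead (oracle comparison).

    Returns a tidy frame with columns gene, group, log_fc, t_stat, p, fdr;
    fdr is Benjamini-Hochberg adjusted within each group contrast.
    """
    labels = pd.Series(labels).loc[m.samples]
    groups = sorted(labels.unique().astype(str))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    counts = labels.value_counts()
    small = list(counts.index[counts < 2])
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    X = m.values.to_numpy(dtype=float)
    genes = np.asarray(m.genes)
    out = []
    for g in groups:
        mask = (labels.astype(str) == g).to_numpy()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        x1, x2 = X[:, mask], X[:, ~mask]
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        log_fc = m1 - m2
        if moderated:
            df = n1 + n2 - 2
            s2 = (
                ((x1 - m1[:, None]) ** 2).sum(axis=1)
                + ((x2 - m2[:, None]) ** 2).sum(axis=1)
            ) / df
            if prior_df is None:
                d0, s02 = _fit_var_prior(s2, df)
            else:
                d0 = prior_df
                s02 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
            if np.isinf(d0):
                s2_post = np.full_like(s2, s02)
                df_total = np.inf
            elif d0 == 0:
                s2_post = s2
                df_total = df
            else:
                s2_post = (d0 * s02 + df * s2) / (d0 + df)
                df_total = df + d0
            se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
        else:
            v1 = x1.var(axis=1, ddof=1) / n1
            v2 = x2.var(axis=1, ddof=1) / n2
            se = np.sqrt(v1 + v2)
            with np.errstate(divide="ignore", invalid="ignore"):
                df_total = (v1 + v2) ** 2 / (
                    v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
                )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log_fc / se
        degenerate = ~np.isfinite(t)
        t = np.where(degenerate, 0.0, t)
        if np.isscalar(df_total) or np.ndim(df_total) == 0:
            dfv = np.full(len(t), df_total, dtype=float)
        else:
            dfv = np.where(np.isfinite(df_total), df_total, 1.0)
        if np.all(np.isinf(dfv)):
            p = 2 * stats.norm.sf(np.abs(t))
        else:
            p = 2 * stats.t.sf(np.abs(t), dfv)
        p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
        fdr = benjamini_hochberg(p)
        out.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "group": g,
                    "log_fc": log_fc,
                    "t_stat": t,
                    "p": p,
                    "fdr": fdr,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_signature_genes(
    de: pd.DataFrame, fdr_threshold: float = 0.05, top_g: int = 50
) -> dict[str, list[str]]:
    """Pick up-regulated marker genes per group from a DE table.

    Genes with fdr below threshold and positive log fold-change are ranked
    by p then |log_fc| and truncated to ``top_g`` per group.  A gene passing
    in several groups is assigned only to the group where its |log_fc| is
    largest, so the marker lists are disjoint.
    """
    if not (0 < fdr_threshold < 1):
        raise ValueError("fdr_threshold must be in (0, 1)")
    if top_g < 1:
        raise ValueError("top_g must be >= 1")
    passing = de[(de["fdr"] < fdr_threshold) & (de["log_fc"] > 0)].copy()
    # disjointify: keep each gene only in its strongest group
    passing["abs_fc"] = passing["log_fc"].abs()
    best = passing.sort_values("abs_fc", ascending=False).drop_duplicates("gene")
    selected: dict[str, list[str]] = {}
    for g in sorted(de["group"].unique()):
        sub = best[best["group"] == g].sort_values(
            ["p", "abs_fc"], ascending=[True, False], kind="stable"
        )
        genes = list(sub["gene"].head(top_g))
        if not genes:
            raise ValueError(f"no genes pass the signature filter for group {g!r}")
        selected[g] = genes
    return selected


def build_signature(
    refs: ExpressionMatrix,
    labels: dict[str, str] | pd.Series,
    gene_union: list[str],
    roles: dict[str, str] | None = None,
) -> SignatureMatrix:
    """Average linear-scale reference profiles into the deconvolution basis.

    Column j is the per-gene mean over the samples of population j,
    restricted to ``gene_union``.
    """
    if refs.scale != "linear":
        raise ValueError("signature construction requires a linear-scale matrix")
    missing = set(gene_union) - set(refs.genes)
    if missing:
        raise ValueError(f"gene_union contains genes absent from refs: {sorted(missing)[:5]}")
    labels = pd.Series(labels).loc[refs.samples].astype(str)
    cols = {}
    for pop in sorted(labels.unique()):
        members = labels.index[labels == pop]
        if len(members) == 0:
            raise ValueError(f"population {pop!r} has no samples")
        cols[pop] = refs.values.loc[gene_union, members].mean(axis=1)
    values = pd.DataFrame(cols)
    return SignatureMatrix(values, roles or {})


def write_signature(sig: SignatureMatrix, path) -> None:
    """TSV with a second header line carrying the role tags."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(sig.populations) + "\n")
        fh.write(
            "#role\t" + "\t".join(sig.roles.get(p, "") for p in sig.populations) + "\n"
        )
        for gene, row in sig.values.iterrows():
            fh.write(gene + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_signature(path) -> SignatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        role_line = fh.readline().rstrip("\n").split("\t")
        pops = header[1:]
        roles = {p: r for p, r in zip(pops, role_line[1:]) if r}
        body = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    body.columns = pops
    body.index.name = "gene"
    return SignatureMatrix(body, roles)
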