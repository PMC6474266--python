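"""Absolute deconvolution of bulk profiles into reference-population fractions.

A bulk tumour profile is modelled, in linear intensity space, as a convex
combination of pure reference profiles: tumour-cell groups, a stromal
profile, and lymphoid/myeloid immune subsets, which together account for
100% of the cells in the sample.  Fractions are therefore constrained to
the probability simplex, which is what makes the estimates *absolute*
(relative to all cells) rather than relative to the immune compartment
only.

Two solvers share the interface:

* ``nusvr`` — the default regression engine: a linear nu-SVR of the
  z-scored bulk profile on the z-scored signature columns, fitted over a
  small grid of nu values, keeping the fit with smallest reconstruction
  RMSE; negative coefficients are clipped to zero and the vector is
  renormalised onto the simplex.  The support-vector loss makes this path
  robust to genes that deviate from the mixture model.
* ``qp`` — the exact minimiser of ||y - B f||^2 subject to f >= 0,
  sum(f) = 1, a strictly convex quadratic program.  It is both a
  config-selectable primary solver and the fallback when the SVR fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.svm import NuSVR

from .exprio import ExpressionMatrix, to_linear
from .signatures import SignatureMatrix

__all__ = [
    "FractionMatrix",
    "DeconvConfig",
    "deconvolve_sample",
    "qp_oracle",
    "deconvolve_cohort",
    "aggregate_roles",
]

ROLE_ORDER = ("tumour", "stromal", "lymphoid", "myeloid")


@dataclass
class DeconvConfig:
    """Tunables of the deconvolution stage.

    nu_grid follows the nu-SVR grid of the algorithm this deconvolution
    adapts; svr_c is the SVR margin penalty (the library default).
    """

    solver: str = "nusvr"  # "nusvr" | "qp"
    nu_grid: tuple[float, ...] = (0.25, 0.50, 0.75)
    svr_c: float = 1.0
    min_gene_overlap: float = 0.5


@dataclass
class FractionMatrix:
    """Samples x populations fraction estimates plus per-sample diagnostics.

    Every row lies on the probability simplex: entries >= 0, summing to 1
    within 1e-6.  ``diagnostics`` carries rmse, pearson_r and chosen_nu per
    sample.
    """

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        f = self.values.to_numpy()
        if f.size and (np.any(f < -1e-9) or np.max(np.abs(f.sum(axis=1) - 1)) > 1e-6):
            raise ValueError("fractions must be non-negative and sum to 1 per row")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)


def _zscore(a: np.ndarray) -> np.ndarray:
    """Standardise by the global mean and sd of the array.

    The signature matrix must be standardised as a whole (not per column):
    because fractions sum to one, a common affine transform of the columns
    keeps the regression coefficients proportional to the fractions,
    whereas per-column scaling would distort them by each column's sd.
    """
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


def qp_oracle(y: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares.

    Minimises ||y - B f||^2 over the probability simplex.  B must have full
    column rank so the program is strictly convex and the minimiser unique.
    """
    y = np.asarray(y, dtype=float).ravel()
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != y.size:
        raise ValueError("y and B have incompatible shapes")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("signature matrix is rank deficient")
    # scale for conditioning; the argmin is scale invariant
    s = np.abs(B).mean()
    if s == 0:
        raise ValueError("all-zero signature matrix")
    Bs, ys = B / s, y / s
    G = Bs.T @ Bs
    h = Bs.T @ ys
    p = B.shape[1]

    def fun(f):
        r = Bs @ f - ys
        return 0.5 * float(r @ r)

    def jac(f):
        return G @ f - h

    res = optimize.minimize(
        fun,
        np.full(p, 1.0 / p),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * p,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                      "jac": lambda f: np.ones(p)}],
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    f = np.clip(res.x, 0.0, None)
    return f / f.sum()


def _nusvr_fit(y_z: np.ndarray, B_z: np.ndarray, nu_grid, c: float):
    """Best-nu linear nu-SVR coefficients; returns (w, rmse, r, nu)."""
    best = None
    for nu in nu_grid:
        try:
            model = NuSVR(kernel="linear", nu=nu, C=c)
            model.fit(B_z, y_z)
        except Exception:
            continue
        w = model.coef_.ravel()
        fitted = B_z @ w + model.intercept_
        rmse = float(np.sqrt(np.mean((fitted - y_z) ** 2)))
        if best is None or rmse < best[1]:
            with np.errstate(invalid="ignore"):
                r = float(np.corrcoef(fitted, y_z)[0, 1])
            best = (w, rmse, r, nu)
    return best


def deconvolve_sample(
    y: np.ndarray,
    B: SignatureMatrix | pd.DataFrame | np.ndarray,
    config: DeconvConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Estimate the population fractions of one linear-scale bulk profile.

    Returns (fractions, diagnostics) where diagnostics holds the
    reconstruction ``rmse`` and ``pearson_r`` in z-score space, the
    ``chosen_nu`` (NaN for the QP path) and the ``solver`` actually used.
    """
    config = config or DeconvConfig()
    Bv = B.values.to_numpy() if isinstance(B, SignatureMatrix) else np.asarray(B)
    Bv = np.asarray(Bv, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != Bv.shape[0]:
        raise ValueError("bulk vector and signature share no common gene order")
    if not np.any(y != 0):
        raise ValueError("all-zero bulk profile")

    if config.solver == "qp":
        f = qp_oracle(y, Bv)
        fitted = Bv @ f
        rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
        r = float(np.corrcoef(fitted, y)[0, 1])
        return f, {"rmse": rmse, "pearson_r": r, "chosen_nu": np.nan, "solver": "qp"}

    y_z = _zscore(y[:, None]).ravel()
    B_z = _zscore(Bv)
    best = _nusvr_fit(y_z, B_z, config.nu_grid, config.svr_c)
    if best is None or not np.any(best[0] > 0):
        warnings.warn(
            "nu-SVR produced no usable fit for any nu; falling back to the QP solver",
            RuntimeWarning,
            stacklevel=2,
        )
        f = qp_oracle(y, Bv)
        fitted = Bv @ f
        rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
        r = float(np.corrcoef(fitted, y)[0, 1])
        return f, {
            "rmse": rmse,
            "pearson_r": r,
            "chosen_nu": np.nan,
            "solver": "qp-fallback",
        }
    w, rmse, r, nu = best
    f = np.clip(w, 0.0, None)
    f = f / f.sum()
    return f, {"rmse": rmse, "pearson_r": r, "chosen_nu": nu, "solver": "nusvr"}


def deconvolve_cohort(
    bulk: ExpressionMatrix,
    B: SignatureMatrix,
    config: DeconvConfig | None = None,
) -> FractionMatrix:
    """Deconvolve every sample of a cohort against the signature.

    ``bulk`` is the stored log2 matrix (or an already-linear one); it is
    restricted to the signature genes, which requires at least
    ``config.min_gene_overlap`` of them to be present.  Genes of the bulk
    matrix absent from the signature are simply dropped.
    """
    config = config or DeconvConfig()
    if bulk.scale == "log2":
        bulk = to_linear(bulk)
    present = [g for g in B.genes if g in set(bulk.genes)]
    overlap = len(present) / len(B.genes)
    if overlap < config.min_gene_overlap:
        raise ValueError(
            f"only {overlap:.1%} of signature genes present in bulk "
            f"(need >= {config.min_gene_overlap:.0%})"
        )
    Bv = B.values.loc[present]
    X = bulk.values.loc[present]
    rows, diags = [], []
    for s in bulk.samples:
        f, d = deconvolve_sample(X[s].to_numpy(), Bv.to_numpy(), config)
        rows.append(f)
        diags.append(d)
    values = pd.DataFrame(rows, index=bulk.samples, columns=B.populations)
    diagnostics = pd.DataFrame(diags, index=bulk.samples)
    return FractionMatrix(values, dict(B.roles), diagnostics)


def aggregate_roles(f: FractionMatrix) -> pd.DataFrame:
    """Collapse population fractions into the four-compartment accounting.

    Returns samples x {tumour, stromal, lymphoid, myeloid}; rows still sum
    to 1 because aggregation only reassigns mass.
    """
    untagged = [p for p in f.populations if p not in f.roles]
    if untagged:
        raise ValueError(f"populations without role tag: {untagged}")
    cols = {}
    for role in ROLE_ORDER:
        spec_role = "tumour-group" if role == "tumour" else role
        members = [p for p in f.populations if f.roles[p] == spec_role]
        cols[role] = f.values[members].sum(axis=1) if members else 0.0
    return pd.DataFrame(cols, index=f.values.index)
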