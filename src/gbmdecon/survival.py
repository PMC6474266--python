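"""Time-to-event machinery: censoring, KM, log-rank, Cox screens, and the
forced-variable LASSO-Cox composite risk score.

Survival records are a DataFrame with columns ``time`` (months, > 0) and
``event`` (1 = death/progression observed, 0 = censored), indexed by
sample.  Endpoints are horizon-censored before modelling (overall survival
at 24 months, disease-free survival at 12 months) so that late follow-up
differences between cohorts cannot drive the fit.

The composite model is an L1-penalised Cox regression on the patient
classification (as dummies), the immune fractions, and their interactions;
the classification dummies are *forced* (penalty factor 0) so the LASSO
can never remove them.  The fitted coefficients, the internal
standardisation parameters and the risk-group thresholds (training median
for the two-group split, training Q1/Q3 for the three-group score) are
frozen in a :class:`RiskModel` and reused verbatim on validation cohorts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "CoxFit",
    "RiskModel",
    "apply_horizon",
    "kaplan_meier",
    "logrank_test",
    "cox_univariate",
    "screen_immune_cells",
    "build_design",
    "lasso_cox",
    "linear_predictor",
    "dichotomize",
    "composite_three_groups",
]

OS_HORIZON_MONTHS = 24.0
DFS_HORIZON_MONTHS = 12.0


@dataclass
class CoxFit:
    covariate: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    flagged: bool = False  # monotone-likelihood / separation warning


@dataclass
class RiskModel:
    """A fitted penalised Cox model with frozen transfer parameters."""

    covariates: list[str]
    coefficients: dict[str, float]  # on the standardised scale
    means: dict[str, float]
    sds: dict[str, float]
    forced: list[str]
    lambda_: float
    thresholds: dict[str, float] = field(default_factory=dict)
    training_cohort: str = "discovery"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("empty survival records")
    if (records["time"] <= 0).any():
        raise ValueError("non-positive survival times")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return records


def apply_horizon(records: pd.DataFrame, horizon_months: float) -> pd.DataFrame:
    """Administratively censor all follow-up beyond the horizon."""
    if horizon_months <= 0:
        raise ValueError("horizon must be > 0")
    out = _check_records(records).copy()
    late = out["time"] > horizon_months
    out.loc[late, "time"] = horizon_months
    out.loc[late, "event"] = 0
    return out


def kaplan_meier(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Product-limit survival curve and median survival.

    Median is the first time at which S(t) <= 0.5, or inf when never
    reached.  The returned frame has columns ``time`` and ``survival``.
    """
    records = _check_records(records)
    km = KaplanMeierFitter()
    km.fit(records["time"], records["event"])
    sf = km.survival_function_.reset_index()
    sf.columns = ["time", "survival"]
    median = float(km.median_survival_time_)
    return sf, median


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> tuple[float, float]:
    """Multi-group log-rank test; returns (chi-square statistic, p)."""
    records = _check_records(records)
    groups = pd.Series(groups).loc[records.index]
    if groups.nunique() < 2:
        raise ValueError("log-rank needs at least two groups")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(records: pd.DataFrame, covariate: pd.Series) -> CoxFit:
    """Univariate Cox proportional hazards fit (Efron ties).

    If the partial likelihood is monotone (complete separation), the fit is
    repeated with a small ridge penalty and flagged.
    """
    records = _check_records(records)
    covariate = pd.Series(covariate).loc[records.index]
    x = covariate.to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    if np.ptp(x) == 0:
        raise ValueError("covariate has no variation")
    name = covariate.name or "x"
    df = pd.DataFrame({"time": records["time"], "event": records["event"], name: x})
    flagged = False
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        if abs(float(cph.params_.iloc[0])) > 20:
            raise ValueError("implausible coefficient; likely separation")
    except Exception:
        flagged = True
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    s = cph.summary.iloc[0]
    return CoxFit(
        covariate=name,
        coef=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n=len(df),
        n_events=int(records["event"].sum()),
        flagged=flagged,
    )


def screen_immune_cells(
    fractions: pd.DataFrame,
    records: pd.DataFrame,
    subgroups: pd.Series | None = None,
    min_subgroup: int = 10,
) -> pd.DataFrame:
    """Univariate Cox screen of every fraction column, overall and by subgroup.

    Each population fraction is tested as a continuous covariate against
    the survival records; subgroups smaller than ``min_subgroup`` are
    skipped (recorded with NaN estimates).
    """
    common = records.index.intersection(fractions.index)
    if len(common) == 0:
        raise ValueError("no overlap between fractions and survival records")
    records = records.loc[common]
    fractions = fractions.loc[common]
    scopes: list[tuple[str, pd.Index]] = [("all", common)]
    if subgroups is not None:
        subgroups = pd.Series(subgroups).loc[common]
        for g in sorted(subgroups.unique().astype(str)):
            scopes.append((g, common[subgroups.astype(str) == g]))
    rows = []
    for scope, idx in scopes:
        for pop in fractions.columns:
            if len(idx) < min_subgroup:
                rows.append(
                    {"population": pop, "subgroup": scope, "n": len(idx),
                     "coef": np.nan, "hr": np.nan, "p": np.nan, "skipped": True}
                )
                continue
            try:
                fit = cox_univariate(records.loc[idx], fractions.loc[idx, pop])
            except ValueError:
                rows.append(
                    {"population": pop, "subgroup": scope, "n": len(idx),
                     "coef": np.nan, "hr": np.nan, "p": np.nan, "skipped": True}
                )
                continue
            rows.append(
                {"population": pop, "subgroup": scope, "n": fit.n,
                 "coef": fit.coef, "hr": fit.hr, "p": fit.p, "skipped": False}
            )
    return pd.DataFrame(rows)


def build_design(class_labels: pd.Series, fractions: pd.DataFrame) -> pd.DataFrame:
    """Model matrix: classification dummies, fractions, and interactions.

    The alphabetically first class is the reference level (all dummies 0).
    Interaction columns are the elementwise product dummy * fraction, named
    ``class_<label>:<population>``.
    """
    class_labels = pd.Series(class_labels).astype(str)
    missing = fractions.index.difference(class_labels.index)
    if len(missing):
        raise ValueError(f"samples without class label: {list(missing[:5])}")
    class_labels = class_labels.loc[fractions.index]
    levels = sorted(class_labels.unique())
    cols = {}
    for lev in levels[1:]:
        cols[f"class_{lev}"] = (class_labels == lev).astype(float)
    for pop in fractions.columns:
        cols[str(pop)] = fractions[pop].astype(float)
    for lev in levels[1:]:
        for pop in fractions.columns:
            cols[f"class_{lev}:{pop}"] = cols[f"class_{lev}"] * fractions[pop]
    return pd.DataFrame(cols, index=fractions.index)


def _cox_partial_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                        beta: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood (used for CV deviance)."""
    order = np.argsort(-time, kind="stable")
    X, time, event = X[order], time[order], event[order]
    eta = X @ beta
    # running log-sum-exp over the risk set (samples sorted by decreasing time)
    ll = 0.0
    log_risk = -np.inf
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        chunk = eta[i:j]
        m = max(log_risk, chunk.max())
        log_risk = m + np.log(np.exp(log_risk - m) + np.exp(chunk - m).sum())
        ev = event[i:j] == 1
        if ev.any():
            ll += chunk[ev].sum() - ev.sum() * log_risk
        i = j
    return float(ll)


def lasso_cox(
    design: pd.DataFrame,
    records: pd.DataFrame,
    forced: list[str],
    folds: int = 5,
    seed: int = 0,
    alphas: list[float] | None = None,
) -> RiskModel:
    """L1-penalised Cox fit with forced covariates and CV-chosen lambda.

    Covariates are standardised internally (parameters frozen in the
    returned model).  Forced columns get penalty factor 0 and can never be
    excluded; all others get factor 1.  Lambda is chosen at the minimum of
    the k-fold cross-validated partial-likelihood deviance
    (Verweij-van Houwelingen), deterministically given the seed.  When
    every column is forced the fit reduces to an unpenalised Cox model.
    """
    records = _check_records(records).loc[design.index]
    if records["event"].sum() == 0:
        raise ValueError("no events in survival records")
    unknown = set(forced) - set(design.columns)
    if unknown:
        raise ValueError(f"forced columns not in design: {sorted(unknown)}")
    means = design.mean()
    sds = design.std(ddof=0).replace(0.0, 1.0)
    Z = ((design - means) / sds).to_numpy(dtype=float)
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    pf = np.array([0.0 if c in forced else 1.0 for c in design.columns])

    def freeze(beta: np.ndarray, lam: float) -> RiskModel:
        return RiskModel(
            covariates=list(design.columns),
            coefficients={c: float(b) for c, b in zip(design.columns, beta)},
            means={c: float(v) for c, v in means.items()},
            sds={c: float(v) for c, v in sds.items()},
            forced=list(forced),
            lambda_=float(lam),
        )

    if pf.sum() == 0:  # everything forced: plain Cox fit
        df = pd.DataFrame(Z, columns=design.columns, index=design.index)
        df["time"], df["event"] = time, event
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        return freeze(cph.params_.loc[list(design.columns)].to_numpy(), 0.0)

    def fit_path(Zt, yt, alpha_list):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0,
            penalty_factor=pf,
            alphas=alpha_list,
            n_alphas=50,
            alpha_min_ratio=0.01,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Zt, yt)
        return model

    full = fit_path(Z, y, alphas)
    path = list(full.alphas_)
    if len(path) == 1:
        beta = full.coef_[:, 0]
        return freeze(beta, path[0])

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    fold_of = np.empty(len(design), dtype=int)
    fold_of[order] = np.arange(len(design)) % folds
    dev = np.zeros(len(path))
    for f in range(folds):
        tr = fold_of != f
        model = fit_path(Z[tr], y[tr], path)
        # the solver may drop path points that fail to converge on a fold
        fold_cols = {a: j for j, a in enumerate(model.alphas_)}
        for a_idx, alpha in enumerate(path):
            j = fold_cols.get(alpha)
            if j is None:
                dev[a_idx] += np.inf
                continue
            beta = model.coef_[:, j]
            ll_full = _cox_partial_loglik(Z, time, event, beta)
            ll_train = _cox_partial_loglik(Z[tr], time[tr], event[tr], beta)
            dev[a_idx] += -2.0 * (ll_full - ll_train)
    best_idx = int(np.argmin(dev))
    lam = path[best_idx]
    beta = full.coef_[:, best_idx]
    return freeze(beta, lam)


def linear_predictor(model: RiskModel, design: pd.DataFrame) -> pd.Series:
    """Risk score eta = sum coef * z(x) using training standardisation."""
    missing = set(model.covariates) - set(design.columns)
    if missing:
        raise ValueError(f"design lacks model covariates: {sorted(missing)}")
    eta = np.zeros(len(design))
    for c in model.covariates:
        z = (design[c].to_numpy(dtype=float) - model.means[c]) / model.sds[c]
        eta += model.coefficients[c] * z
    return pd.Series(eta, index=design.index, name="linear_predictor")


def dichotomize(scores: pd.Series, threshold: float) -> pd.Series:
    """Split into low/high risk at a frozen (training-median) threshold.

    Scores above the threshold are high risk; ties go to low.  The
    threshold is never recomputed on validation data.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, name="risk_group"
    )


def composite_three_groups(
    lp_scores: pd.Series,
    ages: pd.Series,
    records: pd.DataFrame,
    thresholds: tuple[float, float] | None = None,
    coefs: dict[str, float] | None = None,
) -> tuple[pd.Series, tuple[float, float], dict[str, float]]:
    """Age-augmented composite score with a three-tier risk grouping.

    Fits a Cox model on (linear predictor, age), takes its linear predictor
    as the composite score, and cuts at the training first and third
    quartiles into low/medium/high risk.  Pass the frozen ``thresholds``
    and ``coefs`` returned from the training call to transfer the grouping
    to a validation cohort unchanged.
    """
    common = records.index.intersection(lp_scores.index).intersection(ages.index)
    records = _check_records(records.loc[common])
    df = pd.DataFrame(
        {
            "time": records["time"],
            "event": records["event"],
            "lp": lp_scores.loc[common],
            "age": ages.loc[common].astype(float),
        }
    )
    if coefs is None:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coefs = {"lp": float(cph.params_["lp"]), "age": float(cph.params_["age"])}
    score = coefs["lp"] * df["lp"] + coefs["age"] * df["age"]
    if thresholds is None:
        thresholds = (float(score.quantile(0.25)), float(score.quantile(0.75)))
    q1, q3 = thresholds
    labels = pd.Series(
        np.select([score <= q1, score <= q3], ["low", "medium"], default="high"),
        index=score.index,
        name="risk_tier",
    )
    return labels, (q1, q3), coefs


def composite_score(
    coefs: dict[str, float], lp_scores: pd.Series, ages: pd.Series
) -> pd.Series:
    """Apply frozen composite coefficients to a (possibly new) cohort."""
    return coefs["lp"] * lp_scores + coefs["age"] * ages.astype(float)
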