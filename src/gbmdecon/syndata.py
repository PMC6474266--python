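"""Synthetic reference panels, bulk cohorts and survival outcomes.

Every generator is a pure function of its seed and emulates one structural
assumption of the analysis: a reference panel of pure tumour cell lines
with a latent group structure, pure immune/stromal reference profiles with
disjoint marker blocks, bulk tumours that are convex mixtures of the
references in linear intensity space, and survival times whose hazard
depends on known covariates.  The ground truth (cluster labels, mixing
fractions, hazard coefficients) ships with the data so that every pipeline
stage can be checked against it.

Conventions: expression is generated in log2 scale; mixing happens in
linear scale (2**x - 1) because cell populations contribute additively to
measured intensity, and mixtures are shipped back as log2(x + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix, to_linear
from .signatures import SignatureMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_reference_panel",
    "simulate_immune_references",
    "simulate_bulk_cohort",
    "simulate_survival",
    "synthesize_study",
    "DEFAULT_IMMUNE_POPULATIONS",
]

#: Pure reference populations emulating a stromal profile plus lymphoid and
#: myeloid subsets quantified in tumours.
DEFAULT_IMMUNE_POPULATIONS = {
    "stromal": "stromal",
    "B_cells": "lymphoid",
    "NK": "lymphoid",
    "Treg": "lymphoid",
    "Th2": "lymphoid",
    "CD8_central_memory": "lymphoid",
    "macrophages_M1": "myeloid",
    "macrophages_M2": "myeloid",
    "monocytes": "myeloid",
    "dendritic_cells": "myeloid",
}


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic dataset."""

    true_cluster_of_reference: pd.Series | None = None
    true_fractions: pd.DataFrame | None = None
    true_hazard_coefs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.true_fractions is not None:
            f = self.true_fractions.to_numpy()
            if np.any(f < 0):
                raise AssertionError("negative true fraction")
            if np.max(np.abs(f.sum(axis=1) - 1.0)) > 1e-9:
                raise AssertionError("true fractions do not sum to 1")


def simulate_reference_panel(
    n_genes: int = 2000,
    n_per_group: int = 43,
    k_groups: int = 3,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Reference panel of pure tumour cell lines with a latent group structure.

    Defaults emulate a panel of ~129 glioblastoma cell-line transcriptomes
    falling into three latent groups.  Each group owns a disjoint block of
    ``n_genes // (2 * k_groups)`` marker genes whose mean is shifted up by
    ``effect_size`` log2 units in that group; all entries carry i.i.d.
    Gaussian noise of sd ``noise_sd`` around a per-gene baseline.
    """
    if n_genes < 10 * k_groups:
        raise ValueError("n_genes must be at least 10 * k_groups")
    if n_per_group < 1 or k_groups < 2:
        raise ValueError("non-positive dimensions")
    if effect_size < 0 or noise_sd <= 0:
        raise ValueError("effect_size must be >= 0 and noise_sd > 0")
    rng = np.random.default_rng(seed)
    n_samples = n_per_group * k_groups
    baseline = rng.uniform(3.0, 8.0, size=n_genes)
    X = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    block = n_genes // (2 * k_groups)
    labels = np.repeat(np.arange(1, k_groups + 1), n_per_group)
    for g in range(k_groups):
        cols = labels == g + 1
        X[g * block : (g + 1) * block][:, cols] += effect_size
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"CL{j:03d}" for j in range(n_samples)]
    m = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), "log2")
    truth = SyntheticTruth(
        true_cluster_of_reference=pd.Series(labels, index=samples, name="cluster"),
        seed=seed,
    )
    return m, truth


def marker_blocks(n_genes: int, k_groups: int) -> dict[int, list[str]]:
    """Gene ids of the planted marker block of each reference group."""
    block = n_genes // (2 * k_groups)
    return {
        g + 1: [f"G{i:05d}" for i in range(g * block, (g + 1) * block)]
        for g in range(k_groups)
    }


def simulate_immune_references(
    n_genes: int = 2000,
    populations: list[str] | None = None,
    marker_frac: float = 0.02,
    marker_shift: float = 4.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline_seed: int | None = None,
) -> ExpressionMatrix:
    """One pure log2 profile per immune/stromal population.

    Each population owns a disjoint block of ``round(marker_frac * n_genes)``
    marker genes elevated by ``marker_shift`` log2 units.  Marker blocks are
    taken from the top of the gene list downward, so they never collide with
    the tumour marker blocks of :func:`simulate_reference_panel` (which
    occupy the bottom half) when both use the same ``n_genes``.

    ``baseline_seed`` fixes the shared per-gene baseline independently of
    the per-profile noise, so a population can be "re-noised" (same
    baseline, fresh measurement noise) by varying ``seed`` alone.
    """
    if populations is None:
        populations = list(DEFAULT_IMMUNE_POPULATIONS)
    if not populations:
        raise ValueError("populations must be non-empty")
    if len(set(populations)) != len(populations):
        raise ValueError("duplicate population names")
    n_markers = int(round(marker_frac * n_genes))
    if n_markers * len(populations) > n_genes // 2:
        raise ValueError("marker blocks exceed the reserved half of the gene list")
    rng = np.random.default_rng(seed)
    base_rng = rng if baseline_seed is None else np.random.default_rng(baseline_seed)
    baseline = base_rng.uniform(3.0, 8.0, size=n_genes)
    X = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, len(populations)))
    for j, _pop in enumerate(populations):
        top = n_genes - j * n_markers
        X[top - n_markers : top, j] += marker_shift
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return ExpressionMatrix(pd.DataFrame(X, index=genes, columns=populations), "log2")


def immune_marker_blocks(
    n_genes: int, populations: list[str], marker_frac: float
) -> dict[str, list[str]]:
    """Gene ids of the planted marker block of each immune population."""
    n_markers = int(round(marker_frac * n_genes))
    out = {}
    for j, pop in enumerate(populations):
        top = n_genes - j * n_markers
        out[pop] = [f"G{i:05d}" for i in range(top - n_markers, top)]
    return out


def simulate_bulk_cohort(
    ref_signature: SignatureMatrix,
    n_samples: int = 200,
    dirichlet_alpha: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_prefix: str = "S",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Bulk tumours as convex mixtures of the signature columns.

    In linear scale, sample i = B @ f_i + N(0, noise_sd) truncated at 0,
    with f_i ~ Dirichlet(alpha); the draw is stored in the truth.  The
    default alpha gives tumour groups weight 10 and each stromal/immune
    population 0.25, so the expected non-tumour mass stays below 10% of
    all cells whatever the number of immune populations — the
    low-infiltration regime the deconvolution must resolve.  Output is
    shipped in log2(x + 1).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    pops = ref_signature.populations
    if dirichlet_alpha is None:
        dirichlet_alpha = np.array(
            [
                10.0 if ref_signature.roles.get(p) == "tumour-group" else 0.25
                for p in pops
            ]
        )
    dirichlet_alpha = np.asarray(dirichlet_alpha, dtype=float)
    if dirichlet_alpha.shape != (len(pops),):
        raise ValueError(
            f"dirichlet_alpha length {dirichlet_alpha.size} != {len(pops)} populations"
        )
    if np.any(dirichlet_alpha <= 0):
        raise ValueError("dirichlet_alpha entries must be > 0")
    rng = np.random.default_rng(seed)
    F = rng.dirichlet(dirichlet_alpha, size=n_samples)
    B = ref_signature.values.to_numpy()
    X = B @ F.T
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    X = np.maximum(X, 0.0)
    samples = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    bulk = ExpressionMatrix(
        pd.DataFrame(np.log2(X + 1.0), index=ref_signature.genes, columns=samples),
        "log2",
    )
    truth = SyntheticTruth(
        true_fractions=pd.DataFrame(F, index=samples, columns=pops), seed=seed
    )
    truth.validate()
    return bulk, truth


def simulate_survival(
    covariates: pd.DataFrame,
    hazard_coefs: dict[str, float],
    baseline_rate: float = 0.05,
    censor_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival with proportional hazards on known covariates.

    Event time ~ Exp(rate = baseline_rate * exp(sum coef * x)), censoring
    time ~ Exp(censor_rate) independently; the observed record is the
    earlier of the two.  Rates are per month.  Returns a frame with
    columns sample_id, time, event indexed like ``covariates``.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    missing = set(hazard_coefs) - set(covariates.columns)
    if missing:
        raise ValueError(f"hazard_coefs name unknown covariates: {sorted(missing)}")
    sub = covariates[list(hazard_coefs)] if hazard_coefs else covariates.iloc[:, :0]
    if not np.all(np.isfinite(sub.to_numpy(dtype=float))):
        raise ValueError("covariates must be finite")
    rng = np.random.default_rng(seed)
    eta = np.zeros(len(covariates))
    for name, coef in hazard_coefs.items():
        eta = eta + coef * covariates[name].to_numpy(dtype=float)
    rate = baseline_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=len(covariates))
    else:
        t_cens = np.full(len(covariates), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event}, index=covariates.index.rename("sample_id")
    )


def synthesize_study(
    seed: int = 0,
    n_genes: int = 2000,
    n_per_group: int = 43,
    k_groups: int = 3,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    n_discovery: int = 200,
    n_validation: int = 100,
    bulk_noise_frac: float = 0.05,
    cluster_log_hr: float = 3.0,
    immune_log_hr: float = 10.0,
    risk_population: str = "Treg",
    baseline_rate: float = 0.06,
    censor_rate: float = 0.01,
) -> dict:
    """A complete two-cohort synthetic study with planted risk structure.

    Generates the reference cell-line panel, immune/stromal references,
    discovery and validation bulk cohorts mixed from the true population
    profiles, and survival outcomes whose hazard increases for tumours
    dominated by the third tumour group (``cluster_log_hr`` on its true
    fraction) and for tumours rich in ``risk_population``
    (``immune_log_hr`` per unit fraction; immune fractions live below 0.1,
    hence the large per-unit coefficient).

    Patient cluster structure is induced by drawing each bulk sample's
    dominant tumour group at random and concentrating its Dirichlet mass
    there (alpha 24 on the dominant group, 3 on the others, 1 on each
    stromal/immune population).
    """
    rng = np.random.default_rng(seed)
    panel, panel_truth = simulate_reference_panel(
        n_genes, n_per_group, k_groups, effect_size, noise_sd, seed=int(rng.integers(2**31))
    )
    immune_pops = list(DEFAULT_IMMUNE_POPULATIONS)
    immune = simulate_immune_references(
        n_genes, immune_pops, seed=int(rng.integers(2**31))
    )
    # true (noise-free) population profiles used for mixing
    tumour_names = [f"tumour_{g}" for g in range(1, k_groups + 1)]
    panel_lin = to_linear(panel)
    tumour_profiles = {
        name: panel_lin.values.loc[
            :, panel_truth.true_cluster_of_reference.index[
                panel_truth.true_cluster_of_reference == g
            ]
        ].mean(axis=1)
        for g, name in enumerate(tumour_names, start=1)
    }
    immune_lin = to_linear(immune)
    profiles = pd.DataFrame({**tumour_profiles, **immune_lin.values.to_dict("series")})
    roles = {name: "tumour-group" for name in tumour_names}
    roles.update(DEFAULT_IMMUNE_POPULATIONS)
    mixing_basis = SignatureMatrix(profiles, roles)

    mean_signal = float(profiles.to_numpy().mean())

    def make_cohort(n: int, prefix: str, cohort_seed: int):
        crng = np.random.default_rng(cohort_seed)
        dominant = crng.integers(0, k_groups, size=n)
        F = np.empty((n, len(profiles.columns)))
        alphas = np.full(len(profiles.columns), 0.25)
        for i in range(n):
            a = alphas.copy()
            a[:k_groups] = 3.0
            a[dominant[i]] = 24.0
            F[i] = crng.dirichlet(a)
        B = profiles.to_numpy()
        X = B @ F.T + crng.normal(0, bulk_noise_frac * mean_signal, size=(B.shape[0], n))
        X = np.maximum(X, 0)
        samples = [f"{prefix}{i:04d}" for i in range(n)]
        bulk = ExpressionMatrix(
            pd.DataFrame(np.log2(X + 1), index=list(profiles.index), columns=samples),
            "log2",
        )
        fr = pd.DataFrame(F, index=samples, columns=list(profiles.columns))
        ages = crng.uniform(40, 80, size=n)
        covs = pd.DataFrame(
            {
                "risk_group_fraction": fr[tumour_names[-1]],
                risk_population: fr[risk_population],
                "age": ages,
            },
            index=fr.index.rename("sample_id"),
        )
        coefs = {
            "risk_group_fraction": cluster_log_hr,
            risk_population: immune_log_hr,
            "age": 0.023,
        }
        # centre age so the baseline rate applies to the average patient
        covs_c = covs.copy()
        covs_c["age"] = covs_c["age"] - 60.0
        surv = simulate_survival(
            covs_c, coefs, baseline_rate, censor_rate, seed=cohort_seed + 1
        )
        truth = SyntheticTruth(
            true_fractions=fr,
            true_hazard_coefs=coefs,
            true_cluster_of_reference=pd.Series(
                dominant + 1, index=samples, name="cluster"
            ),
            seed=cohort_seed,
        )
        ann = pd.DataFrame({"age": ages}, index=fr.index.rename("sample_id"))
        return {"bulk": bulk, "truth": truth, "survival": surv, "annotations": ann}

    discovery = make_cohort(n_discovery, "D", int(rng.integers(2**31)))
    validation = make_cohort(n_validation, "V", int(rng.integers(2**31)))
    return {
        "panel": panel,
        "panel_truth": panel_truth,
        "immune": immune,
        "mixing_basis": mixing_basis,
        "discovery": discovery,
        "validation": validation,
        "tumour_names": tumour_names,
        "seed": seed,
    }
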