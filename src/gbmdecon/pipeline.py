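"""End-to-end orchestration: discovery fit, validation transfer, artifacts.

The pipeline mirrors the analysis it implements: cluster the pure tumour
reference panel, derive a differential-expression signature of the groups,
deconvolve both bulk cohorts against tumour + stromal + immune references,
cluster patients on their tumour-group fractions (discovery) and transfer
the labels by random forest (validation), then fit the forced-variable
LASSO-Cox composite score on discovery and evaluate it on both cohorts
with frozen coefficients and thresholds.

Every stage writes its result as CSV/JSON under the output directory and
records itself in ``manifest.json`` (seed, shapes, content hashes), so
stages communicate only through declared artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, cluster, deconv, signatures, survival, syndata
from .exprio import (
    ExpressionMatrix,
    read_annotations,
    read_expression,
    to_linear,
    write_expression,
)

__all__ = ["default_config", "run_pipeline", "write_study", "select_immune_marker_genes"]


def default_config() -> dict:
    """Tunables of every stage, at the defaults each module documents."""
    return {
        "seed": 0,
        "signature": {"fdr": 0.05, "top_g": 50},
        "deconv": {"solver": "nusvr", "nu_grid": [0.25, 0.5, 0.75]},
        "cluster": {"n_components": 5, "k_max": 10, "k_range": [2, 6], "b_refs": 50},
        "classify": {"n_trees": 500},
        "survival": {"horizon": survival.OS_HORIZON_MONTHS, "folds": 5},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and k in base else v
    return out


def select_immune_marker_genes(
    immune: ExpressionMatrix, top_g: int = 50
) -> dict[str, list[str]]:
    """Marker genes for single-profile reference populations.

    With one profile per population a t-test is unavailable; markers are
    the ``top_g`` genes with the largest log2 ratio of the population over
    the mean of all other populations, disjointified by assigning each
    gene to its strongest population.
    """
    vals = immune.values
    best_pop = {}
    ratios = {}
    for pop in vals.columns:
        others = vals.drop(columns=pop).mean(axis=1)
        ratios[pop] = vals[pop] - others
    ratio_df = pd.DataFrame(ratios)
    winner = ratio_df.idxmax(axis=1)
    out = {}
    for pop in vals.columns:
        own = ratio_df.loc[winner == pop, pop].sort_values(ascending=False)
        out[pop] = list(own.head(top_g).index)
    return out


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.round(10), index=True).to_numpy().tobytes()
    ).hexdigest()[:16]


def write_study(study: dict, outdir: str | Path) -> Path:
    """Serialise a synthetic study to the input files the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(study["panel"], outdir / "reference_panel.tsv")
    write_expression(study["immune"], outdir / "immune_references.tsv")
    pd.Series(study["mixing_basis"].roles, name="role").rename_axis(
        "population"
    ).to_csv(outdir / "population_roles.csv")
    study["panel_truth"].true_cluster_of_reference.rename_axis("sample_id").to_csv(
        outdir / "truth_panel_clusters.csv"
    )
    for cohort in ("discovery", "validation"):
        c = study[cohort]
        write_expression(c["bulk"], outdir / f"{cohort}_bulk.tsv")
        c["survival"].to_csv(outdir / f"{cohort}_survival.csv")
        c["annotations"].to_csv(outdir / f"{cohort}_annotations.csv")
        c["truth"].true_fractions.rename_axis("sample_id").to_csv(
            outdir / f"truth_{cohort}_fractions.csv"
        )
    config = default_config()
    config["seed"] = study["seed"]
    config["inputs"] = {
        "reference_panel": str(outdir / "reference_panel.tsv"),
        "immune_references": str(outdir / "immune_references.tsv"),
        "population_roles": str(outdir / "population_roles.csv"),
        "discovery_bulk": str(outdir / "discovery_bulk.tsv"),
        "discovery_survival": str(outdir / "discovery_survival.csv"),
        "discovery_annotations": str(outdir / "discovery_annotations.csv"),
        "validation_bulk": str(outdir / "validation_bulk.tsv"),
        "validation_survival": str(outdir / "validation_survival.csv"),
        "validation_annotations": str(outdir / "validation_annotations.csv"),
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return outdir / "config.yaml"


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the full analysis; returns the in-memory results dictionary.

    ``config`` is either a mapping or a path to a YAML file following
    :func:`default_config` plus an ``inputs`` section.  Validation-cohort
    stages are skipped when no validation inputs are configured.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(default_config(), config)
    inputs = cfg.get("inputs")
    if inputs is None:
        raise ValueError("config lacks an 'inputs' section")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    def fail(stage: str, exc: Exception) -> Exception:
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # ---- load ----
    try:
        panel = read_expression(inputs["reference_panel"])
        immune = read_expression(inputs["immune_references"])
        roles = (
            pd.read_csv(inputs["population_roles"], index_col=0)["role"].to_dict()
        )
        disc_bulk = read_expression(inputs["discovery_bulk"])
        disc_surv = pd.read_csv(inputs["discovery_survival"], index_col=0)
        disc_ann = read_annotations(inputs["discovery_annotations"])
        has_validation = "validation_bulk" in inputs
        if has_validation:
            val_bulk = read_expression(inputs["validation_bulk"])
            val_surv = pd.read_csv(inputs["validation_survival"], index_col=0)
            val_ann = read_annotations(inputs["validation_annotations"])
    except Exception as exc:
        raise fail("load", exc)
    record("load", panel=panel.shape, discovery=disc_bulk.shape,
           validation=val_bulk.shape if has_validation else None)

    # ---- cluster the reference panel (HCPC) ----
    try:
        scores = cluster.pca_scores(panel, cfg["cluster"]["n_components"])
        cell_clusters = cluster.hcpc_cluster(scores, cfg["cluster"]["k_max"])
    except Exception as exc:
        raise fail("cluster_cells", exc)
    cell_labels = cell_clusters.labels.map(lambda g: f"tumour_{g}")
    cell_labels.rename_axis("sample_id").rename("group").to_csv(
        outdir / "cell_line_clusters.csv"
    )
    record("cluster_cells", k=cell_clusters.k)

    # ---- signature ----
    try:
        de = signatures.moderated_t_one_vs_rest(panel, cell_labels)
        tumour_markers = signatures.select_signature_genes(
            de, cfg["signature"]["fdr"], cfg["signature"]["top_g"]
        )
        immune_markers = select_immune_marker_genes(immune, cfg["signature"]["top_g"])
        gene_union = sorted(
            {g for genes in tumour_markers.values() for g in genes}
            | {g for genes in immune_markers.values() for g in genes}
        )
        panel_lin = to_linear(panel)
        immune_lin = to_linear(immune)
        tumour_cols = {
            grp: panel_lin.values.loc[gene_union, cell_labels.index[cell_labels == grp]]
            .mean(axis=1)
            for grp in sorted(cell_labels.unique())
        }
        basis_values = pd.DataFrame(tumour_cols).join(
            immune_lin.values.loc[gene_union]
        )
        sig_roles = {grp: "tumour-group" for grp in tumour_cols}
        sig_roles.update({p: roles[p] for p in immune.samples})
        basis = signatures.SignatureMatrix(basis_values, sig_roles)
    except Exception as exc:
        raise fail("signature", exc)
    de.to_csv(outdir / "differential_expression.csv", index=False)
    signatures.write_signature(basis, outdir / "signature_matrix.tsv")
    record("signature", genes=len(gene_union), populations=len(basis.populations),
           condition_number=basis.condition_number())

    # ---- deconvolution ----
    dcfg = deconv.DeconvConfig(
        solver=cfg["deconv"]["solver"], nu_grid=tuple(cfg["deconv"]["nu_grid"])
    )
    try:
        disc_frac = deconv.deconvolve_cohort(disc_bulk, basis, dcfg)
        val_frac = (
            deconv.deconvolve_cohort(val_bulk, basis, dcfg) if has_validation else None
        )
    except Exception as exc:
        raise fail("deconv", exc)
    disc_frac.values.rename_axis("sample_id").to_csv(outdir / "discovery_fractions.csv")
    disc_frac.diagnostics.rename_axis("sample_id").to_csv(
        outdir / "discovery_deconv_diagnostics.csv"
    )
    if has_validation:
        val_frac.values.rename_axis("sample_id").to_csv(
            outdir / "validation_fractions.csv"
        )
    record("deconv", discovery_hash=_hash_df(disc_frac.values))

    # ---- patient clustering + transfer ----
    tumour_cols_list = [
        p for p in basis.populations if basis.roles[p] == "tumour-group"
    ]
    nontumour_cols = [p for p in basis.populations if p not in tumour_cols_list]
    try:
        k_lo, k_hi = cfg["cluster"]["k_range"]
        chosen_k, gap_curve = cluster.gap_statistic(
            disc_frac.values[tumour_cols_list],
            (k_lo, k_hi),
            cfg["cluster"]["b_refs"],
            seed=seed,
        )
        patient_clusters = cluster.ward_cluster(
            disc_frac.values[tumour_cols_list], chosen_k
        )
        disc_class = patient_clusters.labels.map(lambda g: f"C{g}")
        if has_validation:
            val_class = classify.rf_transfer(
                disc_frac.values,
                disc_class,
                val_frac.values,
                cfg["classify"]["n_trees"],
                seed=seed,
            )
    except Exception as exc:
        raise fail("cluster_patients", exc)
    gap_curve.to_csv(outdir / "gap_curve.csv", index=False)
    disc_class.rename_axis("sample_id").rename("class").to_csv(
        outdir / "discovery_patient_classes.csv"
    )
    if has_validation:
        val_class.rename_axis("sample_id").rename("class").to_csv(
            outdir / "validation_patient_classes.csv"
        )
    record("cluster_patients", k=chosen_k)

    # ---- survival ----
    try:
        horizon = cfg["survival"]["horizon"]
        disc_records = survival.apply_horizon(disc_surv, horizon)
        screen = survival.screen_immune_cells(
            disc_frac.values[nontumour_cols], disc_records, disc_class
        )
        design = survival.build_design(disc_class, disc_frac.values[nontumour_cols])
        forced = [c for c in design.columns if c.startswith("class_") and ":" not in c]
        model = survival.lasso_cox(
            design, disc_records, forced, cfg["survival"]["folds"], seed=seed
        )
        lp = survival.linear_predictor(model, design)
        model.thresholds["median"] = float(lp.median())
        disc_groups = survival.dichotomize(lp, model.thresholds["median"])
        disc_chi2, disc_p = survival.logrank_test(disc_records, disc_groups)
        tiers, (q1, q3), comp_coefs = survival.composite_three_groups(
            lp, disc_ann["age"], disc_records
        )
        model.thresholds["q1"], model.thresholds["q3"] = q1, q3
        results_val = {}
        if has_validation:
            val_records = survival.apply_horizon(val_surv, horizon)
            val_design = survival.build_design(
                val_class, val_frac.values[nontumour_cols]
            )
            val_lp = survival.linear_predictor(model, val_design)
            val_groups = survival.dichotomize(val_lp, model.thresholds["median"])
            val_chi2, val_p = survival.logrank_test(val_records, val_groups)
            val_tiers, _, _ = survival.composite_three_groups(
                val_lp, val_ann["age"], val_records,
                thresholds=(q1, q3), coefs=comp_coefs,
            )
            results_val = {
                "records": val_records,
                "lp": val_lp,
                "risk_groups": val_groups,
                "logrank_chi2": val_chi2,
                "logrank_p": val_p,
                "tiers": val_tiers,
            }
    except Exception as exc:
        raise fail("survival", exc)
    screen.to_csv(outdir / "immune_cox_screen.csv", index=False)
    model.to_json(outdir / "risk_model.json")
    lp.rename_axis("sample_id").to_csv(outdir / "discovery_linear_predictor.csv")
    disc_groups.rename_axis("sample_id").to_csv(outdir / "discovery_risk_groups.csv")
    tiers.rename_axis("sample_id").to_csv(outdir / "discovery_risk_tiers.csv")
    for name, groups, records_ in (
        ("discovery", disc_groups, disc_records),
        *(
            [("validation", results_val["risk_groups"], results_val["records"])]
            if has_validation
            else []
        ),
    ):
        curves = []
        for g in sorted(groups.unique()):
            sf, med = survival.kaplan_meier(records_.loc[groups.index[groups == g]])
            sf["group"] = g
            sf["median_survival"] = med
            curves.append(sf)
        pd.concat(curves).to_csv(outdir / f"{name}_km_curves.csv", index=False)
    record(
        "survival",
        discovery_logrank_p=disc_p,
        validation_logrank_p=results_val.get("logrank_p"),
        lambda_=model.lambda_,
        nonzero=[c for c, b in model.coefficients.items() if b != 0],
    )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    out = {
        "cell_clusters": cell_clusters,
        "signature": basis,
        "discovery": {
            "fractions": disc_frac,
            "classes": disc_class,
            "records": disc_records,
            "lp": lp,
            "risk_groups": disc_groups,
            "logrank_chi2": disc_chi2,
            "logrank_p": disc_p,
            "tiers": tiers,
        },
        "model": model,
        "screen": screen,
        "manifest": manifest,
    }
    if has_validation:
        out["validation"] = results_val
        out["validation"]["classes"] = val_class
        out["validation"]["fractions"] = val_frac
    return out
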