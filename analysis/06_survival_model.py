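"""Prognostic modelling: immune Cox screen, forced-variable LASSO, risk groups.

Overall survival is censored at 24 months.  Each immune fraction is
screened with univariate Cox models (overall and within patient classes).
The composite model is an L1-penalised Cox fit on patient-class dummies
(forced), immune fractions, and their interactions; its linear predictor
is split at the discovery median into two risk groups, and the
median/quartile thresholds plus coefficients are frozen and re-applied
verbatim to the validation cohort.  A final Cox fit on (linear predictor,
age) gives the three-tier composite score.

Reads results/study/ and results/analysis/; writes the Cox screen, the
risk model JSON, per-cohort risk groups, KM curves and a summary.
"""

from pathlib import Path

import pandas as pd

from gbmdecon import survival
from gbmdecon.exprio import read_annotations

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
HORIZON = survival.OS_HORIZON_MONTHS


def main() -> None:
    out = ROOT / "analysis"
    data = {}
    for cohort in ("discovery", "validation"):
        data[cohort] = {
            "fractions": pd.read_csv(out / f"{cohort}_fractions.csv", index_col=0),
            "classes": pd.read_csv(
                out / f"{cohort}_patient_classes.csv", index_col=0
            )["class"],
            "records": survival.apply_horizon(
                pd.read_csv(ROOT / "study" / f"{cohort}_survival.csv", index_col=0),
                HORIZON,
            ),
            "ann": read_annotations(ROOT / "study" / f"{cohort}_annotations.csv"),
        }
    disc = data["discovery"]
    immune_cols = [c for c in disc["fractions"].columns if not c.startswith("tumour_")]

    screen = survival.screen_immune_cells(
        disc["fractions"][immune_cols], disc["records"], disc["classes"]
    )
    screen.to_csv(out / "immune_cox_screen.csv", index=False)
    hits = screen[(screen["subgroup"] == "all") & (screen["p"] < 0.05)]
    print("immune populations associated with OS (p<0.05, discovery):",
          list(hits["population"]))

    design = survival.build_design(disc["classes"], disc["fractions"][immune_cols])
    forced = [c for c in design.columns if c.startswith("class_") and ":" not in c]
    model = survival.lasso_cox(design, disc["records"], forced, folds=5, seed=SEED)
    lp = survival.linear_predictor(model, design)
    model.thresholds["median"] = float(lp.median())
    nonzero = {c: round(b, 3) for c, b in model.coefficients.items() if b != 0.0}
    print(f"LASSO kept {len(nonzero)} variables (classification forced): {nonzero}")

    tiers, (q1, q3), comp_coefs = survival.composite_three_groups(
        lp, disc["ann"]["age"], disc["records"]
    )
    model.thresholds["q1"], model.thresholds["q3"] = q1, q3
    model.to_json(out / "risk_model.json")

    for cohort in ("discovery", "validation"):
        d = data[cohort]
        dsg = survival.build_design(d["classes"], d["fractions"][immune_cols])
        lp_c = survival.linear_predictor(model, dsg)
        groups = survival.dichotomize(lp_c, model.thresholds["median"])
        chi2, p = survival.logrank_test(d["records"], groups)
        tiers_c, _, _ = survival.composite_three_groups(
            lp_c, d["ann"]["age"], d["records"],
            thresholds=(q1, q3), coefs=comp_coefs,
        )
        pd.DataFrame(
            {"linear_predictor": lp_c, "risk_group": groups, "risk_tier": tiers_c}
        ).rename_axis("sample_id").to_csv(out / f"{cohort}_risk_groups.csv")
        curves, medians = [], {}
        for g in sorted(groups.unique()):
            sf, med = survival.kaplan_meier(d["records"].loc[groups.index[groups == g]])
            sf["group"] = g
            curves.append(sf)
            medians[g] = round(med, 1)
        pd.concat(curves).to_csv(out / f"{cohort}_km_curves.csv", index=False)
        print(f"{cohort}: median OS by risk group (months) {medians}; "
              f"log-rank chi2 = {chi2:.1f}, p = {p:.2g} "
              f"(frozen discovery threshold)")


if __name__ == "__main__":
    main()
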