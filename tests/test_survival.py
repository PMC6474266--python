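import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gbmdecon import syndata
from gbmdecon.survival import (
    RiskModel,
    apply_horizon,
    build_design,
    composite_score,
    composite_three_groups,
    cox_univariate,
    dichotomize,
    kaplan_meier,
    lasso_cox,
    linear_predictor,
    logrank_test,
    screen_immune_cells,
)


def _records(times, events, prefix="s"):
    return pd.DataFrame(
        {"time": times, "event": events},
        index=[f"{prefix}{i}" for i in range(len(times))],
    )


class TestApplyHorizon:
    def test_late_event_censored_at_horizon(self):
        out = apply_horizon(_records([30.0], [1]), 24.0)
        assert out.iloc[0]["time"] == 24.0 and out.iloc[0]["event"] == 0

    def test_early_event_unchanged(self):
        out = apply_horizon(_records([10.0], [1]), 24.0)
        assert out.iloc[0]["time"] == 10.0 and out.iloc[0]["event"] == 1

    def test_event_count_never_increases(self):
        rng = np.random.default_rng(0)
        rec = _records(rng.exponential(15, 100), rng.integers(0, 2, 100))
        assert apply_horizon(rec, 12.0)["event"].sum() <= rec["event"].sum()

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError):
            apply_horizon(_records([0.0], [1]), 24.0)


class TestKaplanMeier:
    def test_hand_worked_four_subject_curve(self):
        # events at 1,2,3,4 with no censoring: S = .75, .5, .25, 0; median 2
        sf, median = kaplan_meier(_records([1, 2, 3, 4], [1, 1, 1, 1]))
        lookup = sf.set_index("time")["survival"]
        assert np.allclose(lookup.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])
        assert median == 2

    def test_all_censored_curve_stays_at_one(self):
        sf, median = kaplan_meier(_records([5, 8, 12], [0, 0, 0]))
        assert (sf["survival"] == 1.0).all()
        assert np.isinf(median)

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(1)
        sf, _ = kaplan_meier(_records(rng.exponential(10, 50), rng.integers(0, 2, 50)))
        s = sf["survival"].to_numpy()
        assert s[0] <= 1.0 and np.all(np.diff(s) <= 1e-12)
        assert sf.iloc[0]["survival"] == 1.0 or sf.iloc[0]["time"] > 0


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        rec = _records([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        groups = pd.Series(["a", "a", "a", "b", "b", "b"], index=rec.index)
        chi2, p = logrank_test(rec, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_worked_six_subject_example(self):
        """Manual O-E/V arithmetic on a 6-subject two-group dataset."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 0, 1]
        groups = ["a", "b", "a", "b", "a", "b"]
        rec = _records(times, events)
        gs = pd.Series(groups, index=rec.index)
        # manual computation over distinct event times
        o_minus_e, var = 0.0, 0.0
        for t, ev, n_a, n in [
            (1.0, 1, 3, 6), (2.0, 1, 2, 5), (3.0, 1, 2, 4), (4.0, 1, 1, 3), (6.0, 1, 0, 1)
        ]:
            d = 1
            e_a = d * n_a / n
            obs_a = 1 if (t in (1.0, 3.0)) else 0
            o_minus_e += obs_a - e_a
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / max(n - 1, 1)
        manual_chi2 = o_minus_e**2 / var
        chi2, _ = logrank_test(rec, gs)
        assert chi2 == pytest.approx(manual_chi2, abs=1e-6)

    def test_chi_square_anchor(self):
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_single_group_rejected(self):
        rec = _records([1, 2], [1, 1])
        with pytest.raises(ValueError):
            logrank_test(rec, pd.Series(["a", "a"], index=rec.index))


class TestCoxUnivariate:
    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        cov = pd.DataFrame({"x": rng.integers(0, 2, n).astype(float)},
                           index=[f"s{i}" for i in range(n)])
        rec = syndata.simulate_survival(cov, {"x": 0.0}, 0.05, 0.01, seed=3)
        fit = cox_univariate(rec, cov["x"])
        assert abs(fit.coef) < 0.3 and fit.p > 0.001

    def test_recovers_planted_log_hazard(self):
        """Planted log-HR 0.7 on a binary covariate, n=500, 20 seeds."""
        coefs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            cov = pd.DataFrame({"x": rng.integers(0, 2, 500).astype(float)},
                               index=[f"s{i}" for i in range(500)])
            rec = syndata.simulate_survival(cov, {"x": 0.7}, 0.05, 0.005, seed=seed)
            coefs.append(cox_univariate(rec, cov["x"]).coef)
        assert abs(np.mean(coefs) - 0.7) < 0.15

    def test_rescaling_equivariance(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"x": rng.normal(0, 1, 200)},
                           index=[f"s{i}" for i in range(200)])
        rec = syndata.simulate_survival(cov, {"x": 0.5}, 0.05, 0.01, seed=5)
        f1 = cox_univariate(rec, cov["x"])
        f2 = cox_univariate(rec, (cov["x"] * 10).rename("x"))
        assert f2.coef == pytest.approx(f1.coef / 10, rel=1e-6)
        assert f1.hr == pytest.approx(np.exp(f1.coef), rel=1e-9)
        assert f1.ci_low < f1.hr < f1.ci_high

    def test_no_variation_rejected(self):
        rec = _records([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError):
            cox_univariate(rec, pd.Series([1.0, 1.0, 1.0], index=rec.index))

    def test_logrank_matches_cox_score_on_binary_covariate(self):
        rng = np.random.default_rng(6)
        n = 500
        cov = pd.DataFrame({"x": rng.integers(0, 2, n).astype(float)},
                           index=[f"s{i}" for i in range(n)])
        rec = syndata.simulate_survival(cov, {"x": 0.5}, 0.05, 0.01, seed=7)
        chi2, _ = logrank_test(rec, cov["x"].map({0.0: "lo", 1.0: "hi"}))
        fit = cox_univariate(rec, cov["x"])
        wald = (fit.coef / ((np.log(fit.ci_high) - np.log(fit.ci_low)) / (2 * 1.96))) ** 2
        assert abs(chi2 - wald) / chi2 < 0.05


class TestScreen:
    def _setup(self, planted=0.0, n=300, seed=0):
        rng = np.random.default_rng(seed)
        fr = pd.DataFrame(
            rng.dirichlet(np.ones(4) * 2, n) * 0.2,
            index=[f"s{i}" for i in range(n)],
            columns=["B", "Treg", "M1", "M2"],
        )
        rec = syndata.simulate_survival(fr, {"Treg": planted}, 0.06, 0.01, seed=seed)
        return fr, rec

    def test_planted_effect_detected(self):
        hits = 0
        for seed in range(10):
            fr, rec = self._setup(planted=25.0, seed=seed)
            tab = screen_immune_cells(fr, rec)
            row = tab[(tab["population"] == "Treg") & (tab["subgroup"] == "all")]
            hits += int(row["p"].iloc[0] < 0.05)
        assert hits >= 8

    def test_null_false_positive_rate_nominal(self):
        flags = []
        for seed in range(10):
            fr, rec = self._setup(planted=0.0, seed=100 + seed)
            tab = screen_immune_cells(fr, rec)
            flags.extend((tab[tab["subgroup"] == "all"]["p"] < 0.05).tolist())
        assert np.mean(flags) < 0.2

    def test_row_bookkeeping_with_subgroups(self):
        fr, rec = self._setup(seed=1)
        sub = pd.Series(
            np.where(np.arange(len(fr)) < 295, "big", "tiny"), index=fr.index
        )
        tab = screen_immune_cells(fr, rec, sub)
        assert len(tab) == 4 * 3  # populations x (all + 2 subgroups)
        assert tab[tab["subgroup"] == "tiny"]["skipped"].all()


class TestBuildDesign:
    def _inputs(self):
        idx = [f"s{i}" for i in range(6)]
        labels = pd.Series(["C1", "C2", "C3", "C1", "C2", "C3"], index=idx)
        fr = pd.DataFrame(
            {"B": np.linspace(0, 0.5, 6), "Treg": np.linspace(0.5, 0, 6)}, index=idx
        )
        return labels, fr

    def test_column_arithmetic(self):
        labels, fr = self._inputs()
        design = build_design(labels, fr)
        assert design.shape[1] == 2 + 2 + 4

    def test_reference_class_rows_all_zero_dummies(self):
        labels, fr = self._inputs()
        design = build_design(labels, fr)
        ref_rows = design.loc[labels.index[labels == "C1"]]
        assert (ref_rows[["class_C2", "class_C3"]] == 0).all().all()

    def test_interactions_are_exact_products(self):
        labels, fr = self._inputs()
        design = build_design(labels, fr)
        for lev in ("C2", "C3"):
            for pop in ("B", "Treg"):
                assert np.array_equal(
                    design[f"class_{lev}:{pop}"].to_numpy(),
                    (design[f"class_{lev}"] * fr[pop]).to_numpy(),
                )

    def test_missing_label_rejected(self):
        labels, fr = self._inputs()
        with pytest.raises(ValueError):
            build_design(labels.iloc[:-1], fr)


def _lasso_setup(seed=0, n=400, n_noise=20, signal=None):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    labels = pd.Series(rng.choice(["C1", "C2", "C3"], n), index=idx)
    signal = signal or {"class_C3": 1.0, "B": 6.0}
    fr = pd.DataFrame(
        {"B": rng.uniform(0, 0.2, n), "Treg": rng.uniform(0, 0.2, n)}, index=idx
    )
    noise = pd.DataFrame(
        rng.uniform(0, 0.2, (n, n_noise)), index=idx,
        columns=[f"noise{i}" for i in range(n_noise)],
    )
    design = build_design(labels, fr.join(noise))
    # drop interaction columns to keep the planted model simple
    design = design[[c for c in design.columns if ":" not in c]]
    eta = sum(coef * design[c] for c, coef in signal.items())
    rec = syndata.simulate_survival(
        pd.DataFrame({"eta": eta}), {"eta": 1.0}, 0.05, 0.005, seed=seed
    )
    forced = ["class_C2", "class_C3"]
    return design, rec, forced


class TestLassoCox:
    def test_all_forced_equals_unpenalized_cox(self):
        design, rec, _ = _lasso_setup()
        design = design[["class_C2", "class_C3", "B"]]
        model = lasso_cox(design, rec, forced=list(design.columns), seed=0)
        from lifelines import CoxPHFitter

        Z = (design - design.mean()) / design.std(ddof=0)
        df = Z.assign(time=rec["time"], event=rec["event"])
        cph = CoxPHFitter().fit(df, "time", "event")
        for c in design.columns:
            assert model.coefficients[c] == pytest.approx(cph.params_[c], abs=1e-4)

    def test_huge_penalty_keeps_only_forced(self):
        design, rec, forced = _lasso_setup(seed=1)
        model = lasso_cox(design, rec, forced, alphas=[1e4], seed=0)
        for c, b in model.coefficients.items():
            if c not in forced:
                assert b == 0.0
        # forced coefficients equal the unpenalized fit on forced columns alone
        sub = lasso_cox(design[forced], rec, forced, seed=0)
        for c in forced:
            assert model.coefficients[c] == pytest.approx(
                sub.coefficients[c], abs=5e-3
            )

    def test_selection_excludes_noise_and_keeps_signal_sign(self):
        design, rec, forced = _lasso_setup(seed=2)
        model = lasso_cox(design, rec, forced, folds=5, seed=0)
        noise_cols = [c for c in design.columns if c.startswith("noise")]
        excluded = sum(model.coefficients[c] == 0 for c in noise_cols)
        assert excluded >= 0.6 * len(noise_cols)
        assert model.coefficients["class_C3"] > 0
        assert model.coefficients["B"] > 0

    def test_same_seed_identical_fit(self):
        design, rec, forced = _lasso_setup(seed=3)
        m1 = lasso_cox(design, rec, forced, seed=5)
        m2 = lasso_cox(design, rec, forced, seed=5)
        assert m1.lambda_ == m2.lambda_ and m1.coefficients == m2.coefficients

    def test_no_events_rejected(self):
        design, rec, forced = _lasso_setup(seed=4)
        rec = rec.copy()
        rec["event"] = 0
        with pytest.raises(ValueError, match="events"):
            lasso_cox(design, rec, forced)


class TestRiskScoring:
    def test_linear_predictor_linearity(self):
        model = RiskModel(
            covariates=["a", "b"],
            coefficients={"a": 2.0, "b": -1.0},
            means={"a": 0.0, "b": 0.0},
            sds={"a": 1.0, "b": 1.0},
            forced=["a"],
            lambda_=0.1,
        )
        design = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 0.0]}, index=["x", "y"])
        lp = linear_predictor(model, design)
        assert lp["x"] == 0.0 and lp["y"] == 2.0
        with pytest.raises(ValueError):
            linear_predictor(model, design[["a"]])

    def test_median_split_balanced_on_training(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(0, 1, 101), index=[f"s{i}" for i in range(101)])
        groups = dichotomize(scores, float(scores.median()))
        counts = groups.value_counts()
        assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1
        # ties at the threshold go to low
        assert groups[scores.idxmin()] == "low"
        tied = dichotomize(pd.Series([1.0, 1.0]), 1.0)
        assert (tied == "low").all()

    def test_frozen_threshold_not_recomputed(self):
        scores = pd.Series(np.arange(10.0), index=[f"v{i}" for i in range(10)]) + 100
        groups = dichotomize(scores, threshold=5.0)
        assert (groups == "high").all()  # shifted cohort: unbalanced, by design

    def test_end_to_end_two_regime_separation(self):
        """Median split of a planted two-risk-regime cohort separates survival."""
        rng = np.random.default_rng(6)
        n = 300
        idx = [f"s{i}" for i in range(n)]
        x = pd.DataFrame({"x": rng.normal(0, 1, n)}, index=idx)
        rec = syndata.simulate_survival(x, {"x": 1.2}, 0.05, 0.01, seed=7)
        model = RiskModel(["x"], {"x": 1.0}, {"x": 0.0}, {"x": 1.0}, [], 0.0)
        lp = linear_predictor(model, x)
        groups = dichotomize(lp, float(lp.median()))
        _, p = logrank_test(rec, groups)
        assert p < 0.01

    def test_model_serialization_round_trip(self, tmp_path):
        design, rec, forced = _lasso_setup(seed=8, n=150, n_noise=4)
        model = lasso_cox(design, rec, forced, seed=0)
        model.thresholds["median"] = 0.33
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RiskModel.from_json(path)
        assert back.thresholds == model.thresholds
        pd.testing.assert_series_equal(
            linear_predictor(model, design), linear_predictor(back, design)
        )


class TestCompositeThreeGroups:
    def _cohort(self, seed=9, n=240):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        lp = pd.Series(rng.normal(0, 1, n), index=idx, name="lp")
        ages = pd.Series(rng.uniform(40, 80, n), index=idx, name="age")
        cov = pd.DataFrame({"lp": lp, "age": ages - 60})
        rec = syndata.simulate_survival(
            cov, {"lp": 0.8, "age": 0.023}, 0.06, 0.01, seed=seed
        )
        return lp, ages, rec

    def test_training_group_sizes_near_quartiles(self):
        lp, ages, rec = self._cohort()
        labels, (q1, q3), coefs = composite_three_groups(lp, ages, rec)
        frac = labels.value_counts(normalize=True)
        assert frac["low"] == pytest.approx(0.25, abs=0.05)
        assert frac["medium"] == pytest.approx(0.50, abs=0.05)
        assert frac["high"] == pytest.approx(0.25, abs=0.05)

    def test_zero_age_coefficient_reduces_to_lp_quartiles(self):
        lp, ages, rec = self._cohort(seed=10)
        labels, _, _ = composite_three_groups(
            lp, ages, rec, coefs={"lp": 1.0, "age": 0.0}
        )
        expect = pd.Series(
            np.select(
                [lp <= lp.quantile(0.25), lp <= lp.quantile(0.75)],
                ["low", "medium"],
                default="high",
            ),
            index=lp.index,
        )
        assert (labels == expect).all()

    def test_three_tiers_ordered_in_survival(self):
        lp, ages, rec = self._cohort(seed=11, n=400)
        labels, _, _ = composite_three_groups(lp, ages, rec)
        medians = {}
        for tier in ("low", "medium", "high"):
            _, medians[tier] = kaplan_meier(rec.loc[labels.index[labels == tier]])
        assert medians["low"] > medians["medium"] > medians["high"]

    def test_frozen_transfer_uses_training_parameters(self):
        lp, ages, rec = self._cohort(seed=12)
        _, thresholds, coefs = composite_three_groups(lp, ages, rec)
        lp2, ages2, rec2 = self._cohort(seed=13)
        labels2, back_thresholds, back_coefs = composite_three_groups(
            lp2, ages2, rec2, thresholds=thresholds, coefs=coefs
        )
        assert back_thresholds == thresholds and back_coefs == coefs
        score2 = composite_score(coefs, lp2, ages2)
        assert (labels2[score2 <= thresholds[0]] == "low").all()
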