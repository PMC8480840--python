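"""Coupling Cox models: design matrices, season covariates, ILR, PH diagnostics."""
import math

import numpy as np
import pandas as pd
import pytest
from _oracles import ilr_basis_oracle

from actcouple.survmodel import (
    DEFAULT_PARTITION,
    CouplingModelSpec,
    bout_spec,
    build_design_matrix,
    close_composition,
    compute_season_covariates,
    fit_coupling_cox,
    fit_ilr_cox,
    ilr_substitution_loghr,
    ilr_transform,
    overall_spec,
    scaled_schoenfeld_residuals,
    schoenfeld_residuals,
)
from actcouple.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_participants=2500, seed=424242)
    return generate_cohort(cfg, include_epochs=False)


class TestSeasonCovariates:
    def test_day_365_wraps_to_unit_cosine(self):
        s = compute_season_covariates(365)
        assert s.c1 == pytest.approx(1.0, abs=1e-12)
        assert s.c2 == pytest.approx(0.0, abs=1e-12)

    def test_quarter_year(self):
        s = compute_season_covariates(91)
        assert s.c1 == pytest.approx(math.cos(2 * math.pi * 91 / 365), abs=1e-15)
        assert s.c2 == pytest.approx(math.sin(2 * math.pi * 91 / 365), abs=1e-15)
        assert abs(s.c1) < 0.02  # ~cos(pi/2)

    @pytest.mark.parametrize("d", [1, 100, 200, 365])
    def test_unit_circle_identity(self, d):
        s = compute_season_covariates(d)
        assert s.c1**2 + s.c2**2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("d", [0, 366, -3])
    def test_out_of_range_rejected(self, d):
        with pytest.raises(ValueError):
            compute_season_covariates(d)


class TestDesignMatrix:
    def test_overall_model_has_three_scaled_activity_columns(self, cohort):
        spec = overall_spec(baseline="sleep")
        X = build_design_matrix(cohort.true_summaries, cohort.covariates, spec)
        acts = [c for c in X.columns if c.startswith("act_")]
        assert sorted(acts) == ["act_light", "act_mvpa", "act_sedentary"]
        pid = cohort.participant_ids[0]
        assert X.loc[pid, "act_mvpa"] == pytest.approx(
            cohort.true_summaries.set_index("participant_id").loc[pid, "mvpa"] / 10.0
        )

    def test_mvpa_bout_model_has_six_activity_columns(self, cohort):
        spec = bout_spec("mvpa", baseline="light")
        X = build_design_matrix(cohort.true_summaries, cohort.covariates, spec)
        acts = [c for c in X.columns if c.startswith("act_")]
        assert len(acts) == 6 and "act_light" not in acts

    def test_covariate_set_toggle(self, cohort):
        full = build_design_matrix(
            cohort.true_summaries, cohort.covariates, overall_spec("sleep")
        )
        reduced = build_design_matrix(
            cohort.true_summaries,
            cohort.covariates,
            overall_spec("sleep", covariate_set="no_bmi_no_illness"),
        )
        dropped = set(full.columns) - set(reduced.columns)
        assert dropped == {"bmi", "prior_cvd", "prior_cancer", "prior_respiratory"}
        assert {"c1", "c2", "townsend", "sex"} <= set(reduced.columns)

    def test_unclosed_components_rejected(self, cohort):
        bad = cohort.true_summaries.copy()
        bad.loc[0, "sleep"] += 1.0
        with pytest.raises(ValueError, match="close"):
            build_design_matrix(bad, cohort.covariates, overall_spec("sleep"))


class TestCouplingFit:
    def test_baseline_switch_identity(self, cohort):
        spec1 = overall_spec(baseline="sleep")
        spec2 = overall_spec(baseline="light")
        f1 = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec1),
            cohort.survival,
            spec1,
        )
        f2 = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec2),
            cohort.survival,
            spec2,
        )
        b1, b2 = f1.coefs, f2.coefs
        assert b2["act_sedentary"] == pytest.approx(
            b1["act_sedentary"] - b1["act_light"], abs=1e-6
        )
        assert b2["act_mvpa"] == pytest.approx(b1["act_mvpa"] - b1["act_light"], abs=1e-6)
        assert b2["act_sleep"] == pytest.approx(-b1["act_light"], abs=1e-6)

    def test_estimates_carry_wald_intervals_and_ph(self, cohort):
        spec = overall_spec(baseline="light")
        fit = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
            cohort.survival,
            spec,
        )
        est = fit.estimates
        assert set(est["comparison"]) == {"sleep", "sedentary", "mvpa"}
        assert ((est["ci_low"] <= est["hr"]) & (est["hr"] <= est["ci_high"])).all()
        assert est["ph_p"].between(0, 1).all()
        assert fit.n_events >= 400

    def test_true_hazard_ratios_inside_wald_intervals(self, cohort):
        # single-cohort sanity check of the simulated truths (0.96, 1.02)
        spec = overall_spec(baseline="light")
        fit = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
            cohort.survival,
            spec,
        )
        est = fit.estimates.set_index("comparison")
        assert est.loc["mvpa", "ci_low"] <= 0.96 <= est.loc["mvpa", "ci_high"]
        assert est.loc["sedentary", "ci_low"] <= 1.02 <= est.loc["sedentary", "ci_high"]

    def test_delayed_entry_counts_monotone_and_risk_sets_respect_delay(self, cohort):
        sizes = []
        for delay in (0, 1, 2):
            spec = overall_spec(baseline="sleep", entry_delay_years=delay)
            fit = fit_coupling_cox(
                build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
                cohort.survival,
                spec,
            )
            sizes.append(fit.n)
            assert (fit.data["exit_age"] > fit.data["entry_age"]).all()
            expected_dropped = int(
                (
                    cohort.survival["exit_age"]
                    <= cohort.survival["entry_age"] + delay
                ).sum()
            )
            assert fit.n_dropped_pre_entry == expected_dropped
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_bout_length_model_recovers_common_stratum_effect(self, cohort):
        # generation gives every sedentary stratum the same true effect
        # (HR 1.02 vs light); each stratum estimate should sit within
        # ~3.3 SE of that common truth
        spec = bout_spec("sedentary", baseline="light")
        fit = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
            cohort.survival,
            spec,
        )
        truth = math.log(1.02)
        strata = fit.estimates[fit.estimates["comparison"].str.startswith("sedentary_bout")]
        assert len(strata) == 3
        for row in strata.itertuples():
            se = (math.log(row.ci_high) - math.log(row.ci_low)) / (2 * 1.959964)
            assert abs(math.log(row.hr) - truth) < 3.3 * se

    def test_zero_events_rejected(self, cohort):
        surv = cohort.survival.copy()
        surv["event"] = False
        spec = overall_spec(baseline="sleep")
        with pytest.raises(ValueError, match="no events"):
            fit_coupling_cox(
                build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
                cohort.survival.assign(event=False),
                spec,
            )


class TestIlr:
    def test_equal_composition_maps_to_zero(self):
        comp = pd.DataFrame(
            {"sleep": [360.0], "sedentary": [360.0], "light": [360.0], "mvpa": [360.0]}
        )
        z = ilr_transform(comp)
        assert np.allclose(z.to_numpy(), 0.0, atol=1e-15)

    def test_permutation_within_one_side_leaves_coordinate_unchanged(self, rng):
        comp = pd.DataFrame(
            rng.uniform(10, 600, (20, 4)), columns=["sleep", "sedentary", "light", "mvpa"]
        )
        swapped = comp.rename(columns={"light": "mvpa", "mvpa": "light"})[comp.columns]
        z1 = ilr_transform(comp)["ilr_2"]
        z2 = ilr_transform(swapped)["ilr_2"]
        assert np.allclose(z1, z2, atol=1e-12)

    def test_matches_basis_matrix_oracle(self, rng):
        parts = ["sleep", "sedentary", "light", "mvpa"]
        comp = pd.DataFrame(rng.uniform(1, 800, (50, 4)), columns=parts)
        B = ilr_basis_oracle(DEFAULT_PARTITION, parts)
        expected = np.log(comp.to_numpy()) @ B.T
        assert np.allclose(ilr_transform(comp).to_numpy(), expected, atol=1e-12)

    def test_zero_replacement_then_closure(self):
        comp = pd.DataFrame(
            {"sleep": [700.0], "sedentary": [600.0], "light": [140.0], "mvpa": [0.0]}
        )
        closed = close_composition(comp)
        assert closed.sum(axis=1).iloc[0] == pytest.approx(1440.0)
        assert closed["mvpa"].iloc[0] > 0
        with pytest.raises(ValueError, match="positive"):
            ilr_transform(comp)

    def test_ilr_fit_consistent_with_per_minute_fit(self):
        # clear, non-null effects so sign agreement is a stable check
        cfg = SimulationConfig(n_participants=2500, seed=909)
        cfg.true_log_hr = {
            "sleep": math.log(1.04),
            "sedentary": math.log(1.08),
            "mvpa": math.log(0.85),
        }
        cohort = generate_cohort(cfg, include_epochs=False)
        spec = overall_spec(baseline="light")
        linear = fit_coupling_cox(
            build_design_matrix(cohort.true_summaries, cohort.covariates, spec),
            cohort.survival,
            spec,
        )
        ilr_fit = fit_ilr_cox(cohort.true_summaries, cohort.covariates, cohort.survival, spec)
        mean_comp = cohort.true_summaries[list(spec.components)].mean().to_dict()
        lin = linear.estimates.set_index("comparison")
        implied, direct = {}, {}
        for comp in ("sleep", "sedentary", "mvpa"):
            implied[comp] = ilr_substitution_loghr(ilr_fit, mean_comp, "light", comp)
            direct[comp] = math.log(lin.loc[comp, "hr"])
            assert np.sign(implied[comp]) == np.sign(direct[comp])
        # same ordering of contrasts (approximate-magnitude agreement)
        assert sorted(implied, key=implied.get) == sorted(direct, key=direct.get)


class TestSchoenfeld:
    def test_matches_lifelines_residuals_without_truncation(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 120
        df = pd.DataFrame(
            {
                "x1": rng.normal(size=n),
                "x2": rng.binomial(1, 0.4, n).astype(float),
            }
        )
        df["exit_age"] = rng.exponential(10, n) * np.exp(-0.3 * df["x1"])
        df["event"] = rng.random(n) < 0.7
        cph = CoxPHFitter().fit(df, duration_col="exit_age", event_col="event")
        times, resid = schoenfeld_residuals(
            df[["x1", "x2"]].to_numpy(),
            np.zeros(n),
            df["exit_age"].to_numpy(),
            df["event"].to_numpy(),
            cph.params_.to_numpy(),
        )
        ll = cph.compute_residuals(df, kind="schoenfeld").sort_index()
        # align lifelines residuals (indexed by row label) to event-time order
        ev = df[df["event"]].sort_values("exit_age")
        ll_aligned = ll.loc[ev.index, ["x1", "x2"]].to_numpy()
        assert np.allclose(resid, ll_aligned, atol=1e-8)

    def test_two_event_residuals_match_hand_formula(self):
        # 3 subjects, events for A (t=2) and B (t=4); C censored at t=5
        X = np.array([[1.0], [0.0], [2.0]])
        entry = np.zeros(3)
        duration = np.array([2.0, 4.0, 5.0])
        event = np.array([True, True, False])
        beta = np.array([0.5])
        times, resid = schoenfeld_residuals(X, entry, duration, event, beta)
        w = np.exp(X[:, 0] * beta[0])
        xbar1 = (1 * w[0] + 0 * w[1] + 2 * w[2]) / (w[0] + w[1] + w[2])
        xbar2 = (0 * w[1] + 2 * w[2]) / (w[1] + w[2])
        assert times.tolist() == [2.0, 4.0]
        assert resid[0, 0] == pytest.approx(1.0 - xbar1, abs=1e-12)
        assert resid[1, 0] == pytest.approx(0.0 - xbar2, abs=1e-12)
        scaled = scaled_schoenfeld_residuals(resid, np.array([[0.25]]), beta)
        assert scaled[0, 0] == pytest.approx(2 * 0.25 * resid[0, 0] + 0.5, abs=1e-12)

    def test_detects_injected_time_varying_effect(self):
        # hazard effect of x reverses at age 70: strong PH violation
        rng = np.random.default_rng(99)
        n = 4000
        x = rng.binomial(1, 0.5, n).astype(float)
        entry = np.full(n, 60.0)
        # piecewise exponential: rate multiplier exp(+0.8x) before 70, exp(-0.8x) after
        t1 = rng.exponential(1 / 0.05, n) / np.exp(0.8 * x)
        age = np.where(60 + t1 < 70, 60 + t1, np.nan)
        t2 = rng.exponential(1 / 0.05, n) / np.exp(-0.8 * x)
        age = np.where(np.isnan(age), 70 + t2, age)
        exit_age = np.minimum(age, 85.0)
        event = age <= 85.0
        df = pd.DataFrame(
            {"x": x, "entry_age": entry, "exit_age": exit_age, "event": event}
        )
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(
            df, duration_col="exit_age", event_col="event", entry_col="entry_age"
        )
        from actcouple.survmodel import CouplingFit, ph_test

        fit = CouplingFit(
            spec=overall_spec("sleep"),
            model=cph,
            data=df,
            estimates=pd.DataFrame(),
            ph=pd.DataFrame(),
            n=n,
            n_events=int(event.sum()),
            n_dropped_pre_entry=0,
        )
        result = ph_test(fit).set_index("covariate")
        assert result.loc["x", "ph_p"] < 1e-4
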