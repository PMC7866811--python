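"""Cox machinery: fitting, screening, selection, interaction model and KM."""

import numpy as np
import pandas as pd
import pytest

from neurotme.errors import DegenerateDesignError, DomainError, HierarchyError
from neurotme.survival import (
    ModelSpec,
    backward_select,
    cox_score_test,
    fit_cox,
    interaction_model,
    km_curves,
    pairwise_interaction_screen,
    univariate_screen,
)
from neurotme.synth import CohortSimConfig, generate_cohort


def two_group_exponential(rng, n, hr, rate0=0.05, p=0.5, censor_max=None):
    """Exponential survival in two arms with hazard ratio `hr`."""
    x = rng.binomial(1, p, n)
    t = rng.exponential(1.0 / (rate0 * hr**x))
    if censor_max is None:
        return pd.DataFrame({"x": x, "time": t, "event": 1})
    c = rng.uniform(0, censor_max, n)
    return pd.DataFrame(
        {"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)}
    )


class TestFitCox:
    def test_matches_exponential_mle_oracle(self):
        """With exponential two-group data the Cox HR tracks the closed-form
        exponential MLE (d1/T1)/(d0/T0)."""
        rng = np.random.default_rng(0)
        df = two_group_exponential(rng, 1000, hr=2.0)
        res = fit_cox(df, ("x",))
        d1, t1 = (df.x == 1).sum(), df.loc[df.x == 1, "time"].sum()
        d0, t0 = (df.x == 0).sum(), df.loc[df.x == 0, "time"].sum()
        mle = (d1 / t1) / (d0 / t0)
        assert res.hr("x") == pytest.approx(mle, rel=0.05)

    def test_null_recovery(self):
        """Mean estimated coefficient near zero under the null."""
        coefs = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            df = two_group_exponential(rng, 1000, hr=1.0, censor_max=30.0)
            coefs.append(fit_cox(df, ("x",)).coef("x"))
        assert abs(np.mean(coefs)) < 0.02

    def test_wald_interval_contains_hr(self):
        rng = np.random.default_rng(1)
        df = two_group_exponential(rng, 300, hr=1.8)
        res = fit_cox(df, ("x",))
        row = res.summary.loc["x"]
        assert row["hr_lower"] < row["hr"] < row["hr_upper"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]))
        assert 0 <= row["p"] <= 1

    def test_duplicated_covariate_rejected(self):
        rng = np.random.default_rng(2)
        df = two_group_exponential(rng, 100, hr=1.5)
        df["x2"] = df["x"]
        with pytest.raises(DegenerateDesignError):
            fit_cox(df, ("x", "x2"))

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(3)
        df = two_group_exponential(rng, 100, hr=1.5)
        df["const"] = 1.0
        with pytest.raises(DegenerateDesignError):
            fit_cox(df, ("x", "const"))

    def test_no_events_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "time": [1, 2, 3, 4],
                           "event": [0, 0, 0, 0]})
        with pytest.raises(DegenerateDesignError):
            fit_cox(df, ("x",))

    def test_binary_hrs_invariant_to_covariate_shift(self):
        cfg = CohortSimConfig(true_log_hr={"nfd_low": 0.5})
        cohort = generate_cohort(cfg, seed=4)
        res1 = fit_cox(cohort, ("age", "gender01", "bmi", "nfd_low"))
        shifted = cohort.copy()
        shifted["age"] = shifted["age"] + 50.0
        res2 = fit_cox(shifted, ("age", "gender01", "bmi", "nfd_low"))
        for term in ("gender01", "nfd_low"):
            assert res2.hr(term) == pytest.approx(res1.hr(term), rel=1e-8)


class TestUnivariateScreen:
    def test_strong_effect_flagged(self):
        """A planted log-HR of 0.9 at n=500 is essentially always relevant."""
        flagged = 0
        cfg = CohortSimConfig(n_patients=500, true_log_hr={"nfd_low": 0.9})
        for seed in range(50):
            cohort = generate_cohort(cfg, seed=seed)
            res = univariate_screen(cohort, ["nfd_low"])
            flagged += "nfd_low" in res.relevant
        assert flagged >= 48

    def test_empty_candidates(self):
        cohort = generate_cohort(CohortSimConfig(), seed=0)
        res = univariate_screen(cohort, [])
        assert res.table.empty and res.relevant == []

    def test_errors_recorded_not_fatal(self):
        cohort = generate_cohort(CohortSimConfig(), seed=1)
        cohort["broken"] = 1.0  # constant
        res = univariate_screen(cohort, ["broken", "nfd_low"])
        assert "broken" in res.errors
        assert set(res.table["candidate"]) == {"nfd_low"}


class TestBackwardSelect:
    def test_strong_kept_null_dropped(self):
        kept_strong, kept_null = 0, 0
        cfg = CohortSimConfig(n_patients=500, true_log_hr={"nfd_low": 1.0})
        for seed in range(30):
            cohort = generate_cohort(cfg, seed=seed)
            sel = backward_select(cohort, ModelSpec(("nfd_low", "la_ge5")))
            kept_strong += "nfd_low" in sel.final.terms
            kept_null += "la_ge5" in sel.final.terms
        assert kept_strong >= 27
        assert kept_null <= 10

    def test_adjusters_never_removed(self):
        cohort = generate_cohort(CohortSimConfig(), seed=5)
        sel = backward_select(cohort, ModelSpec(("nfd_low", "la_ge5", "tc")))
        for term in ("age", "gender01", "bmi"):
            assert term in sel.final.terms

    def test_hierarchy_spec_enforced(self):
        with pytest.raises(HierarchyError):
            ModelSpec(("nfd_low", "nfd_low:la_ge5"))

    def test_main_effect_protected_while_interaction_remains(self):
        """A planted pure interaction keeps its main effects in the model."""
        cfg = CohortSimConfig(
            n_patients=800, true_log_hr={"la_ge5:nfd_high": -1.2}
        )
        cohort = generate_cohort(cfg, seed=6)
        sel = backward_select(
            cohort, ModelSpec(("la_ge5", "nfd_high", "la_ge5:nfd_high"))
        )
        if "la_ge5:nfd_high" in sel.final.terms:
            assert {"la_ge5", "nfd_high"} <= set(sel.final.terms)


class TestInteractionScreen:
    def test_planted_interaction_found(self):
        cfg = CohortSimConfig(
            n_patients=1000,
            true_log_hr={"la_ge5:nfd_high": -1.5},
        )
        cohort = generate_cohort(cfg, seed=7)
        found = pairwise_interaction_screen(cohort, ["la_ge5", "nfd_high", "tc"])
        assert "la_ge5:nfd_high" in found


class TestInteractionModel:
    def test_null_interaction_rarely_significant(self):
        hits = 0
        n_reps = 40
        cfg = CohortSimConfig(n_patients=300)
        for seed in range(n_reps):
            cohort = generate_cohort(cfg, seed=seed)
            res = interaction_model(cohort)
            hits += res.la_nfd_p < 0.05
        assert hits <= 0.05 * n_reps + 3 * np.sqrt(n_reps * 0.05 * 0.95)

    def test_planted_subgroup_hazard_ratios_recovered(self):
        """Subgroup HRs of high- vs low-NFD recover the planted values
        (protective only where aggregate burden is high)."""
        hr_ge5, hr_lt5 = 0.388, 0.959
        cfg = CohortSimConfig(
            n_patients=800,
            true_log_hr={
                "nfd_high": float(np.log(hr_lt5)),
                "la_ge5:nfd_high": float(np.log(hr_ge5 / hr_lt5)),
            },
        )
        logs_ge5, logs_lt5 = [], []
        for seed in range(60):
            cohort = generate_cohort(cfg, seed=seed)
            res = interaction_model(cohort)
            sub = res.subgroups.set_index("stratum")
            logs_ge5.append(np.log(sub.loc["la_ge5", "hr"]))
            logs_lt5.append(np.log(sub.loc["la_lt5", "hr"]))
        assert np.exp(np.mean(logs_ge5)) == pytest.approx(hr_ge5, rel=0.10)
        assert np.exp(np.mean(logs_lt5)) == pytest.approx(hr_lt5, rel=0.10)

    def test_constant_tc_rejected(self):
        cohort = generate_cohort(CohortSimConfig(), seed=8)
        cohort["tc"] = 0.5
        with pytest.raises(DegenerateDesignError):
            interaction_model(cohort)


class TestKaplanMeier:
    def test_single_group_steps_one_over_n(self):
        n = 8
        df = pd.DataFrame({"g": 0, "time": np.arange(1.0, n + 1), "event": 1})
        res = km_curves(df, "g")
        surv = res.curves[0]["survival"].to_numpy()
        expected = 1 - np.arange(0, n + 1) / n  # includes t=0 row
        np.testing.assert_allclose(surv, expected, atol=1e-12)

    def test_identical_groups_zero_statistic(self):
        rng = np.random.default_rng(9)
        half = pd.DataFrame({"time": rng.exponential(10, 50), "event": 1})
        df = pd.concat([half.assign(g=0), half.assign(g=1)], ignore_index=True)
        res = km_curves(df, "g")
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-9)

    def test_rate_ratio_two_detected(self):
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            df = two_group_exponential(rng, 500, hr=2.0).rename(columns={"x": "g"})
            assert km_curves(df, "g").logrank_p < 0.001

    def test_empty_table_rejected(self):
        with pytest.raises(DomainError):
            km_curves(pd.DataFrame({"g": [], "time": [], "event": []}), "g")

    def test_plot_written(self, tmp_path):
        rng = np.random.default_rng(10)
        df = two_group_exponential(rng, 80, hr=1.5).rename(columns={"x": "g"})
        res = km_curves(df, "g")
        path = tmp_path / "km.png"
        res.plot(path)
        assert path.stat().st_size > 0


class TestScoreTest:
    @pytest.mark.parametrize("seed", range(5))
    def test_logrank_agrees_with_cox_score_test(self, seed):
        """On tie-free data the log-rank test is the Cox score test."""
        rng = np.random.default_rng(300 + seed)
        df = two_group_exponential(rng, 200, hr=1.4, censor_max=40.0)
        df = df.rename(columns={"x": "g"})
        assert df["time"].nunique() == len(df)  # no ties
        km = km_curves(df, "g")
        chi2, p = cox_score_test(df, "g")
        assert chi2 == pytest.approx(km.logrank_stat, abs=5e-4)
        assert p == pytest.approx(km.logrank_p, abs=5e-4)
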