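"""Growth rates, covariate screening, linear models and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from aortiq import cohort_stats as CS
from aortiq.errors import CohortError
from aortiq.phantoms import CohortSpec, make_cohort


@pytest.fixture(scope="module")
def cohort():
    return make_cohort(CohortSpec(n_patients=300, seed=42))


class TestGrowthRates:
    def test_simple_rate_arithmetic(self):
        t = pd.DataFrame(
            {
                "interval_years": [10.0],
                "baseline_diameter_S1_mm": [40.0],
                "followup_diameter_S1_mm": [44.0],
            }
        )
        rates = CS.compute_growth_rates(t, segments=("S1",))
        assert rates["diameter_growth_S1_mm_per_year"].iloc[0] == pytest.approx(0.40)

    def test_missing_followup_yields_missing_rate(self):
        t = pd.DataFrame(
            {
                "interval_years": [10.0, 8.0],
                "baseline_diameter_S1_mm": [40.0, 42.0],
                "followup_diameter_S1_mm": [44.0, np.nan],
            }
        )
        rates = CS.compute_growth_rates(t, segments=("S1",))
        assert np.isnan(rates["diameter_growth_S1_mm_per_year"].iloc[1])

    def test_zero_interval_rejected(self):
        t = pd.DataFrame(
            {
                "interval_years": [0.0],
                "baseline_diameter_S1_mm": [40.0],
                "followup_diameter_S1_mm": [44.0],
            }
        )
        with pytest.raises(CohortError, match="interval"):
            CS.compute_growth_rates(t, segments=("S1",))

    def test_phantom_rates_recovered(self, cohort):
        rates = CS.compute_growth_rates(cohort)
        assert np.allclose(
            rates["length_growth_S1_mm_per_year"],
            cohort["length_growth_S1_mm_per_year"],
        )


class TestScreenCovariates:
    def test_inclusion_rule_is_p_below_threshold_or_forced(self, cohort):
        screen = CS.screen_covariates(
            cohort,
            "diameter_growth_S1_mm_per_year",
            ["curvature_radius_mm", "flow_displacement", "map_mmHg", "bsa_m2", "smoking"],
        )
        tab = screen.table
        expected = (tab["p_value"] < 0.20) | tab["forced"]
        assert (tab["included"] == expected.fillna(False)).all()
        assert tab.loc["curvature_radius_mm", "included"]  # true strong effect

    def test_forced_age_sex_included_even_when_unassociated(self, cohort):
        screen = CS.screen_covariates(
            cohort, "diameter_growth_S1_mm_per_year", ["map_mmHg"]
        )
        for forced in ("age_years", "sex_male"):
            assert screen.table.loc[forced, "forced"]
            assert screen.table.loc[forced, "included"]
        # in this synthetic world age/sex have no effect, so their p is typically large
        assert screen.table.loc["age_years", "p_value"] > 0.0

    def test_constant_candidate_excluded_with_warning(self, cohort, caplog):
        t = cohort.copy()
        t["constant_flag"] = 1.0
        with caplog.at_level("WARNING"):
            screen = CS.screen_covariates(
                t, "diameter_growth_S1_mm_per_year", ["constant_flag"]
            )
        assert not screen.table.loc["constant_flag", "included"]
        assert "constant" in caplog.text

    def test_too_few_outcomes_rejected(self):
        t = make_cohort(CohortSpec(n_patients=5, seed=0))
        with pytest.raises(CohortError, match="present for only"):
            CS.screen_covariates(t, "diameter_growth_S1_mm_per_year", ["map_mmHg"])


class TestFitLinearModel:
    def test_noiseless_beta_recovered_exactly(self):
        spec = CohortSpec(
            n_patients=100,
            coefficient_map={
                "diameter_growth_S1_mm_per_year": {
                    "intercept": 1.2,
                    "curvature_radius_mm": -0.018,
                }
            },
            noise_sd=0.0,
            seed=7,
        )
        t = make_cohort(spec)
        fit = CS.fit_linear_model(
            t, "diameter_growth_S1_mm_per_year", ["curvature_radius_mm"]
        )
        assert fit.beta["curvature_radius_mm"] == pytest.approx(-0.018, rel=1e-9)
        assert fit.se["curvature_radius_mm"] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_cases_rejected(self):
        t = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0],
                "a": [1.0, 2.0, 4.0],
                "b": [0.0, 1.0, 0.0],
                "c": [2.0, 1.0, 0.5],
                "d": [1.0, 1.5, 2.5],
            }
        )
        with pytest.raises(CohortError, match="complete cases"):
            CS.fit_linear_model(t, "y", ["a", "b", "c", "d"])

    def test_rank_deficiency_names_collinear_predictors(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({"a": rng.normal(size=50)})
        t["b"] = 2.0 * t["a"]
        t["y"] = t["a"] + rng.normal(size=50)
        with pytest.raises(CohortError, match="collinear") as exc:
            CS.fit_linear_model(t, "y", ["a", "b"])
        assert "a" in str(exc.value) and "b" in str(exc.value)

    def test_complete_case_determinism(self, cohort):
        """Injecting missingness never changes estimates on the remaining rows."""
        outcome = "length_growth_S1_mm_per_year"
        preds = ["flow_displacement", "age_years"]
        damaged = cohort.copy()
        dropped = damaged.index[::7]
        damaged.loc[dropped, "flow_displacement"] = np.nan
        fit_damaged = CS.fit_linear_model(damaged, outcome, preds)
        fit_manual = CS.fit_linear_model(cohort.drop(index=dropped), outcome, preds)
        assert np.allclose(fit_damaged.beta, fit_manual.beta)
        assert fit_damaged.n_used == fit_manual.n_used


class TestCompareGroups:
    def test_identical_groups_give_near_zero_t(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(10.0, 2.0, size=50)
        t = pd.DataFrame({"group": ["A"] * 50 + ["B"] * 50, "x": np.r_[vals, vals]})
        res = CS.compare_groups(t, "x")
        assert res.t_statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_one_sd_shift_power(self):
        """A 1 SD mean shift at n = 30/30 is detected (p < 0.05) in >= 80% of runs."""
        hits = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            t = pd.DataFrame(
                {
                    "group": ["A"] * 30 + ["B"] * 30,
                    "x": np.r_[rng.normal(0, 1, 30), rng.normal(1.0, 1, 30)],
                }
            )
            hits += CS.compare_groups(t, "x").p_value < 0.05
        assert hits / n_runs >= 0.80

    def test_age_adjustment_reports_group_coefficient(self, cohort):
        res = CS.compare_groups(
            cohort, "baseline_diameter_S1_mm", age_adjust=True
        )
        assert res.age_adjusted_beta is not None
        assert 0.0 <= res.age_adjusted_p <= 1.0

    def test_degenerate_groups_rejected(self):
        t = pd.DataFrame({"group": ["A"] * 5, "x": np.arange(5.0)})
        with pytest.raises(CohortError, match="2 groups"):
            CS.compare_groups(t, "x")
        t2 = pd.DataFrame({"group": ["A"] * 5 + ["B"], "x": np.arange(6.0)})
        with pytest.raises(CohortError, match="at least 2 members"):
            CS.compare_groups(t2, "x")


class TestScreeningMonotonicity:
    def test_stronger_effect_never_less_included(self):
        """Raising a covariate's true effect does not reduce its inclusion frequency."""
        freqs = []
        for beta in (0.0, 0.5, 2.0):
            included = 0
            for seed in range(30):
                rng = np.random.default_rng(1000 + seed)  # fixed noise per seed family
                x = rng.normal(0, 1, 60)
                noise = rng.normal(0, 1, 60)
                t = pd.DataFrame(
                    {
                        "x": x,
                        "age_years": rng.normal(50, 10, 60),
                        "sex_male": rng.integers(0, 2, 60).astype(float),
                        "y": beta * x + noise,
                    }
                )
                screen = CS.screen_covariates(t, "y", ["x"])
                included += screen.table.loc["x", "included"]
            freqs.append(included / 30)
        assert freqs[0] <= freqs[1] + 1e-12 <= freqs[2] + 2e-12
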