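"""Reference-level rule, inequality regressions, adjusted exposure model."""

import copy

import numpy as np
import pytest

from ineqshift.cohort import LEVELS, PREDICTORS
from ineqshift.generator import default_params, generate_cohort
from ineqshift.inequality import (
    choose_reference,
    choose_references,
    estimate_inequality,
    fit_adjusted_exposure_model,
)

from conftest import make_toy_table


class TestChooseReference:
    def test_unique_minimum(self):
        t = make_toy_table(
            "education",
            ["high"] * 3 + ["medium"] * 3 + ["low"] * 3,
            [1] * 9,
            [10.0, 10.0, 10.0, 12.0, 12.0, 12.0, 12.0, 12.0, 12.0],
        )
        assert choose_reference(t, "education") == "high"

    def test_tie_breaks_by_dictionary_order(self):
        t = make_toy_table("employment", ["yes", "yes", "no", "no"], [1] * 4,
                           [11.0, 11.0, 11.0, 11.0])
        assert choose_reference(t, "employment") == "yes"

    def test_empty_level_excluded_with_warning(self):
        t = make_toy_table("education", ["high"] * 4 + ["low"] * 4, [1] * 8,
                           [12.0] * 4 + [10.0] * 4)
        with pytest.warns(UserWarning, match="medium"):
            assert choose_reference(t, "education") == "low"

    def test_idempotent_on_generated_cohort(self, cohort_complete):
        first = choose_references(cohort_complete)
        second = choose_references(cohort_complete)
        assert first == second

    def test_default_cohort_reference_levels_follow_coefficient_ordering(
        self, cohort_complete
    ):
        refs = choose_references(cohort_complete)
        assert refs["age_group"] == "30-35"
        assert refs["education"] == "high"
        assert refs["income"] == "high"
        assert refs["housing"] == "own"


class TestEstimateInequality:
    def test_contrast_equals_group_mean_difference_exactly(self):
        rng = np.random.default_rng(0)
        groups = rng.choice(["own", "rented"], size=200)
        y = rng.normal(12.0, 2.0, size=200) + (groups == "rented") * 1.5
        t = make_toy_table("housing", groups, np.ones(200), y)
        fit = estimate_inequality(t, "housing", "own")
        diff = y[groups == "rented"].mean() - y[groups == "own"].mean()
        assert fit.get("housing[rented]") == pytest.approx(diff, abs=1e-10)

    def test_null_inequality_when_means_equal(self):
        t = make_toy_table("deprivation", ["low", "medium", "high"] * 4, [1] * 12,
                           [12.0] * 12)
        fit = estimate_inequality(t, "deprivation", "low")
        assert fit.get("deprivation[medium]") == pytest.approx(0.0, abs=1e-12)
        assert fit.get("deprivation[high]") == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_coefficient_without_confounding(self):
        p = default_params(n=30000)
        for var in p.exposure_coefs:
            p.exposure_coefs[var] = {lv: 0.0 for lv in LEVELS[var]}
        p.exposure_effect = 0.0
        t = generate_cohort(p, seed=60)
        fit = estimate_inequality(t, "education", "high")
        se = fit.se("education[low]")
        assert abs(fit.get("education[low]") - 1.5) <= 3 * se

    def test_coverage_of_generating_coefficients(self):
        # complete synthetic data: the generating contrast lies inside its
        # 95% CI in about 95% of replications
        p = default_params(n=2000)
        for var in p.exposure_coefs:
            p.exposure_coefs[var] = {lv: 0.0 for lv in LEVELS[var]}
        p.exposure_effect = 0.0
        hits = reps = 0
        for s in range(100):
            t = generate_cohort(p, seed=700 + s)
            fit = estimate_inequality(t, "employment", "yes")
            est, se = fit.get("employment[no]"), fit.se("employment[no]")
            hits += abs(est - 1.6) <= 1.96 * se
            reps += 1
        assert 0.89 <= hits / reps <= 0.99


class TestAdjustedExposureModel:
    def test_recovers_exposure_effect_under_confounding(self):
        p = default_params(n=50000)
        t = generate_cohort(p, seed=61)
        fit = fit_adjusted_exposure_model(t)
        se = fit.se("early_recognition")
        assert abs(fit.exposure_effect - (-0.6)) <= 3 * se

    def test_null_exposure_effect(self):
        p = default_params(n=20000)
        p.exposure_effect = 0.0
        sys_mean_shift = 0.6 * 0.817  # removing the effect shifts the mean; harmless
        t = generate_cohort(p, seed=62)
        fit = fit_adjusted_exposure_model(t)
        assert abs(fit.exposure_effect) <= 3 * fit.se("early_recognition")

    def test_adjusted_equals_unadjusted_without_confounding(self):
        p = default_params(n=30000)
        for var in p.exposure_coefs:
            p.exposure_coefs[var] = {lv: 0.0 for lv in LEVELS[var]}
        t = generate_cohort(p, seed=63)
        adj = fit_adjusted_exposure_model(t)
        # unadjusted: OLS of outcome on the exposure alone = mean difference
        y, a = t["init_weeks"], t["early_recognition"]
        unadj = y[a == 1].mean() - y[a == 0].mean()
        assert abs(adj.exposure_effect - unadj) <= 3 * adj.se("early_recognition")

    def test_adjusted_estimate_differs_from_confounded_contrast(self, cohort_complete):
        # with confounding on, the crude contrast is more negative than -0.6
        y, a = cohort_complete["init_weeks"], cohort_complete["early_recognition"]
        crude = y[a == 1].mean() - y[a == 0].mean()
        fit = fit_adjusted_exposure_model(cohort_complete)
        assert crude < fit.exposure_effect < 0
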