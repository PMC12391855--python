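"""G-computation: counterfactual shift, reductions, standardisation oracle."""

import numpy as np
import pandas as pd
import pytest

from ineqshift.cohort import PREDICTORS
from ineqshift.inequality import (
    ModelFit,
    choose_references,
    fit_adjusted_exposure_model,
    fit_interaction_exposure_model,
)
from ineqshift.intervention import (
    PositivityViolationError,
    counterfactual_outcomes,
    estimate_reduction,
    reduction_closed_form,
    standardization_oracle,
)

from conftest import make_toy_table


def _shift_fit(beta_a: float) -> ModelFit:
    return ModelFit(terms=["intercept", "early_recognition"],
                    coefs=np.array([0.0, beta_a]),
                    vcov=np.eye(2), n=0, sigma2=1.0)


class TestCounterfactualOutcomes:
    def test_shift_arithmetic_and_consistency(self):
        t = make_toy_table("housing", ["own", "rented"], [0, 1], [14.0, 11.0])
        y_star = counterfactual_outcomes(t, _shift_fit(-0.6))
        assert y_star[0] == pytest.approx(13.4)  # unexposed row shifted
        assert y_star[1] == pytest.approx(11.0)  # exposed row untouched

    def test_null_effect_identity(self, small_cohort):
        y_star = counterfactual_outcomes(small_cohort, _shift_fit(0.0))
        assert np.array_equal(y_star, small_cohort["init_weeks"].to_numpy())

    def test_consistency_for_all_exposed_rows(self, small_cohort):
        fit = fit_adjusted_exposure_model(small_cohort)
        y_star = counterfactual_outcomes(small_cohort, fit)
        exposed = small_cohort["early_recognition"] == 1.0
        assert np.array_equal(y_star[exposed], small_cohort.loc[exposed, "init_weeks"])

    def test_predict_mode_consistency(self, small_cohort):
        fit = fit_adjusted_exposure_model(small_cohort)
        y_star = counterfactual_outcomes(small_cohort, fit, mode="predict")
        exposed = small_cohort["early_recognition"].to_numpy() == 1.0
        assert np.allclose(y_star[exposed], small_cohort.loc[exposed, "init_weeks"],
                           atol=1e-8)


class TestEstimateReduction:
    def test_closed_form_identity_every_predictor(self, small_cohort):
        fit = fit_adjusted_exposure_model(small_cohort)
        refs = choose_references(small_cohort)
        for pred in PREDICTORS:
            rows = estimate_reduction(small_cohort, pred, fit, reference=refs[pred])
            cf = reduction_closed_form(small_cohort, pred, fit, reference=refs[pred])
            got = rows.set_index("level")["reduction"].dropna()
            assert np.allclose(got, cf[got.index], atol=1e-10), pred

    def test_hand_computed_prevalence_gap(self):
        # beta_A = -1, exposure prevalence 0.9 in reference vs 0.5 in the
        # contrast level -> reduction = -1 * (0.9 - 0.5) = -0.4
        n_ref, n_lvl = 10, 10
        groups = ["own"] * n_ref + ["rented"] * n_lvl
        a = [1] * 9 + [0] + [1] * 5 + [0] * 5
        y = list(np.linspace(10, 12, n_ref)) + list(np.linspace(12, 15, n_lvl))
        t = make_toy_table("housing", groups, a, y)
        rows = estimate_reduction(t, "housing", _shift_fit(-1.0), reference="own")
        red = rows.set_index("level").loc["rented", "reduction"]
        assert red == pytest.approx(-0.4, abs=1e-10)

    def test_equal_prevalence_zero_reduction(self):
        groups = ["own"] * 6 + ["rented"] * 6
        a = [1, 1, 1, 0, 0, 0] * 2
        y = [10, 11, 12, 13, 14, 15, 12, 13, 14, 15, 16, 17]
        t = make_toy_table("housing", groups, a, y)
        rows = estimate_reduction(t, "housing", _shift_fit(-2.0), reference="own")
        assert rows.set_index("level").loc["rented", "reduction"] == pytest.approx(0.0, abs=1e-12)

    def test_null_effect_zero_reduction_everywhere(self, small_cohort):
        refs = choose_references(small_cohort)
        for pred in PREDICTORS[:4]:
            rows = estimate_reduction(small_cohort, pred, _shift_fit(0.0),
                                      reference=refs[pred])
            assert np.allclose(rows["reduction"].dropna(), 0.0, atol=1e-12)

    def test_direction_when_disadvantaged_group_has_lower_exposure(self, cohort_complete):
        # education: low level has lower early-recognition prevalence by
        # construction, and beta_A < 0, so its inequality must shrink
        fit = fit_adjusted_exposure_model(cohort_complete)
        rows = estimate_reduction(cohort_complete, "education", fit, reference="high")
        assert rows.set_index("level").loc["low", "reduction"] < 0


class TestStandardizationOracle:
    def test_two_stratum_hand_calculation(self):
        # stratum own: A=1 mean 10; stratum rented: A=1 mean 12
        groups = ["own"] * 4 + ["rented"] * 4
        a = [1, 1, 0, 0, 1, 1, 0, 0]
        y = [9.0, 11.0, 13.0, 15.0, 11.0, 13.0, 15.0, 17.0]
        t = make_toy_table("housing", groups, a, y)
        rows = standardization_oracle(t, "housing").set_index("level")
        # observed means: own 12, rented 14 -> without = 2.0
        # substituted: own (9+11+10+10)/4 = 10, rented (11+13+12+12)/4 = 12
        assert rows.loc["rented", "beta_without"] == pytest.approx(2.0, abs=1e-12)
        assert rows.loc["rented", "beta_with"] == pytest.approx(2.0, abs=1e-12)
        assert rows.loc["rented", "reduction"] == pytest.approx(0.0, abs=1e-12)

    def test_all_exposed_is_identity(self):
        groups = ["own"] * 3 + ["rented"] * 3
        t = make_toy_table("housing", groups, [1] * 6, [10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
        rows = standardization_oracle(t, "housing").set_index("level")
        assert rows.loc["rented", "beta_with"] == rows.loc["rented", "beta_without"]

    def test_positivity_violation_raises(self):
        groups = ["own"] * 4 + ["rented"] * 4
        a = [1, 1, 0, 0, 0, 0, 0, 0]  # no exposed rows among renters
        t = make_toy_table("housing", groups, a, [10.0] * 8)
        with pytest.raises(PositivityViolationError, match="rented"):
            standardization_oracle(t, "housing")

    @pytest.mark.parametrize("seed", range(25))
    def test_saturated_equivalence_on_random_tables(self, seed):
        # one binary covariate, saturated exposure model: prediction-based
        # g-computation must agree with exhaustive standardisation to 1e-10
        rng = np.random.default_rng(seed)
        n = int(rng.integers(40, 200))
        while True:
            groups = rng.choice(["yes", "no"], size=n)
            a = (rng.random(n) < 0.6).astype(float)
            ok = all(((groups == g) & (a == v)).any()
                     for g in ("yes", "no") for v in (0.0, 1.0))
            if ok:
                break
        y = rng.normal(12, 3, size=n) + 2.0 * (groups == "no") - 1.0 * a
        t = make_toy_table("employment", groups, a, y)
        fit = fit_interaction_exposure_model(t, ["employment"])
        gcomp = estimate_reduction(t, "employment", fit, mode="predict")
        oracle = standardization_oracle(t, "employment")
        for col in ("beta_without", "beta_with", "reduction"):
            assert np.allclose(gcomp[col].dropna(), oracle[col].dropna(), atol=1e-10)
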