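"""Chained-equation imputation and Rubin pooling."""

import numpy as np
import pytest
from scipy import stats

from ineqshift.generator import apply_missingness, default_params, generate_cohort
from ineqshift.imputation import (
    ImputationError,
    impute_chained,
    pool_rubin,
)


@pytest.fixture(scope="module")
def imputed_small():
    """n=1500 cohort under default missingness, m=3 short chains."""
    p = default_params(n=1500)
    complete = generate_cohort(p, seed=50)
    observed = apply_missingness(complete, p, seed=51)
    sets = impute_chained(observed, m=3, iterations=3, seed=52)
    return complete, observed, sets


class TestImputeChained:
    def test_no_missing_gives_identical_copies(self, small_cohort):
        sets = impute_chained(small_cohort, m=3, iterations=2, seed=1)
        assert sets.m == 3
        assert all(t.equals(small_cohort) for t in sets.tables)

    def test_completes_all_cells_and_preserves_observed(self, imputed_small):
        complete, observed, sets = imputed_small
        check_cols = [c for c in observed.columns if c != "participant_id"]
        for t in sets.tables:
            assert not t[check_cols].isna().any().any()
        for var in sets.visit_order:
            mask = observed[var].notna()
            for t in sets.tables:
                if observed[var].dtype.kind == "f":
                    assert np.allclose(t.loc[mask, var], observed.loc[mask, var])
                else:
                    assert (t.loc[mask, var] == observed.loc[mask, var]).all()

    def test_pmm_values_come_from_observed_donors(self, imputed_small):
        _, observed, sets = imputed_small
        donors = set(observed["recognition_weeks"].dropna())
        mask = observed["recognition_weeks"].isna()
        for t in sets.tables:
            assert all(v in donors for v in t.loc[mask, "recognition_weeks"])
        lo, hi = observed["recognition_weeks"].min(), observed["recognition_weeks"].max()
        for t in sets.tables:
            assert t["recognition_weeks"].between(lo, hi).all()

    def test_passive_exposure_definition_holds(self, imputed_small):
        _, _, sets = imputed_small
        for t in sets.tables:
            assert ((t["recognition_weeks"] <= 6.0).astype(float)
                    == t["early_recognition"]).all()

    def test_visit_order_ascending_missing_fraction(self, imputed_small):
        _, observed, sets = imputed_small
        fracs = [observed[v].isna().mean() for v in sets.visit_order]
        assert fracs == sorted(fracs)

    def test_determinism_and_chain_independence(self, imputed_small):
        _, observed, sets = imputed_small
        again = impute_chained(observed, m=3, iterations=3, seed=52)
        assert all(a.equals(b) for a, b in zip(sets.tables, again.tables))
        assert not sets.tables[0].equals(sets.tables[1])

    def test_fully_missing_variable_is_rejected(self, small_cohort):
        bad = small_cohort.copy()
        bad["iq"] = np.nan
        with pytest.raises(ImputationError, match="iq"):
            impute_chained(bad, m=2, iterations=1, seed=0)

    def test_m_below_two_rejected(self, small_cohort):
        with pytest.raises(ImputationError):
            impute_chained(small_cohort, m=1, iterations=1, seed=0)

    def test_pooled_prevalence_tracks_complete_data(self, imputed_small):
        complete, _, sets = imputed_small
        truth = complete["early_recognition"].mean()
        prev = [t["early_recognition"].mean() for t in sets.tables]
        var = [pv * (1 - pv) / len(complete) for pv in prev]
        pooled = pool_rubin(prev, var)
        assert abs(pooled.estimate - truth) <= 3 * np.sqrt(pooled.total_var)


class TestPoolRubin:
    def test_zero_between_variance(self):
        pooled = pool_rubin([1.0, 1.0, 1.0], [4.0, 4.0, 4.0])
        assert pooled.estimate == 1.0
        assert pooled.within_var == 4.0
        assert pooled.between_var == 0.0
        assert pooled.total_var == 4.0

    def test_two_point_algebra(self):
        pooled = pool_rubin([0.0, 2.0], [1.0, 1.0])
        assert pooled.estimate == 1.0
        assert pooled.between_var == pytest.approx(2.0)
        assert pooled.total_var == pytest.approx(1.0 + 1.5 * 2.0)
        assert pooled.ci[0] <= pooled.estimate <= pooled.ci[1]

    def test_total_variance_invariant(self):
        rng = np.random.default_rng(3)
        q = rng.normal(size=20)
        u = rng.uniform(0.5, 2.0, size=20)
        pooled = pool_rubin(q, u)
        m = len(q)
        assert pooled.total_var == pytest.approx(
            pooled.within_var + (1 + 1 / m) * pooled.between_var, abs=1e-12
        )

    def test_single_imputation_rejected(self):
        with pytest.raises(ImputationError):
            pool_rubin([1.0], [1.0])

    def test_interval_coverage_for_known_mean(self):
        # Rubin-consistent Monte Carlo: the observed-data estimator has
        # variance W + B (complete-data part W=1 plus missing-information
        # part B=1); each of m=50 imputations adds N(0, B) noise.  The pooled
        # t-interval with claimed within-variance 1 should cover mu ~95%.
        rng = np.random.default_rng(8)
        mu, reps, hits = 5.0, 200, 0
        for _ in range(reps):
            theta_obs = rng.normal(mu, np.sqrt(2.0))
            est = theta_obs + rng.normal(0.0, 1.0, size=50)
            pooled = pool_rubin(est, np.ones(50))
            hits += pooled.ci[0] <= mu <= pooled.ci[1]
        assert 0.91 <= hits / reps <= 0.99
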