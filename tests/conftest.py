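"""Shared fixtures: calibrated parameter sets, generated cohorts, toy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ineqshift.cohort import COLUMNS, LEVELS, PREDICTORS
from ineqshift.generator import apply_missingness, default_params, generate_cohort


@pytest.fixture(scope="session")
def params_default():
    return default_params(n=4196)


@pytest.fixture(scope="session")
def cohort_complete(params_default):
    """One complete cohort at the reference sample size."""
    return generate_cohort(params_default, seed=42)


@pytest.fixture(scope="session")
def cohort_observed(params_default):
    """The same cohort after the default missingness mechanism."""
    complete = generate_cohort(params_default, seed=42)
    return apply_missingness(complete, params_default, seed=43)


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete cohort for fast model-fitting tests."""
    return generate_cohort(default_params(n=900), seed=7)


def make_toy_table(predictor: str, levels, exposure, outcome, **extra) -> pd.DataFrame:
    """Minimal valid cohort table with one predictor varied and the rest
    pinned to their first dictionary level."""
    n = len(outcome)
    data: dict[str, object] = {"participant_id": [f"T{i:04d}" for i in range(n)]}
    for p in PREDICTORS:
        data[p] = np.array(levels, dtype=object) if p == predictor else np.array(
            [LEVELS[p][0]] * n, dtype=object)
    a = np.asarray(exposure, dtype=float)
    data["early_recognition"] = a
    data["recognition_weeks"] = np.where(a == 1.0, 4.0, 10.0)
    data["init_weeks"] = np.asarray(outcome, dtype=float)
    data["regular_cycle"] = np.ones(n)
    data["bmi_intake"] = np.full(n, 24.0)
    data["ga_intake"] = np.asarray(outcome, dtype=float) + 1.5
    data["apgar5"] = np.full(n, 9.0)
    data.update(extra)
    return pd.DataFrame(data, columns=COLUMNS)
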