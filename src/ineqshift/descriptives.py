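"""Descriptive tables and causal-assumption diagnostics.

Covers the cohort characteristics table (counts and column percentages over
the total sample and the timely / late initiation strata), the two
dichotomisations (early recognition at <= 6 weeks, timely initiation at
<= 14 weeks; both boundaries inclusive), the positivity diagnostic via
propensity scores, and the regular-menstrual-cycle sensitivity subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import (
    EARLY_RECOGNITION_WEEKS,
    LEVELS,
    PREDICTORS,
    TIMELY_INITIATION_WEEKS,
    percentage,
)
from .inequality import EXPOSURE

log = logging.getLogger(__name__)


class SeparationError(ValueError):
    """Perfect separation in the propensity model (positivity violation)."""


@dataclass
class PropensityReport:
    """Fitted propensity scores for early recognition and their range."""

    probabilities: np.ndarray
    minimum: float
    maximum: float
    model_terms: list[str]
    n: int
    warnings: list[str]


def dichotomize_early(recognition_weeks):
    """1 if recognition within 6 weeks (inclusive), 0 beyond, NaN propagates."""
    x = np.asarray(recognition_weeks, dtype=float)
    if (x[~np.isnan(x)] < 0).any():
        raise ValueError("recognition_weeks must be non-negative")
    out = np.where(np.isnan(x), np.nan, (x <= EARLY_RECOGNITION_WEEKS).astype(float))
    return out if out.ndim else float(out)


def dichotomize_timely(init_weeks):
    """1 if initiation within 14 weeks (inclusive), else 0; missing is an error."""
    x = np.asarray(init_weeks, dtype=float)
    if np.isnan(x).any():
        raise ValueError("init_weeks is never missing")
    if (x <= 0).any():
        raise ValueError("init_weeks must be positive")
    out = (x <= TIMELY_INITIATION_WEEKS).astype(float)
    return out if out.ndim else float(out)


_TABLE1_VARS = PREDICTORS + ["early_recognition", "regular_cycle"]
_BINARY_DISPLAY = {
    "early_recognition": {0.0: "no", 1.0: "yes"},
    "regular_cycle": {0.0: "irregular", 1.0: "regular"},
}


def make_table1(table: pd.DataFrame) -> pd.DataFrame:
    """Counts and column percentages per variable level, stratified by
    timely (<= 14 wk) versus late initiation.

    Percentages use the non-missing denominator of that variable within the
    stratum, rounded to one decimal.  Tidy output: variable, level, stratum
    in {total, timely, late}, count, pct.
    """
    timely = dichotomize_timely(table["init_weeks"]) == 1.0
    strata = {"total": np.ones(len(table), bool), "timely": timely, "late": ~timely}
    rows = []
    for var in _TABLE1_VARS:
        col = table[var]
        if var in _BINARY_DISPLAY:
            values = col.map(_BINARY_DISPLAY[var])
            levels = list(_BINARY_DISPLAY[var].values())
        else:
            values = col
            levels = LEVELS[var]
        for stratum, mask in strata.items():
            sub = values[mask]
            denom = sub.notna().sum()
            for lv in levels:
                count = int((sub == lv).sum())
                rows.append({
                    "variable": var, "level": lv, "stratum": stratum,
                    "count": count, "pct": percentage(count, denom),
                })
    return pd.DataFrame(rows)


def check_positivity(table: pd.DataFrame, floor: float = 0.01) -> PropensityReport:
    """Logistic propensity model of early recognition on all 13 predictors.

    Runs on complete cases of the non-imputed data.  Reports every fitted
    probability and the minimum; logs a warning when the minimum falls below
    ``floor``.  Perfect separation raises :class:`SeparationError` naming a
    separating covariate.
    """
    sub = table.dropna(subset=[EXPOSURE, *PREDICTORS])
    a = sub[EXPOSURE].to_numpy(dtype=float)
    terms = ["intercept"]
    cols = [np.ones(len(sub))]
    for pred in PREDICTORS:
        codes = sub[pred].to_numpy(dtype=object)
        for lv in LEVELS[pred][1:]:
            ind = (codes == lv).astype(float)
            if ind.std() == 0.0:
                continue
            terms.append(f"{pred}[{lv}]")
            cols.append(ind)
    X = np.column_stack(cols)

    def _separating_covariate() -> str | None:
        for pred in PREDICTORS:
            tab = pd.crosstab(sub[pred], a)
            if (tab.to_numpy() == 0).any():
                return pred
        return None

    # a level observed only with one exposure value separates the main-effects
    # model exactly; detect it up front so the error names the covariate
    culprit = _separating_covariate()
    if culprit is not None:
        raise SeparationError(f"perfect separation; separating covariate: {culprit}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(a, X).fit(disp=0, maxiter=200)
            proba = np.asarray(res.predict(X), dtype=float)
        except Exception as exc:  # noqa: BLE001 - statsmodels raises several types
            raise SeparationError("propensity model did not fit cleanly") from exc
    eps = 1e-10
    if (proba <= eps).any() or (proba >= 1 - eps).any():
        raise SeparationError("fitted propensities at 0/1")
    msgs = []
    if proba.min() < floor:
        msg = f"minimum propensity {proba.min():.4f} below floor {floor}"
        log.warning(msg)
        msgs.append(msg)
    return PropensityReport(
        probabilities=proba,
        minimum=float(proba.min()),
        maximum=float(proba.max()),
        model_terms=terms,
        n=len(sub),
        warnings=msgs,
    )


def filter_regular_cycle(table: pd.DataFrame) -> pd.DataFrame:
    """Subset to participants with a regular menstrual cycle (28 +/- 4 days).

    The full pipeline is re-runnable unchanged on the result.
    """
    if "regular_cycle" not in table.columns:
        raise ValueError("regular_cycle column absent")
    out = table[table["regular_cycle"] == 1.0].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("regular-cycle subset is empty")
    return out
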