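"""G-computation of the "everyone recognises pregnancy early" scenario.

The hypothetical intervention sets every participant's exposure (early
pregnancy recognition, within 6 gestational weeks) to 1.  Under the
main-effects linear outcome model the counterfactual outcome is the observed
outcome shifted by the adjusted exposure effect for participants without
early recognition:

    Y*_i = Y_i + beta_A (1 - A_i)

which preserves each participant's residual and satisfies consistency
(Y*_i = Y_i exactly when A_i = 1).  For models with exposure-covariate
interactions the prediction-based variant is available:

    Y*_i = Yhat_i(A=1, X_i) + (Y_i - Yhat_i(A_i, X_i)).

The inequality "with intervention" is the same one-predictor regression run
on Y*; the reduction is with-minus-without.  Under the shift construction
the reduction for level l has the closed form beta_A (Abar_ref - Abar_l),
where Abar_g is the exposure prevalence in group g.

A brute-force standardisation oracle (stratum-wise substitution of observed
stratum-specific means among the exposed) provides an independent check on
small, coarse tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import LEVELS
from .inequality import (
    EXPOSURE,
    OUTCOME,
    ModelFit,
    choose_reference,
    estimate_inequality,
)

ROW_COLUMNS = [
    "predictor", "level", "is_reference",
    "beta_without", "ci_without_lo", "ci_without_hi",
    "beta_with", "ci_with_lo", "ci_with_hi",
    "reduction", "ci_reduction_lo", "ci_reduction_hi",
]


class PositivityViolationError(ValueError):
    """A covariate stratum with unexposed rows has no exposed counterpart."""


def counterfactual_outcomes(
    table: pd.DataFrame,
    fit: ModelFit,
    mode: str = "shift",
) -> np.ndarray:
    """Counterfactual initiation timing under do(A = 1), in weeks.

    ``mode="shift"`` applies the observed-outcome shift (exact for
    main-effects models); ``mode="predict"`` uses model predictions plus the
    participant's residual, valid for interaction models too.  Rows with
    missing exposure raise an alignment error.
    """
    a = table[EXPOSURE].to_numpy(dtype=float)
    y = table[OUTCOME].to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(y).any():
        raise ValueError("exposure/outcome missing: counterfactuals need completed data")
    if mode == "shift":
        return y + fit.exposure_effect * (1.0 - a)
    if mode == "predict":
        pred_1 = fit.predict(table, set_exposure=1.0)
        pred_obs = fit.predict(table)
        return pred_1 + (y - pred_obs)
    raise ValueError(f"unknown counterfactual mode {mode!r}")


def estimate_reduction(
    table: pd.DataFrame,
    predictor: str,
    fit: ModelFit,
    reference: str | None = None,
    mode: str = "shift",
) -> pd.DataFrame:
    """Inequality rows without/with intervention and their reduction.

    Point estimates only (CI columns are NaN here; intervals come from the
    bootstrap).  The reference level, if not given, is chosen from this
    table's observed outcomes.
    """
    ref = reference if reference is not None else choose_reference(table, predictor)
    y_star = pd.Series(counterfactual_outcomes(table, fit, mode=mode), index=table.index)
    fit_without = estimate_inequality(table, predictor, ref)
    fit_with = estimate_inequality(table, predictor, ref, outcome=y_star)
    rows = []
    for lv in LEVELS[predictor]:
        row = {c: np.nan for c in ROW_COLUMNS}
        row.update(predictor=predictor, level=lv, is_reference=lv == ref)
        if lv == ref:
            row.update(beta_without=0.0, beta_with=0.0, reduction=0.0)
        else:
            term = f"{predictor}[{lv}]"
            if term in fit_without.dropped or term not in fit_without.terms:
                warnings.warn(f"{term}: empty level, estimates absent", stacklevel=2)
            else:
                bw = fit_without.get(term)
                bi = fit_with.get(term)
                row.update(beta_without=bw, beta_with=bi, reduction=bi - bw)
        rows.append(row)
    return pd.DataFrame(rows, columns=ROW_COLUMNS)


def reduction_closed_form(
    table: pd.DataFrame,
    predictor: str,
    fit: ModelFit,
    reference: str | None = None,
) -> pd.Series:
    """beta_A (Abar_ref - Abar_l) per level: the shift-mode reduction identity."""
    ref = reference if reference is not None else choose_reference(table, predictor)
    sub = table.dropna(subset=[predictor, EXPOSURE])
    abar = sub.groupby(predictor, observed=True)[EXPOSURE].mean()
    out = {}
    for lv in LEVELS[predictor]:
        if lv == ref:
            out[lv] = 0.0
        elif lv in abar.index:
            out[lv] = fit.exposure_effect * (abar[ref] - abar[lv])
        else:
            out[lv] = np.nan
    return pd.Series(out, name="reduction")


def standardization_oracle(
    table: pd.DataFrame,
    predictor: str,
    strata_cols: list[str] | None = None,
    reference: str | None = None,
) -> pd.DataFrame:
    """Exhaustive standardisation: substitute, for every unexposed row, the
    observed mean outcome of the exposed rows in its covariate stratum.

    Agrees with g-computation when the outcome model is saturated in
    (stratum x exposure).  Intended for small, coarse tables; raises
    :class:`PositivityViolationError` when an unexposed cell has no exposed
    counterpart.
    """
    strata = strata_cols if strata_cols is not None else [predictor]
    ref = reference if reference is not None else choose_reference(table, predictor)
    a = table[EXPOSURE].to_numpy(dtype=float)
    y = table[OUTCOME].to_numpy(dtype=float)
    key = [tuple(row) for row in table[strata].astype(str).to_numpy()]
    exposed_mean = (
        pd.Series(y[a == 1.0], index=[key[i] for i in np.flatnonzero(a == 1.0)])
        .groupby(level=0)
        .mean()
    )
    y_star = y.copy()
    unexposed = np.flatnonzero(a == 0.0)
    for i in unexposed:
        cell = key[i]
        if cell not in exposed_mean.index:
            raise PositivityViolationError(
                f"stratum {dict(zip(strata, cell))} has unexposed rows but no exposed rows"
            )
        y_star[i] = exposed_mean[cell]

    y_star = pd.Series(y_star, index=table.index)
    fit_without = estimate_inequality(table, predictor, ref)
    fit_with = estimate_inequality(table, predictor, ref, outcome=y_star)
    rows = []
    for lv in LEVELS[predictor]:
        row = {c: np.nan for c in ROW_COLUMNS}
        row.update(predictor=predictor, level=lv, is_reference=lv == ref)
        if lv == ref:
            row.update(beta_without=0.0, beta_with=0.0, reduction=0.0)
        else:
            term = f"{predictor}[{lv}]"
            if term in fit_without.terms:
                bw = fit_without.get(term)
                bi = fit_with.get(term)
                row.update(beta_without=bw, beta_with=bi, reduction=bi - bw)
        rows.append(row)
    return pd.DataFrame(rows, columns=ROW_COLUMNS)
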