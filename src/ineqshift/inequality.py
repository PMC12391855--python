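"""Per-predictor inequality regressions and the adjusted exposure model.

An "inequality" is the contrast, in weeks of gestation at the first
antenatal visit, between a predictor level and that predictor's reference
level.  Following the convention that keeps every inequality non-negative,
the reference level is the level with the *earliest* mean initiation,
chosen once on the observed data and reused for the counterfactual scenario.

Two model families live here:

* one-predictor-at-a-time OLS (the default "inequality" models; contrasts
  equal group-mean differences exactly), and
* the adjusted exposure model: OLS of initiation timing on the early
  recognition flag plus main effects of all thirteen predictors, whose
  exposure coefficient is the g-computation shift.

Fits use statsmodels OLS with its pseudo-inverse solver, which degrades
gracefully on near-collinear indicator sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import LEVELS, PREDICTORS

EXPOSURE = "early_recognition"
OUTCOME = "init_weeks"


@dataclass
class ModelFit:
    """Fitted linear model: named coefficients, covariance, design metadata."""

    terms: list[str]
    coefs: np.ndarray
    vcov: np.ndarray
    n: int
    sigma2: float
    dropped: list[str] = field(default_factory=list)
    design_builder: Callable[[pd.DataFrame], np.ndarray] | None = None

    def get(self, term: str) -> float:
        return float(self.coefs[self.terms.index(term)])

    def se(self, term: str) -> float:
        i = self.terms.index(term)
        return float(np.sqrt(self.vcov[i, i]))

    @property
    def exposure_effect(self) -> float:
        return self.get(EXPOSURE)

    def predict(self, table: pd.DataFrame, *, set_exposure: float | None = None) -> np.ndarray:
        """Model prediction, optionally with the exposure column forced."""
        if self.design_builder is None:
            raise ValueError("fit carries no design builder")
        frame = table
        if set_exposure is not None:
            frame = table.copy()
            frame[EXPOSURE] = float(set_exposure)
        return self.design_builder(frame) @ self.coefs


def choose_reference(table: pd.DataFrame, predictor: str) -> str:
    """Level of ``predictor`` with the earliest mean initiation.

    Ties break by the level dictionary's order; levels with zero rows are
    excluded from candidacy with a warning.  Deterministic for a fixed table.
    """
    levels = LEVELS[predictor]
    sub = table[[predictor, OUTCOME]].dropna(subset=[predictor])
    means = sub.groupby(predictor, observed=True)[OUTCOME].mean()
    empty = [lv for lv in levels if lv not in means.index]
    if empty:
        warnings.warn(f"{predictor}: levels with no rows excluded from reference "
                      f"candidacy: {empty}", stacklevel=2)
    candidates = [lv for lv in levels if lv in means.index]
    if len(candidates) < 2:
        raise ValueError(f"{predictor}: needs >= 2 non-empty levels")
    best = candidates[0]
    for lv in candidates[1:]:
        if means[lv] < means[best]:
            best = lv
    return best


def choose_references(table: pd.DataFrame) -> dict[str, str]:
    """Reference level per predictor, frozen from one (observed) table."""
    return {p: choose_reference(table, p) for p in PREDICTORS}


def _ols(y: np.ndarray, X: np.ndarray, terms: list[str],
         builder: Callable | None = None) -> ModelFit:
    res = sm.OLS(y, X).fit()
    return ModelFit(
        terms=terms,
        coefs=np.asarray(res.params, dtype=float),
        vcov=np.asarray(res.cov_params(), dtype=float),
        n=int(res.nobs),
        sigma2=float(res.mse_resid) if res.df_resid > 0 else float("nan"),
        design_builder=builder,
    )


def estimate_inequality(
    table: pd.DataFrame,
    predictor: str,
    reference: str,
    outcome: str | pd.Series = OUTCOME,
) -> ModelFit:
    """Unadjusted OLS of the outcome on one predictor's level indicators.

    Coefficients are mean differences in weeks versus ``reference``.
    ``outcome`` may name a column or be an aligned series (used for the
    counterfactual scenario).  Levels empty after subsetting are dropped from
    the design and recorded in ``fit.dropped``.
    """
    if reference not in LEVELS[predictor]:
        raise ValueError(f"{reference!r} is not a level of {predictor!r}")
    y_all = table[outcome] if isinstance(outcome, str) else outcome
    keep = table[predictor].notna() & pd.Series(y_all).notna().to_numpy()
    sub = table.loc[keep, predictor].to_numpy(dtype=object)
    y = np.asarray(y_all)[np.asarray(keep)]
    terms = ["intercept"]
    cols = [np.ones(len(y))]
    dropped = []
    for lv in LEVELS[predictor]:
        if lv == reference:
            continue
        ind = (sub == lv).astype(float)
        if ind.sum() == 0:
            dropped.append(f"{predictor}[{lv}]")
            continue
        terms.append(f"{predictor}[{lv}]")
        cols.append(ind)
    fit = _ols(y, np.column_stack(cols), terms)
    fit.dropped = dropped
    return fit


def _adjusted_design(references: dict[str, str]):
    """Design builder: intercept, exposure, all-predictor level indicators."""
    def build(frame: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(frame)), frame[EXPOSURE].to_numpy(dtype=float)]
        for pred in PREDICTORS:
            ref = references[pred]
            codes = frame[pred].to_numpy(dtype=object)
            for lv in LEVELS[pred]:
                if lv != ref:
                    cols.append((codes == lv).astype(float))
        return np.column_stack(cols)

    terms = ["intercept", EXPOSURE]
    for pred in PREDICTORS:
        terms += [f"{pred}[{lv}]" for lv in LEVELS[pred] if lv != references[pred]]
    return build, terms


def fit_adjusted_exposure_model(
    table: pd.DataFrame,
    references: dict[str, str] | None = None,
) -> ModelFit:
    """OLS of initiation timing on early recognition + all 13 predictors.

    The exposure coefficient is the adjusted effect of early recognition in
    weeks.  Zero-variance indicator columns (empty levels) are dropped with a
    warning and recorded in ``fit.dropped``.
    """
    refs = references if references is not None else choose_references(table)
    build, terms = _adjusted_design(refs)
    sub = table.dropna(subset=[EXPOSURE, OUTCOME, *PREDICTORS])
    X = build(sub)
    keep_cols = np.ones(X.shape[1], dtype=bool)
    dropped = []
    for j in range(2, X.shape[1]):  # never drop intercept or exposure
        if X[:, j].std() == 0.0:
            keep_cols[j] = False
            dropped.append(terms[j])
    if dropped:
        warnings.warn(f"dropping empty/constant indicators: {dropped}", stacklevel=2)
    kept_terms = [t for t, k in zip(terms, keep_cols) if k]

    def builder(frame: pd.DataFrame, _keep=keep_cols, _build=build) -> np.ndarray:
        return _build(frame)[:, _keep]

    fit = _ols(sub[OUTCOME].to_numpy(dtype=float), X[:, keep_cols], kept_terms, builder)
    fit.dropped = dropped
    return fit


def fit_interaction_exposure_model(
    table: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> ModelFit:
    """Exposure model with full exposure-by-covariate interactions.

    With a single categorical covariate this is saturated in
    (stratum x exposure), the regime where g-computation matches exhaustive
    standardisation exactly.  Used with prediction-based counterfactuals.
    """
    refs = dict(references or {})
    for c in covariates:
        refs.setdefault(c, choose_reference(table, c))

    def build(frame: pd.DataFrame) -> np.ndarray:
        a = frame[EXPOSURE].to_numpy(dtype=float)
        cols = [np.ones(len(frame)), a]
        for pred in covariates:
            codes = frame[pred].to_numpy(dtype=object)
            for lv in LEVELS[pred]:
                if lv != refs[pred]:
                    ind = (codes == lv).astype(float)
                    cols.append(ind)
                    cols.append(ind * a)
        return np.column_stack(cols)

    terms = ["intercept", EXPOSURE]
    for pred in covariates:
        for lv in LEVELS[pred]:
            if lv != refs[pred]:
                terms += [f"{pred}[{lv}]", f"{EXPOSURE}:{pred}[{lv}]"]
    sub = table.dropna(subset=[EXPOSURE, OUTCOME, *covariates])
    return _ols(sub[OUTCOME].to_numpy(dtype=float), build(sub), terms, build)
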