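"""Multiple imputation by chained equations, with Rubin pooling.

Each incomplete variable is visited once per iteration (ascending order of
missing fraction, ties alphabetical) and re-imputed from a conditional model
given all other variables: predictive mean matching with k = 5 donors for
continuous variables, (multinomial) logistic draws for categorical and binary
ones.  The derived exposure flag (early recognition, recognition within 6
weeks) is never imputed directly: it is recomputed from the imputed
recognition timing after every update, so the definitional invariant holds in
every completed dataset.  The three auxiliaries (BMI at intake, gestational
age at intake, 5-minute Apgar) enter every conditional model.

Pooling follows Rubin's rules: pooled estimate = mean over imputations,
total variance = within + (1 + 1/m) x between, interval via a t reference
with Barnard-Rubin degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    AUXILIARIES,
    BINARY,
    EARLY_RECOGNITION_WEEKS,
    LEVELS,
    PREDICTORS,
)

log = logging.getLogger(__name__)

#: Variables eligible for imputation (everything except the outcome, the id
#: and the passively derived exposure flag).
IMPUTABLE: list[str] = PREDICTORS + ["recognition_weeks", "regular_cycle"] + AUXILIARIES

#: Variables usable as predictors in conditional models.  The exposure flag
#: is excluded (it is a deterministic function of recognition_weeks).
_MODEL_VARS: list[str] = PREDICTORS + ["recognition_weeks", "init_weeks", "regular_cycle"] + AUXILIARIES


class ImputationError(ValueError):
    """Imputation is impossible as requested (e.g. a fully missing variable)."""


@dataclass
class ImputedSets:
    """M completed copies of a cohort table sharing all observed cells."""

    tables: list[pd.DataFrame]
    m: int
    iterations: int
    seed: int
    visit_order: list[str]

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ImputationError("m must be >= 2")
        if self.m != len(self.tables):
            raise ImputationError("m does not match number of tables")


@dataclass
class PooledEstimate:
    """Rubin-pooled estimate with its variance decomposition and CI."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci: tuple[float, float]


def _design_matrix(work: pd.DataFrame, exclude: str) -> np.ndarray:
    """Numeric design matrix from all model variables except ``exclude``."""
    cols = []
    for var in _MODEL_VARS:
        if var == exclude:
            continue
        if var in LEVELS:
            levels = LEVELS[var]
            codes = work[var].to_numpy()
            for lv in levels[1:]:
                cols.append((codes == lv).astype(float))
        else:
            cols.append(work[var].to_numpy(dtype=float))
    X = np.column_stack(cols)
    return np.column_stack([np.ones(len(work)), X])


def _pmm_impute(y_obs, X_obs, X_mis, rng, k: int = 5) -> np.ndarray:
    """Predictive mean matching (type-1): Bayesian draw of the regression
    parameters for the missing-row predictions, k-nearest-donor draw."""
    n, p = X_obs.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - rank, 1)
    sigma2_star = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    # ridge jitter keeps the draw defined when indicators are collinear
    xtx = X_obs.T @ X_obs + 1e-8 * np.eye(p)
    try:
        L = np.linalg.cholesky(np.linalg.inv(xtx) * sigma2_star)
        beta_star = beta_hat + L @ rng.standard_normal(p)
    except np.linalg.LinAlgError:  # pragma: no cover - extreme collinearity
        beta_star = beta_hat
    pred_obs = X_obs @ beta_hat
    pred_mis = X_mis @ beta_star

    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    pos = np.searchsorted(sorted_pred, pred_mis)
    k_eff = min(k, n)
    out = np.empty(len(pred_mis))
    for i, (pm, ins) in enumerate(zip(pred_mis, pos)):
        lo = max(ins - k_eff, 0)
        hi = min(ins + k_eff, n)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist, kind="stable")[:k_eff]]
        out[i] = y_obs[donors[rng.integers(len(donors))]]
    return out


def _categorical_impute(y_obs, X_obs, X_mis, levels, rng) -> np.ndarray:
    """Multinomial-logistic posterior-predictive draw; falls back to a
    marginal draw when the model cannot be fitted."""
    present = [lv for lv in levels if (y_obs == lv).any()]
    if len(present) == 1:
        return np.full(len(X_mis), present[0], dtype=object)
    try:
        from sklearn.linear_model import LogisticRegression

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(penalty=None, max_iter=200, tol=1e-4)
            clf.fit(X_obs[:, 1:], y_obs.astype(str))
            proba = clf.predict_proba(X_mis[:, 1:])
        classes = clf.classes_
    except Exception:  # noqa: BLE001 - any fit failure falls back
        log.warning("conditional model failed; falling back to marginal draw")
        classes = np.array(present, dtype=object)
        counts = np.array([(y_obs == lv).sum() for lv in present], dtype=float)
        proba = np.tile(counts / counts.sum(), (len(X_mis), 1))
    cum = np.cumsum(proba, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(X_mis))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(classes, dtype=object)[idx]


def _visit_order(table: pd.DataFrame, variables: list[str]) -> list[str]:
    fractions = {v: float(table[v].isna().mean()) for v in variables}
    return sorted(variables, key=lambda v: (fractions[v], v))


def _run_chain(table, masks, order, iterations, rng, donor_k):
    work = table.copy()
    # initial fill: random draws from the observed marginal of each variable
    for var in order:
        mask = masks[var]
        observed = table.loc[~mask, var].to_numpy()
        work.loc[mask, var] = rng.choice(observed, size=int(mask.sum()), replace=True)
    _refresh_derived(work)
    for _ in range(iterations):
        for var in order:
            mask = masks[var].to_numpy()
            X = _design_matrix(work, exclude=var)
            if var in LEVELS:
                imputed = _categorical_impute(
                    table.loc[~mask, var].to_numpy(dtype=object), X[~mask], X[mask],
                    LEVELS[var], rng,
                )
            elif var in BINARY:
                imputed = _categorical_impute(
                    table.loc[~mask, var].to_numpy().astype(int).astype(str),
                    X[~mask], X[mask], ["0", "1"], rng,
                ).astype(float)
            else:
                imputed = _pmm_impute(
                    table.loc[~mask, var].to_numpy(dtype=float), X[~mask], X[mask],
                    rng, k=donor_k,
                )
            work.loc[mask, var] = imputed
            if var == "recognition_weeks":
                _refresh_derived(work)
        log.debug("iteration means: recognition=%.3f", work["recognition_weeks"].mean())
    return work


def _refresh_derived(work: pd.DataFrame) -> None:
    work["early_recognition"] = (
        work["recognition_weeks"] <= EARLY_RECOGNITION_WEEKS
    ).astype(float)


def impute_chained(
    table: pd.DataFrame,
    m: int = 50,
    iterations: int = 100,
    seed: int = 0,
    donor_k: int = 5,
) -> ImputedSets:
    """Impute a cohort table m times by chained equations.

    Runs m independent chains (seeded from ``seed``), each sweeping the
    incomplete variables ``iterations`` times.  A table with no missing cells
    returns m identical copies.  A 100%-missing variable raises
    :class:`ImputationError`.
    """
    if m < 2:
        raise ImputationError("m must be >= 2")
    incomplete = [v for v in IMPUTABLE if v in table.columns and table[v].isna().any()]
    for var in incomplete:
        if table[var].isna().all():
            raise ImputationError(f"variable {var!r} is 100% missing")
    order = _visit_order(table, incomplete)
    if not incomplete:
        tables = [table.copy() for _ in range(m)]
        return ImputedSets(tables=tables, m=m, iterations=iterations, seed=seed, visit_order=[])
    masks = {v: table[v].isna() for v in incomplete}
    tables = []
    for j in range(m):
        rng = np.random.default_rng([seed, j])
        tables.append(_run_chain(table, masks, order, iterations, rng, donor_k))
    return ImputedSets(tables=tables, m=m, iterations=iterations, seed=seed, visit_order=order)


def pool_rubin(
    estimates,
    variances,
    alpha: float = 0.05,
    nu_complete: float | None = None,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    ``nu_complete`` is the complete-data degrees of freedom; when given, the
    Barnard-Rubin small-sample adjustment is applied, otherwise the classical
    large-sample degrees of freedom are used.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    m = len(q)
    if m < 2:
        raise ImputationError("pooling requires m >= 2 (between-variance undefined)")
    if (u < 0).any():
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1 + 1 / m) * between
    if between == 0.0 or total == 0.0:
        df = np.inf
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        r = (1 + 1 / m) * between / within if within > 0 else np.inf
        df_old = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1.0
        if nu_complete is not None:
            lam = (1 + 1 / m) * between / total
            nu_obs = (nu_complete + 1) / (nu_complete + 3) * nu_complete * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / nu_obs)
        else:
            df = df_old
        crit = stats.t.ppf(1 - alpha / 2, df)
    half = crit * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        within_var=within,
        between_var=between,
        total_var=total,
        df=float(df),
        ci=(qbar - half, qbar + half),
    )
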