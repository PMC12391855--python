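"""Percentile-bootstrap confidence intervals combined with multiple imputation.

Ordering: imputation happens once; each bootstrap replicate draws one
row-index resample of size n and applies it identically across all M
completed datasets (keeping within-person correlation intact), runs the
estimator on each resampled dataset, and pools the M parameter vectors by
their mean (the Rubin point-combining rule).  The confidence interval for a
parameter is the percentile interval over its B pooled replicates; point
estimates come from the unresampled data.

Replicates in which a parameter is inestimable (a predictor level vanished
from the resample) are recorded as absent; parameters with more than 1% of
draws absent are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .imputation import ImputedSets


@dataclass
class BootstrapDistribution:
    """Bootstrap draws of one parameter (NaN marks an absent draw)."""

    parameter: str
    draws: np.ndarray
    B: int
    alpha: float
    seed: int

    def ci(self) -> tuple[float, float]:
        return percentile_ci(self.draws[~np.isnan(self.draws)], self.alpha)


def percentile_ci(draws, alpha: float = 0.05) -> tuple[float, float]:
    """(alpha/2, 1 - alpha/2) linear-interpolation quantiles of the draws.

    For sorted draws x_1..x_n and probability p the value is
    x_{floor(h)} + (h - floor(h)) (x_{floor(h)+1} - x_{floor(h)}) with
    h = (n - 1) p + 1.
    """
    x = np.asarray(draws, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("percentile CI needs >= 2 present draws")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def bootstrap_pipeline(
    imputed: ImputedSets,
    estimator: Callable[[pd.DataFrame], pd.Series],
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    flag_threshold: float = 0.01,
) -> pd.DataFrame:
    """Percentile CIs for every parameter of ``estimator`` over B resamples.

    ``estimator`` maps one completed cohort table to a flat named parameter
    vector (NaN for parameters inestimable on that table).  Returns a tidy
    frame: parameter, estimate (pooled, unresampled), ci_lo, ci_hi,
    n_absent, flagged.  Fully reproducible from ``seed``.
    """
    point = _pooled(imputed.tables, estimator)
    n = len(imputed.tables[0])
    rng = np.random.default_rng(seed)
    draws = np.empty((B, len(point)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = [t.iloc[idx].reset_index(drop=True) for t in imputed.tables]
        draws[b] = _pooled(resampled, estimator).to_numpy()

    rows = []
    for j, name in enumerate(point.index):
        col = draws[:, j]
        absent = int(np.isnan(col).sum())
        present = col[~np.isnan(col)]
        if len(present) >= 2:
            lo, hi = percentile_ci(present, alpha)
        else:
            lo = hi = np.nan
        rows.append({
            "parameter": name,
            "estimate": point[name],
            "ci_lo": lo,
            "ci_hi": hi,
            "n_absent": absent,
            "flagged": absent > flag_threshold * B,
        })
    return pd.DataFrame(rows)


def _pooled(tables, estimator) -> pd.Series:
    """Rubin point-combining: mean of the per-imputation parameter vectors.

    A parameter absent (NaN) in any imputation is absent from the pooled
    vector for that replicate.
    """
    stacked = pd.concat([estimator(t) for t in tables], axis=1)
    return stacked.mean(axis=1, skipna=False)
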