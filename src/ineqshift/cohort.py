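"""Cohort table schema: column dictionary, categorical level sets, validation, CSV I/O.

The analysis operates on a participant-level table with thirteen categorical
predictors of antenatal-care timing, a binary exposure (early pregnancy
recognition, i.e. recognition within 6 gestational weeks), a continuous
outcome (gestational age in weeks at the first antenatal visit), a
menstrual-cycle regularity flag used in sensitivity analyses, and three
continuous auxiliaries carried along only to strengthen imputation models.

The table itself is a plain :class:`pandas.DataFrame`; this module owns the
schema and keeps every reader/writer honest about it.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Categorical predictor levels, in display order.  The first level is only
#: the display anchor; reference levels for regression contrasts are chosen
#: from the data (see :func:`ineqshift.inequality.choose_reference`).
LEVELS: dict[str, list[str]] = {
    "age_group": ["<20", "20-25", "25-30", "30-35", ">=35"],
    "migration": ["none", "2nd_generation", "1st_generation"],
    "relationship": ["partner", "single"],
    "intention": ["planned", "unplanned_wanted", "unplanned_ambivalent"],
    "mental_illness": ["no", "ever", "recent"],
    "language": ["sufficient", "reasonable", "insufficient"],
    "parity": ["0", "1", "2", "3+"],
    "education": ["high", "medium", "low"],
    "employment": ["yes", "no"],
    "income": ["high", "medium", "low"],
    "housing": ["own", "rented"],
    "deprivation": ["low", "medium", "high"],
    "iq": [">=85", "70-85", "<70"],
}

PREDICTORS: list[str] = list(LEVELS)

#: Continuous columns (weeks for the gestational ones).
CONTINUOUS: list[str] = ["recognition_weeks", "init_weeks", "bmi_intake", "ga_intake", "apgar5"]

#: Binary 0/1 columns (floats so that missing values are representable).
BINARY: list[str] = ["early_recognition", "regular_cycle"]

COLUMNS: list[str] = (
    ["participant_id"]
    + PREDICTORS
    + ["recognition_weeks", "early_recognition", "init_weeks", "regular_cycle",
       "bmi_intake", "ga_intake", "apgar5"]
)

#: Imputation auxiliaries: enter every conditional imputation model but no
#: analysis model.
AUXILIARIES: list[str] = ["bmi_intake", "ga_intake", "apgar5"]

#: Gestational-week threshold defining early pregnancy recognition (inclusive).
EARLY_RECOGNITION_WEEKS: float = 6.0
#: Threshold for "timely" antenatal-care initiation (inclusive).
TIMELY_INITIATION_WEEKS: float = 14.0

# ---------------------------------------------------------------------------
# Published calibration marginals.
#
# Observed counts per level of each characteristic in the reference cohort
# (analytical sample N = 4196): (total, initiation <= 14 wk, initiation > 14 wk).
# Denominators vary by variable because counts are over non-missing rows.
# Parity counts were not published; the generator's parity prevalences are a
# package choice (see docs/methods.md).
# ---------------------------------------------------------------------------

N_TOTAL = 4196
N_TIMELY = 3417
N_LATE = 779

TABLE1_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "age_group": {
        "<20": (239, 140, 99),
        "20-25": (769, 584, 185),
        "25-30": (1142, 940, 202),
        "30-35": (1506, 1319, 187),
        ">=35": (490, 387, 103),
    },
    "migration": {
        "none": (1908, 1711, 197),
        "2nd_generation": (610, 498, 112),
        "1st_generation": (1348, 1007, 341),
    },
    "relationship": {
        "partner": (3196, 2725, 471),
        "single": (598, 430, 168),
    },
    "intention": {
        "planned": (2454, 2139, 315),
        "unplanned_wanted": (638, 491, 147),
        "unplanned_ambivalent": (465, 324, 141),
    },
    "mental_illness": {
        "no": (1845, 1559, 286),
        "ever": (770, 673, 97),
        "recent": (365, 308, 57),
    },
    "language": {
        "sufficient": (2400, 2085, 315),
        "reasonable": (728, 578, 150),
        "insufficient": (391, 274, 117),
    },
    "education": {
        "high": (910, 815, 95),
        "medium": (1892, 1605, 287),
        "low": (977, 726, 251),
    },
    "employment": {
        "yes": (2174, 1935, 239),
        "no": (862, 641, 221),
    },
    "income": {
        "high": (1886, 1704, 182),
        "medium": (598, 490, 108),
        "low": (686, 492, 194),
    },
    "housing": {
        "own": (1626, 1466, 160),
        "rented": (1572, 1249, 323),
    },
    "deprivation": {
        "low": (1336, 1181, 155),
        "medium": (1367, 1134, 233),
        "high": (1445, 1058, 387),
    },
    "iq": {
        ">=85": (2001, 1759, 242),
        "70-85": (521, 405, 116),
        "<70": (153, 110, 43),
    },
    "early_recognition": {
        "no": (572, 410, 162),
        "yes": (2554, 2180, 374),
    },
    "regular_cycle": {
        "irregular": (1836, 1408, 428),
        "regular": (2360, 2009, 351),
    },
}


def percentage(count: float, denominator: float) -> float:
    """Column percentage rounded to one decimal, the table-display convention."""
    if denominator <= 0:
        return math.nan
    return round(100.0 * count / denominator, 1)


class CohortValidationError(ValueError):
    """A table violates the cohort column dictionary."""


def validate_cohort(table: pd.DataFrame, *, require_complete: bool = False) -> None:
    """Check a cohort table against the column dictionary.

    Raises :class:`CohortValidationError` naming the first offending column
    (and row, for bad categorical labels).  With ``require_complete`` every
    cell must be non-missing.
    """
    missing_cols = [c for c in COLUMNS if c not in table.columns]
    if missing_cols:
        raise CohortValidationError(f"missing required columns: {missing_cols}")
    if table["init_weeks"].isna().any():
        raise CohortValidationError("init_weeks has missing values (inclusion criterion)")
    if (table["init_weeks"].dropna() <= 0).any():
        raise CohortValidationError("init_weeks must be positive gestational weeks")
    rec = table["recognition_weeks"].dropna()
    if (rec < 0).any():
        raise CohortValidationError("recognition_weeks must be non-negative")
    for col, levels in LEVELS.items():
        observed = table[col].dropna()
        bad = ~observed.isin(levels)
        if bad.any():
            row = int(observed.index[bad][0])
            raise CohortValidationError(
                f"unknown label {observed[bad].iloc[0]!r} for {col!r} at row {row}; "
                f"allowed: {levels}"
            )
    for col in BINARY:
        observed = table[col].dropna()
        if not observed.isin([0, 1, 0.0, 1.0]).all():
            raise CohortValidationError(f"{col!r} must be 0/1")
    # derived-exposure consistency wherever recognition is observed
    obs = table["recognition_weeks"].notna()
    if obs.any():
        expected = (table.loc[obs, "recognition_weeks"] <= EARLY_RECOGNITION_WEEKS).astype(float)
        actual = table.loc[obs, "early_recognition"]
        if not np.allclose(expected.to_numpy(), actual.to_numpy(), equal_nan=False):
            raise CohortValidationError(
                "early_recognition inconsistent with recognition_weeks <= "
                f"{EARLY_RECOGNITION_WEEKS}"
            )
    if table["early_recognition"].notna().to_numpy().sum() < obs.to_numpy().sum():
        raise CohortValidationError("early_recognition missing where recognition_weeks observed")
    if require_complete:
        cols = [c for c in COLUMNS if c != "participant_id"]
        if table[cols].isna().any().any():
            bad = table[cols].isna().any()
            raise CohortValidationError(f"missing cells in {list(bad.index[bad])}")
    if table["participant_id"].duplicated().any():
        raise CohortValidationError("participant_id not unique")


def read_cohort_csv(path, *, validate: bool = True) -> pd.DataFrame:
    """Read a cohort CSV (empty cells are missing; labels are case-sensitive)."""
    table = pd.read_csv(
        path,
        dtype={c: "string" for c in ["participant_id", *PREDICTORS]},
        keep_default_na=True,
        na_values=[""],
        float_precision="round_trip",
    )
    extra = [c for c in table.columns if c not in COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"ignoring unknown columns: {extra}", stacklevel=2)
        table = table.drop(columns=extra)
    for col in ["participant_id", *PREDICTORS]:
        if col in table.columns:
            table[col] = table[col].astype(object).where(table[col].notna(), np.nan)
    for col in CONTINUOUS + BINARY:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="raise")
    if validate:
        validate_cohort(table)
    return table[COLUMNS] if all(c in table.columns for c in COLUMNS) else table


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing cells serialise as empty strings."""
    out = table[COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="")
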