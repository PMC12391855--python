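"""Descriptives and causal-assumption diagnostics.

Builds the stratified characteristics table (counts and column percentages
for the whole sample and the timely / late initiation strata) on the
non-imputed cohort, and runs the positivity diagnostic: a logistic propensity
model of early recognition on all thirteen predictors, reported through its
minimum fitted probability.
"""

import json
from pathlib import Path

from ineqshift.cohort import read_cohort_csv
from ineqshift.descriptives import SeparationError, check_positivity, make_table1

OUT = Path("results/analysis")


def main() -> None:
    observed = read_cohort_csv(OUT / "cohort_observed.csv")
    table1 = make_table1(observed)
    table1.to_csv(OUT / "table1.csv", index=False)

    total = table1[table1["stratum"] == "total"]
    early = total[(total["variable"] == "early_recognition") & (total["level"] == "yes")]
    print(f"early recognition among respondents: {early['pct'].iloc[0]:.1f}%")

    try:
        report = check_positivity(observed)
        diag = {"min": report.minimum, "max": report.maximum, "n": report.n,
                "warnings": report.warnings}
        print(f"positivity: minimum propensity {report.minimum:.3f} "
              f"over {report.n} complete cases (assumption satisfied if > 0)")
    except SeparationError as exc:
        diag = {"error": str(exc)}
        print(f"positivity diagnostic unavailable: {exc}")
    with open(OUT / "positivity.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    print(f"wrote {OUT / 'table1.csv'} and {OUT / 'positivity.json'}")


if __name__ == "__main__":
    main()
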