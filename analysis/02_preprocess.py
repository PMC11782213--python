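"""Classify A/T pathology status, summarize demographics, log exclusions.

Reads results/cohort.csv, prints the demographic comparison between
groups (sex imbalance is built into the generator, echoing the cohort's
female excess among controls), and writes the demographics table plus
the exclusion log for the group-comparison analysis set.
"""

import dataclasses
import json
from pathlib import Path

from adcascade.demographics import compare_demographics, demographics_table
from adcascade.preprocess import build_analysis_table
from adcascade.synthetic_cohort import read_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    demo = demographics_table(cohort)
    demo.to_csv(OUT / "demographics.csv", index=False)
    print(demo.to_string(index=False))

    tests = compare_demographics(cohort)
    (OUT / "demographic_tests.json").write_text(
        json.dumps({k: dataclasses.asdict(v) for k, v in tests.items()}, indent=2, sort_keys=True)
    )
    print(f"\nsex-by-group chi-square p = {tests['sex_female_chi2'].p_value:.2e}")
    print(f"age Kruskal-Wallis p = {tests['age_kruskal'].p_value:.3f}")

    at = build_analysis_table(cohort, ["at_group", "gfap"])
    (OUT / "exclusions_group_compare.jsonl").write_text(at.log_as_jsonl() + "\n")
    counts = at.data["at_group"].value_counts()
    print(f"\ngroup-comparison analysis set: N = {at.n}")
    print(counts.to_string())
    discordant = sum("A-/T+" in e["reason"] for e in at.log)
    print(f"discordant A-/T+ DS participants excluded: {discordant}")


if __name__ == "__main__":
    main()
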