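"""Stair-step comparison of plasma GFAP and pTau-217 across A/T groups.

Kruskal-Wallis omnibus, then all pairwise Wilcoxon tests with Bonferroni
correction and Hodges-Lehmann shifts.  The expected picture: controls
and A-/T- DS participants indistinguishable, both plasma markers
elevated once amyloid is positive, highest in A+/T+.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from adcascade.group_compare import compare_by_pathology_group
from adcascade.preprocess import build_analysis_table
from adcascade.synthetic_cohort import read_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(OUT / "cohort.csv")
    for biomarker in ("gfap", "ptau217"):
        at = build_analysis_table(cohort, ["at_group", biomarker])
        report = compare_by_pathology_group(at, biomarker)
        frame = pd.DataFrame([dataclasses.asdict(c) for c in report.pairwise])
        frame.to_csv(OUT / f"comparisons_{biomarker}.csv", index=False)
        print(
            f"\n{biomarker}: omnibus H = {report.omnibus.statistic:.1f}, "
            f"p = {report.omnibus.p_value:.2e} (N = {at.n}, "
            f"Bonferroni family = {report.family_size})"
        )
        for c in report.pairwise:
            shift = -c.hl_shift  # report as second (later-stage) group minus first
            print(
                f"  {c.group_b} - {c.group_a}: shift {shift:8.3f} "
                f"[{-c.hl_ci_high:8.3f}, {-c.hl_ci_low:8.3f}]  adj p = {c.adjusted_p:.3g}"
            )


if __name__ == "__main__":
    main()
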