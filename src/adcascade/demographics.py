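"""Demographic summaries and between-group contingency tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_compare import OmnibusResult, chi_square_2x2, kruskal_wallis
from .synthetic_cohort import GROUP_CONTROL, GROUP_DS


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded to the printed precision of a summary table."""
    if total <= 0:
        raise ValueError("percentage: total must be positive")
    if count < 0 or count > total:
        raise ValueError("percentage: count must be in [0, total]")
    return round(100.0 * count / total, decimals)


def demographics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per group for the standard summary rows."""
    rows = []
    for group in (GROUP_CONTROL, GROUP_DS):
        sub = cohort[cohort["group"] == group]
        n = len(sub)
        entries = {
            "group": group,
            "n": n,
            "age_mean": float(sub["age"].mean()),
            "age_sd": float(sub["age"].std(ddof=1)),
        }
        for name, mask in (
            ("female", sub["sex"] == "female"),
            ("apoe4_positive", sub["apoe4"] == "carrier"),
        ):
            count = int(mask.sum())
            entries[f"{name}_n"] = count
            entries[f"{name}_pct"] = percentage(count, n)
        for modality in ("centiloid", "tau_suvr", "gfap", "ptau217"):
            if modality in sub.columns:
                avail = int(sub[modality].notna().sum())
                entries[f"{modality}_available_n"] = avail
                entries[f"{modality}_available_pct"] = percentage(avail, n)
        rows.append(entries)
    return pd.DataFrame(rows)


def compare_demographics(cohort: pd.DataFrame) -> dict[str, OmnibusResult]:
    """Chi-square tests for sex and APOE e4 by group (with and without
    continuity correction) and a Kruskal-Wallis test for age."""
    results: dict[str, OmnibusResult] = {}
    for name, column, positive in (
        ("sex_female", "sex", "female"),
        ("apoe4", "apoe4", "carrier"),
    ):
        table = []
        for group in (GROUP_CONTROL, GROUP_DS):
            sub = cohort[cohort["group"] == group]
            pos = int((sub[column] == positive).sum())
            table.append([pos, len(sub) - pos])
        table = np.asarray(table)
        results[f"{name}_chi2"] = chi_square_2x2(table, correction=False)
        results[f"{name}_chi2_corrected"] = chi_square_2x2(table, correction=True)
    results["age_kruskal"] = kruskal_wallis(
        [
            cohort.loc[cohort["group"] == g, "age"].dropna().to_numpy()
            for g in (GROUP_CONTROL, GROUP_DS)
        ]
    )
    return results
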