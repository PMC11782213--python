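"""EYO derivation, A/T pathology classification, and analysis-table assembly.

Amyloid positivity is Centiloid > 18 and tau positivity is tau summary
SUVR > 1.3, both strict inequalities.  Sibling controls are never given
A/T labels: they form their own comparison group regardless of their PET
values.  DS participants who are amyloid-negative but tau-positive are
discordant with the amyloid-first cascade and are excluded from
analyses, with every exclusion logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import GROUP_CONTROL, GROUP_DS

AMYLOID_THRESHOLD_CENTILOID = 18.0
TAU_THRESHOLD_SUVR = 1.3
DEFAULT_AAO = 52.5

LABEL_CONTROL = "control"
LABEL_AN_TN = "A-/T-"
LABEL_AP_TN = "A+/T-"
LABEL_AP_TP = "A+/T+"
LABEL_AN_TP = "A-/T+"
LABEL_UNKNOWN = "unknown"

#: ordering used for group comparisons (discordant A-/T+ excluded upstream)
COMPARISON_GROUPS = (LABEL_CONTROL, LABEL_AN_TN, LABEL_AP_TN, LABEL_AP_TP)

#: default FreeSurfer-style composite for Braak stage I/III/IV tau spread:
#: medial temporal (stage I), limbic/fusiform (stage III) and the
#: neocortical temporal extensions (stage IV).  Configurable per call.
BRAAK_134_REGIONS = (
    "entorhinal",
    "parahippocampal",
    "amygdala",
    "fusiform",
    "lingual",
    "inferiortemporal",
    "middletemporal",
    "insula",
    "posteriorcingulate",
    "isthmuscingulate",
)


@dataclass(frozen=True)
class PathologyStatus:
    amyloid: str  # negative / positive / unknown
    tau: str
    combined_label: str


def compute_eyo(age, aao: float = DEFAULT_AAO):
    """Estimated years to symptom onset: ``aao - age`` (scalar or array).

    Positive before the expected onset age, zero at it, negative past it.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr <= 0):
        raise ValueError("compute_eyo: age must be positive")
    eyo = aao - age_arr
    return eyo if eyo.ndim else float(eyo)


def _marker_status(value, threshold: float) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    return "positive" if value > threshold else "negative"


def classify_at_status(
    centiloid,
    tau_suvr,
    group: str,
    centiloid_threshold: float = AMYLOID_THRESHOLD_CENTILOID,
    tau_threshold: float = TAU_THRESHOLD_SUVR,
) -> PathologyStatus:
    """A/T status for one participant; missing values map to ``unknown``.

    Controls always get the combined label ``control`` (their per-marker
    statuses are still computed for reference curves and logging).
    """
    amyloid = _marker_status(centiloid, centiloid_threshold)
    tau = _marker_status(tau_suvr, tau_threshold)
    if group == GROUP_CONTROL:
        combined = LABEL_CONTROL
    elif amyloid == "unknown" or tau == "unknown":
        combined = LABEL_UNKNOWN
    else:
        combined = {
            ("negative", "negative"): LABEL_AN_TN,
            ("positive", "negative"): LABEL_AP_TN,
            ("positive", "positive"): LABEL_AP_TP,
            ("negative", "positive"): LABEL_AN_TP,
        }[(amyloid, tau)]
    return PathologyStatus(amyloid=amyloid, tau=tau, combined_label=combined)


def tau_summary_suvr(
    regional_suvrs: Mapping[str, float], region_set: Sequence[str] = BRAAK_134_REGIONS
) -> float:
    """Unweighted mean SUVR over the composite region set.

    Raises ``KeyError`` naming the first region absent from the input.
    """
    values = []
    for region in region_set:
        if region not in regional_suvrs:
            raise KeyError(f"tau_summary_suvr: region {region!r} missing from input")
        values.append(float(regional_suvrs[region]))
    return float(np.mean(values))


def add_derived_columns(
    cohort: pd.DataFrame,
    aao: float = DEFAULT_AAO,
    centiloid_threshold: float = AMYLOID_THRESHOLD_CENTILOID,
    tau_threshold: float = TAU_THRESHOLD_SUVR,
) -> pd.DataFrame:
    """Return a copy with EYO, numeric covariates and A/T status columns."""
    out = cohort.copy()
    out["eyo"] = compute_eyo(out["age"].to_numpy(), aao=aao)
    if "sex" in out.columns:
        out["sex_female"] = (out["sex"] == "female").astype(int)
    if "apoe4" in out.columns and out["apoe4"].dtype == object:
        out["apoe4_carrier"] = (out["apoe4"] == "carrier").astype(int)

    centiloid = out["centiloid"] if "centiloid" in out.columns else pd.Series(np.nan, index=out.index)
    tau = out["tau_suvr"] if "tau_suvr" in out.columns else pd.Series(np.nan, index=out.index)
    statuses = [
        classify_at_status(c, t, g, centiloid_threshold, tau_threshold)
        for c, t, g in zip(centiloid, tau, out["group"])
    ]
    out["amyloid_status"] = [s.amyloid for s in statuses]
    out["tau_status"] = [s.tau for s in statuses]
    out["at_group"] = [s.combined_label for s in statuses]
    return out


@dataclass
class AnalysisTable:
    """Rows ready for one analysis plus a provenance log of every drop."""

    data: pd.DataFrame
    log: list[dict] = field(default_factory=list)
    required_variables: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.data)

    def log_as_jsonl(self) -> str:
        import json

        return "\n".join(json.dumps(entry, sort_keys=True) for entry in self.log)


def build_analysis_table(
    cohort: pd.DataFrame,
    required_variables: Iterable[str],
    aao: float = DEFAULT_AAO,
    centiloid_threshold: float = AMYLOID_THRESHOLD_CENTILOID,
    tau_threshold: float = TAU_THRESHOLD_SUVR,
    exclude_discordant: bool = True,
) -> AnalysisTable:
    """Derive statuses, apply exclusion rules and complete-case filtering.

    ``required_variables`` are the columns this particular analysis
    needs; rows missing any of them are dropped and logged.  Requiring
    ``at_group`` additionally drops DS rows whose A/T status cannot be
    determined.  Complete-case filtering is per-analysis by design: the
    same participant can contribute to group comparisons but not to
    mediation.
    """
    required = tuple(required_variables)
    table = add_derived_columns(
        cohort, aao=aao, centiloid_threshold=centiloid_threshold, tau_threshold=tau_threshold
    )
    log: list[dict] = []

    if exclude_discordant:
        discordant = table["at_group"] == LABEL_AN_TP
        for pid in table.loc[discordant, "participant_id"]:
            log.append(
                {"participant_id": str(pid), "reason": "discordant A-/T+ excluded"}
            )
        table = table.loc[~discordant]

    keep = pd.Series(True, index=table.index)
    for column in required:
        if column not in table.columns:
            raise ValueError(f"build_analysis_table: required column {column!r} absent")
        if column == "at_group":
            bad = table[column] == LABEL_UNKNOWN
        else:
            bad = table[column].isna()
        keep &= ~bad
    dropped = table.loc[~keep]
    for _, row in dropped.iterrows():
        missing_cols = [
            c
            for c in required
            if (row[c] == LABEL_UNKNOWN if c == "at_group" else pd.isna(row[c]))
        ]
        log.append(
            {
                "participant_id": str(row["participant_id"]),
                "reason": "incomplete: missing " + ", ".join(missing_cols),
            }
        )
    table = table.loc[keep].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("build_analysis_table: no rows remain after filtering")
    return AnalysisTable(data=table, log=log, required_variables=required)
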