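"""Seeded synthetic Down's-syndrome / sibling-control cohorts.

The generator encodes the causal structure that the downstream analyses
assume: amyloid PET burden (Centiloid) accumulates along a sigmoid in
estimated years to symptom onset (EYO) for participants with DS, plasma
GFAP responds to amyloid (the mediator path ``a``), and tau PET SUVR /
plasma pTau-217 respond both to amyloid directly (``c_prime``) and to
GFAP (``b``).  Sibling controls are age-flat: every biomarker is drawn
around its pre-pathology floor.  Sex imbalance between groups, APOE e4
carriage, inter-measurement latency, and per-modality missing-at-random
data complete the picture, so every pipeline stage can be exercised and
calibrated against a known ground truth.

EYO convention: EYO = AAO - age, so EYO counts *down* toward 0 at the
expected age of symptom onset (52.5 years by default) and is negative
past onset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

GROUP_DS = "DS"
GROUP_CONTROL = "control"
GROUPS = (GROUP_DS, GROUP_CONTROL)

#: biomarker columns, also the modalities that can go missing independently
BIOMARKERS = ("centiloid", "gfap", "ptau217", "tau_suvr")

#: covariate keys accepted in ``covariate_effects`` mappings
COVARIATE_KEYS = ("sex_female", "apoe4", "latency_days")

COHORT_COLUMNS = (
    "participant_id",
    "group",
    "age",
    "sex",
    "apoe4",
    "latency_days",
    "centiloid",
    "gfap",
    "ptau217",
    "tau_suvr",
)


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class TrajectoryParams:
    """Sigmoidal mean trajectory of one biomarker against EYO.

    ``floor`` is the pre-pathology mean (also the control-group mean),
    ``amplitude`` the asymptotic rise, ``midpoint_eyo`` the EYO at
    half-rise, ``rate`` the sigmoid steepness in 1/years, and
    ``noise_sd`` the additive Gaussian measurement noise.
    """

    floor: float
    amplitude: float
    midpoint_eyo: float
    rate: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("TrajectoryParams.amplitude must be >= 0")
        if self.rate <= 0:
            raise ConfigError("TrajectoryParams.rate must be > 0")
        if self.noise_sd <= 0:
            raise ConfigError("TrajectoryParams.noise_sd must be > 0")


@dataclass(frozen=True)
class MediationStructure:
    """Linear mediation triangle amyloid -> GFAP -> outcome.

    ``a`` is the mediator response per treatment unit (pg/mL GFAP per
    Centiloid), ``b`` the outcome response per mediator unit, and
    ``c_prime`` the direct amyloid -> outcome path.  Covariate effects
    are additive linear contributions keyed by :data:`COVARIATE_KEYS`.
    """

    a: float
    b: float
    c_prime: float
    mediator_noise_sd: float
    outcome_noise_sd: float
    covariate_effects_mediator: Mapping[str, float] = field(default_factory=dict)
    covariate_effects_outcome: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mediator_noise_sd <= 0:
            raise ConfigError("MediationStructure.mediator_noise_sd must be > 0")
        if self.outcome_noise_sd <= 0:
            raise ConfigError("MediationStructure.outcome_noise_sd must be > 0")
        for mapping_name in ("covariate_effects_mediator", "covariate_effects_outcome"):
            for key in getattr(self, mapping_name):
                if key not in COVARIATE_KEYS:
                    raise ConfigError(
                        f"MediationStructure.{mapping_name}: unknown covariate {key!r}"
                    )


def true_proportion_mediated(structure: MediationStructure) -> float:
    """Ground-truth proportion mediated a*b / (c' + a*b).

    Raises
    ------
    ValueError
        If the total effect ``c_prime + a*b`` is zero, in which case the
        proportion is undefined.
    """
    indirect = structure.a * structure.b
    total = structure.c_prime + indirect
    if abs(total) < 1e-12:
        raise ValueError(
            "proportion mediated is undefined: total effect c_prime + a*b is zero"
        )
    return indirect / total


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort draw."""

    n_ds: int
    n_controls: int
    seed: int
    age_range: tuple[float, float] = (25.0, 65.0)
    aao: float = 52.5
    trajectories: Mapping[str, TrajectoryParams] = field(default_factory=dict)
    mediation: Mapping[str, MediationStructure] = field(default_factory=dict)
    #: probability that a participant is female, per group
    sex_prob: Mapping[str, float] = field(
        default_factory=lambda: {GROUP_CONTROL: 0.786, GROUP_DS: 0.451}
    )
    apoe4_prob: float = 0.236
    latency_days_range: tuple[int, int] = (0, 540)
    #: per-group, per-modality probability that a measurement is missing
    missingness: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_ds <= 0:
            raise ConfigError("CohortConfig.n_ds must be > 0")
        if self.n_controls <= 0:
            raise ConfigError("CohortConfig.n_controls must be > 0")
        if not self.age_range[0] < self.age_range[1] or self.age_range[0] <= 0:
            raise ConfigError("CohortConfig.age_range must be increasing and positive")
        for name in BIOMARKERS:
            if name not in self.trajectories:
                raise ConfigError(f"CohortConfig.trajectories missing {name!r}")
        for outcome in ("tau_suvr", "ptau217"):
            if outcome not in self.mediation:
                raise ConfigError(f"CohortConfig.mediation missing outcome {outcome!r}")
        med_tau = self.mediation["tau_suvr"]
        med_ptau = self.mediation["ptau217"]
        # GFAP is generated once, so the mediator model must be shared
        if med_tau.a != med_ptau.a:
            raise ConfigError("CohortConfig.mediation: path 'a' must match across outcomes")
        if med_tau.mediator_noise_sd != med_ptau.mediator_noise_sd:
            raise ConfigError(
                "CohortConfig.mediation: mediator_noise_sd must match across outcomes"
            )
        if med_tau.covariate_effects_mediator != med_ptau.covariate_effects_mediator:
            raise ConfigError(
                "CohortConfig.mediation: covariate_effects_mediator must match across outcomes"
            )
        for group, p in self.sex_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"CohortConfig.sex_prob[{group!r}] must be in [0, 1]")
        if not 0.0 <= self.apoe4_prob <= 1.0:
            raise ConfigError("CohortConfig.apoe4_prob must be in [0, 1]")
        if not 0 <= self.latency_days_range[0] <= self.latency_days_range[1]:
            raise ConfigError("CohortConfig.latency_days_range must be 0 <= lo <= hi")
        for group, fractions in self.missingness.items():
            if group not in GROUPS:
                raise ConfigError(f"CohortConfig.missingness: unknown group {group!r}")
            for modality, frac in fractions.items():
                if modality not in BIOMARKERS:
                    raise ConfigError(
                        f"CohortConfig.missingness[{group!r}]: unknown modality {modality!r}"
                    )
                if not 0.0 <= frac <= 1.0:
                    raise ConfigError(
                        f"CohortConfig.missingness[{group!r}][{modality!r}] must be in [0, 1]"
                    )


def default_config(seed: int = 0, n_ds: int = 348, n_controls: int = 42) -> CohortConfig:
    """Default study conditions.

    Cohort sizes, sex split, APOE e4 prevalence and per-modality
    availability follow the DS-cohort demographics the pipeline is
    designed around; trajectory and mediation parameters are plausible
    magnitudes on each assay's scale, with the mediated fractions set to
    0.153 (tau PET outcome) and 0.421 (pTau-217 outcome).
    """
    trajectories = {
        # Centiloid: near zero until the late 30s, midpoint at EYO 6 (age 46.5)
        "centiloid": TrajectoryParams(
            floor=3.0, amplitude=90.0, midpoint_eyo=6.0, rate=0.30, noise_sd=12.0
        ),
        # downstream markers: sigmoid fields other than floor/noise are unused
        # for DS draws (their DS means derive from amyloid via the mediation
        # structure); floor and noise_sd define the control distributions
        "gfap": TrajectoryParams(
            floor=130.0, amplitude=0.0, midpoint_eyo=5.0, rate=0.35, noise_sd=45.0
        ),
        "ptau217": TrajectoryParams(
            floor=0.15, amplitude=0.0, midpoint_eyo=5.0, rate=0.35, noise_sd=0.07
        ),
        # tau floor sits well under the 1.3 positivity cutoff and the total
        # amyloid->tau slope is gentle, so tau positivity lags amyloid
        # positivity (the compressed-but-ordered cascade)
        "tau_suvr": TrajectoryParams(
            floor=1.05, amplitude=0.0, midpoint_eyo=5.0, rate=0.35, noise_sd=0.13
        ),
    }
    shared_mediator_effects = {"sex_female": 8.0, "apoe4": 5.0}
    mediation = {
        # a*b / (c' + a*b) = 0.000612 / 0.004 = 0.153
        "tau_suvr": MediationStructure(
            a=1.5,
            b=0.000408,
            c_prime=0.003388,
            mediator_noise_sd=45.0,
            outcome_noise_sd=0.13,
            covariate_effects_mediator=shared_mediator_effects,
            covariate_effects_outcome={"apoe4": 0.02},
        ),
        # a*b / (c' + a*b) = 0.003 / 0.007126 = 0.421
        "ptau217": MediationStructure(
            a=1.5,
            b=0.002,
            c_prime=0.004126,
            mediator_noise_sd=45.0,
            outcome_noise_sd=0.07,
            covariate_effects_mediator=shared_mediator_effects,
            covariate_effects_outcome={"apoe4": 0.005},
        ),
    }
    missingness = {
        # availability as in the study demographics: DS 211/348 amyloid PET,
        # 158/348 tau PET, 302/348 plasma; controls 34/42, 37/42, 37/42
        GROUP_DS: {
            "centiloid": 137 / 348,
            "tau_suvr": 190 / 348,
            "gfap": 46 / 348,
            "ptau217": 46 / 348,
        },
        GROUP_CONTROL: {
            "centiloid": 8 / 42,
            "tau_suvr": 5 / 42,
            "gfap": 5 / 42,
            "ptau217": 5 / 42,
        },
    }
    return CohortConfig(
        n_ds=n_ds,
        n_controls=n_controls,
        seed=seed,
        trajectories=trajectories,
        mediation=mediation,
        missingness=missingness,
    )


def null_config(seed: int = 0, n_ds: int = 348, n_controls: int = 42) -> CohortConfig:
    """Null study conditions: flat trajectories, zeroed mediation paths,
    no covariate effects, no sex imbalance, no missingness.

    Under this configuration DS and control biomarker distributions are
    identical in law, so any downstream p-value must be uniform.
    """
    base = default_config(seed=seed, n_ds=n_ds, n_controls=n_controls)
    flat = {
        name: dataclasses.replace(tp, amplitude=0.0)
        for name, tp in base.trajectories.items()
    }
    null_med = {
        outcome: dataclasses.replace(
            structure,
            a=0.0,
            b=0.0,
            c_prime=0.0,
            covariate_effects_mediator={},
            covariate_effects_outcome={},
        )
        for outcome, structure in base.mediation.items()
    }
    return dataclasses.replace(
        base,
        trajectories=flat,
        mediation=null_med,
        sex_prob={GROUP_CONTROL: 0.5, GROUP_DS: 0.5},
        missingness={},
    )


def sigmoid_mean(eyo, params: TrajectoryParams):
    """Mean biomarker level at a given EYO.

    ``floor + amplitude / (1 + exp(-rate * (midpoint_eyo - eyo)))``:
    rises as EYO counts down toward (and past) onset at 0, strictly
    monotone in EYO whenever ``amplitude > 0``.
    """
    eyo = np.asarray(eyo, dtype=float)
    value = params.floor + params.amplitude / (
        1.0 + np.exp(-params.rate * (params.midpoint_eyo - eyo))
    )
    return value if value.ndim else float(value)


def apply_missingness(
    table: pd.DataFrame, fractions: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Mark biomarker cells missing completely at random, per modality.

    Each modality is masked independently per participant at its
    configured rate.  Rows are never removed; the input is not mutated.
    """
    for modality, frac in fractions.items():
        if modality not in BIOMARKERS:
            raise ConfigError(f"apply_missingness: unknown modality {modality!r}")
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"apply_missingness: fraction for {modality!r} not in [0, 1]")
    out = table.copy()
    rng = np.random.default_rng(seed)
    for modality in BIOMARKERS:
        frac = fractions.get(modality, 0.0)
        if frac == 0.0:
            continue
        mask = rng.random(len(out)) < frac
        out.loc[mask, modality] = np.nan
    return out


def _covariate_contribution(effects: Mapping[str, float], covariates: Mapping[str, np.ndarray]):
    total = 0.0
    for key, coef in effects.items():
        total = total + coef * covariates[key]
    return total


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort and its ground-truth sidecar.

    Controls draw every biomarker around its floor (no age dependence);
    DS participants draw latent amyloid from the sigmoid at their EYO,
    then GFAP from the mediator model, then both outcomes from the
    outcome models.  Identical config (including seed) gives
    byte-identical output.  The sidecar records every generative
    parameter plus the true proportion mediated per outcome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    med_shared = config.mediation["tau_suvr"]  # mediator path shared across outcomes

    frames = []
    for group, n, prefix in (
        (GROUP_DS, config.n_ds, "DS"),
        (GROUP_CONTROL, config.n_controls, "C"),
    ):
        age = rng.uniform(config.age_range[0], config.age_range[1], n)
        sex_female = (rng.random(n) < config.sex_prob[group]).astype(int)
        apoe4 = (rng.random(n) < config.apoe4_prob).astype(int)
        latency = rng.integers(
            config.latency_days_range[0], config.latency_days_range[1] + 1, n
        )
        covs = {
            "sex_female": sex_female.astype(float),
            "apoe4": apoe4.astype(float),
            "latency_days": latency.astype(float),
        }

        tp = config.trajectories
        if group == GROUP_DS:
            eyo = config.aao - age
            amyloid = sigmoid_mean(eyo, tp["centiloid"]) + rng.normal(
                0.0, tp["centiloid"].noise_sd, n
            )
            delta_a = amyloid - tp["centiloid"].floor
            gfap = (
                tp["gfap"].floor
                + med_shared.a * delta_a
                + _covariate_contribution(med_shared.covariate_effects_mediator, covs)
                + rng.normal(0.0, med_shared.mediator_noise_sd, n)
            )
            gfap = np.clip(gfap, 0.0, None)  # concentrations cannot be negative
            delta_m = gfap - tp["gfap"].floor
            outcomes = {}
            for name in ("tau_suvr", "ptau217"):
                s = config.mediation[name]
                outcomes[name] = (
                    tp[name].floor
                    + s.c_prime * delta_a
                    + s.b * delta_m
                    + _covariate_contribution(s.covariate_effects_outcome, covs)
                    + rng.normal(0.0, s.outcome_noise_sd, n)
                )
            tau_suvr = outcomes["tau_suvr"]
            ptau217 = np.clip(outcomes["ptau217"], 0.0, None)
        else:
            amyloid = tp["centiloid"].floor + rng.normal(0.0, tp["centiloid"].noise_sd, n)
            gfap = (
                tp["gfap"].floor
                + _covariate_contribution(med_shared.covariate_effects_mediator, covs)
                + rng.normal(0.0, tp["gfap"].noise_sd, n)
            )
            gfap = np.clip(gfap, 0.0, None)
            tau_suvr = (
                tp["tau_suvr"].floor
                + _covariate_contribution(
                    config.mediation["tau_suvr"].covariate_effects_outcome, covs
                )
                + rng.normal(0.0, tp["tau_suvr"].noise_sd, n)
            )
            ptau217 = np.clip(
                tp["ptau217"].floor
                + _covariate_contribution(
                    config.mediation["ptau217"].covariate_effects_outcome, covs
                )
                + rng.normal(0.0, tp["ptau217"].noise_sd, n),
                0.0,
                None,
            )

        frame = pd.DataFrame(
            {
                "participant_id": [f"{prefix}-{i + 1:04d}" for i in range(n)],
                "group": group,
                "age": age,
                "sex": np.where(sex_female == 1, "female", "male"),
                "apoe4": np.where(apoe4 == 1, "carrier", "non-carrier"),
                "latency_days": latency,
                "centiloid": amyloid,
                "gfap": gfap,
                "ptau217": ptau217,
                "tau_suvr": tau_suvr,
            }
        )
        fractions = config.missingness.get(group, {})
        if fractions:
            frame = apply_missingness(frame, fractions, seed=int(rng.integers(2**31)))
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)[list(COHORT_COLUMNS)]
    sidecar = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "true_proportion_mediated": {
            outcome: true_proportion_mediated(structure)
            if abs(structure.c_prime + structure.a * structure.b) >= 1e-12
            else None
            for outcome, structure in config.mediation.items()
        },
        "n_ds": config.n_ds,
        "n_controls": config.n_controls,
    }
    return cohort, sidecar


def write_cohort(cohort: pd.DataFrame, sidecar: dict, csv_path, sidecar_path=None) -> None:
    """Write the cohort CSV (missing cells empty) and its JSON sidecar."""
    csv_path = Path(csv_path)
    cohort.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".truth.json")
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_cohort(csv_path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made to
    the same schema); empty biomarker cells become NaN."""
    cohort = pd.read_csv(csv_path)
    missing = [c for c in ("participant_id", "group", "age") if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    for column in BIOMARKERS:
        if column in cohort.columns:
            cohort[column] = pd.to_numeric(cohort[column], errors="coerce")
    return cohort
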