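"""Shared fixtures: small cohorts and purpose-built generator configs."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from adcascade.synthetic_cohort import (
    CohortConfig,
    TrajectoryParams,
    default_config,
    generate_cohort,
)


def encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["sex_female"] = (out["sex"] == "female").astype(int)
    out["apoe4_carrier"] = (out["apoe4"] == "carrier").astype(int)
    return out


def steep_amyloid_config(seed: int, n_ds: int = 348, n_controls: int = 42) -> CohortConfig:
    """Sharply rising amyloid trajectory with no missing data.

    The steep rate makes the first-crossing age nearly insensitive to
    the detection threshold, so the divergence age is a well-defined
    estimand that dense-cohort and study-scale runs must agree on.
    """
    base = default_config(seed=seed, n_ds=n_ds, n_controls=n_controls)
    traj = dict(base.trajectories)
    traj["centiloid"] = TrajectoryParams(
        floor=3.0, amplitude=100.0, midpoint_eyo=6.0, rate=2.0, noise_sd=10.0
    )
    return dataclasses.replace(base, trajectories=traj, missingness={})


def mediation_recovery_config(
    seed: int, a: float, b: float, c_prime: float, n_ds: int = 500
) -> CohortConfig:
    """Cohort with configured mediation paths, moderate noise, no
    covariate effects and no missingness, for parameter-recovery runs."""
    base = default_config(seed=seed, n_ds=n_ds, n_controls=10)
    med = {
        outcome: dataclasses.replace(
            s,
            a=a,
            b=b,
            c_prime=c_prime,
            mediator_noise_sd=15.0,
            outcome_noise_sd=15.0,
            covariate_effects_mediator={},
            covariate_effects_outcome={},
        )
        for outcome, s in base.mediation.items()
    }
    return dataclasses.replace(base, mediation=med, missingness={})


@pytest.fixture(scope="session")
def default_cohort():
    cohort, sidecar = generate_cohort(default_config(seed=1))
    return cohort, sidecar


@pytest.fixture(scope="session")
def small_complete_cohort():
    """120 DS / 40 controls, default structure but no missing data."""
    config = dataclasses.replace(
        default_config(seed=5, n_ds=120, n_controls=40), missingness={}
    )
    cohort, _ = generate_cohort(config)
    return cohort
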