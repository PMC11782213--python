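"""Bootstrap estimation of the age at which a DS biomarker curve
diverges from the sibling-control curve, and pairwise comparisons of
divergence timing between biomarkers.

For each bootstrap replicate, participants are resampled with
replacement within group, both penalized-spline curves are refit (with
knots and smoothing parameter frozen at their full-sample values, the
usual bootstrap-of-a-smoother convention), and the DS - control
difference is evaluated on an age grid.

Two detection rules operate side by side:

* cohort level: the divergence age is the smallest grid age at which
  the pointwise bootstrap percentile interval of the difference lies
  strictly above zero there and at every older age (sustained
  exceedance);
* replicate level: a replicate detects at the smallest grid age where
  its own difference minus z * (model-based pointwise SE of the
  difference) stays positive through the end of the grid.  The
  replicate-level ages give the confidence interval for the divergence
  age and the detection fraction, and the SE margin keeps false
  detection at the nominal level under the null.

Ages are modelled internally on the age axis; the EYO axis is a pure
relabelling (EYO = AAO - age), available for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import DEFAULT_AAO
from .splines import CubicSplineBasis, fit_penalized_spline
from .synthetic_cohort import GROUP_CONTROL, GROUP_DS


@dataclass
class DivergenceResult:
    biomarker: str
    axis: str
    divergence_age: float | None
    ci_low: float | None
    ci_high: float | None
    n_bootstrap: int
    detection_fraction: float
    bootstrap_ages: np.ndarray  # per-replicate first-detection age; NaN = none
    grid: np.ndarray
    ds_curve: np.ndarray
    control_curve: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    seed: int
    n_ds: int
    n_controls: int
    alpha: float = 0.05
    failed_replicates: int = 0


@dataclass
class TimingComparison:
    biomarker_a: str
    biomarker_b: str
    p_value: float
    n_used: int
    dropped_fraction: float
    mean_difference: float
    paired: bool
    differences: np.ndarray = field(repr=False, default=None)


def _sustained_first_index(values: np.ndarray) -> int | None:
    """Smallest index i such that values[j] > 0 for all j >= i."""
    positive = values > 0
    if not positive[-1]:
        return None
    # suffix of consecutive True from the end
    run = 0
    for flag in positive[::-1]:
        if flag:
            run += 1
        else:
            break
    return len(values) - run


def _adjust_for_covariates(data: pd.DataFrame, biomarker: str) -> np.ndarray:
    """Residualize the biomarker on linear covariate terms (latency, sex,
    APOE), keeping the group contrast intact by including a group
    indicator in the adjustment model."""
    y = data[biomarker].to_numpy(dtype=float)
    cols = [c for c in ("latency_days", "sex_female", "apoe4_carrier") if c in data.columns]
    if not cols:
        return y
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[c].to_numpy(dtype=float) for c in cols]
        + [(data["group"] == GROUP_DS).to_numpy(dtype=float)]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    covariate_part = X[:, 1 : 1 + len(cols)] @ beta[1 : 1 + len(cols)]
    return y - (covariate_part - covariate_part.mean())


def estimate_divergence_age(
    cohort: pd.DataFrame,
    biomarker: str,
    axis: str = "age",
    n_bootstrap: int = 10_000,
    alpha: float = 0.05,
    grid_step: float = 0.1,
    k: int = 10,
    seed: int = 0,
    aao: float = DEFAULT_AAO,
    adjust: bool = False,
    min_detection: float = 0.5,
) -> DivergenceResult:
    """Earliest age of sustained DS-over-control elevation for one biomarker.

    ``cohort`` needs columns group, age and the biomarker (plus numeric
    covariates when ``adjust=True``).  Returns no divergence age when
    the band rule never fires or fewer than ``min_detection`` of the
    replicates detect.
    """
    if axis not in ("age", "eyo"):
        raise ValueError("estimate_divergence_age: axis must be 'age' or 'eyo'")
    data = cohort.dropna(subset=["age", biomarker]).reset_index(drop=True)
    y_all = _adjust_for_covariates(data, biomarker) if adjust else data[biomarker].to_numpy(float)

    groups = {}
    for label in (GROUP_DS, GROUP_CONTROL):
        mask = (data["group"] == label).to_numpy()
        x = data.loc[mask, "age"].to_numpy(dtype=float)
        y = y_all[mask]
        if len(np.unique(x)) < k:
            raise ValueError(
                f"estimate_divergence_age: group {label!r} has fewer than k={k} distinct ages"
            )
        groups[label] = (x, y)

    fits = {}
    designs = {}
    for label, (x, y) in groups.items():
        fit = fit_penalized_spline(x, y, k=k, lam="gcv")
        fits[label] = fit
        designs[label] = fit.basis.design(x)

    lo = max(groups[GROUP_DS][0].min(), groups[GROUP_CONTROL][0].min())
    hi = min(groups[GROUP_DS][0].max(), groups[GROUP_CONTROL][0].max())
    grid = np.arange(lo, hi + grid_step / 2.0, grid_step)
    Bg = {label: fits[label].basis.design(grid) for label in fits}

    rng = np.random.default_rng(seed)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n_grid = len(grid)
    diff_boot = np.empty((n_bootstrap, n_grid))
    rep_ages = np.full(n_bootstrap, np.nan)
    failed = 0

    penalties = {label: fits[label].basis.penalty for label in fits}
    for b in range(n_bootstrap):
        curves = {}
        variances = {}
        ok = True
        for label in (GROUP_DS, GROUP_CONTROL):
            x, y = groups[label]
            n = len(x)
            idx = rng.integers(0, n, n)
            Bb = designs[label][idx]
            yb = y[idx]
            btb = Bb.T @ Bb
            C = btb + fits[label].lam * penalties[label]
            try:
                inv = np.linalg.inv(C)
            except np.linalg.LinAlgError:
                ok = False
                break
            coef = inv @ (Bb.T @ yb)
            edf = float(np.trace(inv @ btb))
            rss = float(np.sum((yb - Bb @ coef) ** 2))
            sigma2 = rss / (n - edf) if n - edf > 1e-8 else 0.0
            M = inv @ btb @ inv
            curves[label] = Bg[label] @ coef
            variances[label] = sigma2 * np.einsum(
                "ij,jk,ik->i", Bg[label], M, Bg[label]
            )
        if not ok:
            failed += 1
            diff_boot[b] = np.nan
            continue
        diff = curves[GROUP_DS] - curves[GROUP_CONTROL]
        diff_boot[b] = diff
        margin = z * np.sqrt(
            np.clip(variances[GROUP_DS] + variances[GROUP_CONTROL], 0.0, None)
        )
        idx_detect = _sustained_first_index(diff - margin)
        if idx_detect is not None:
            rep_ages[b] = grid[idx_detect]

    valid = ~np.isnan(diff_boot).any(axis=1)
    band_low = np.nanquantile(diff_boot[valid], alpha / 2.0, axis=0)
    band_high = np.nanquantile(diff_boot[valid], 1.0 - alpha / 2.0, axis=0)
    band_idx = _sustained_first_index(band_low)
    detection_fraction = float(np.mean(~np.isnan(rep_ages[valid]))) if valid.any() else 0.0

    divergence = None
    if band_idx is not None and detection_fraction >= min_detection:
        divergence = float(grid[band_idx])

    detected = rep_ages[~np.isnan(rep_ages)]
    if len(detected) > 0:
        ci_low, ci_high = np.quantile(detected, [alpha / 2.0, 1.0 - alpha / 2.0])
        ci_low, ci_high = float(ci_low), float(ci_high)
    else:
        ci_low = ci_high = None

    ds_curve = fits[GROUP_DS].predict(grid).mean
    control_curve = fits[GROUP_CONTROL].predict(grid).mean

    result = DivergenceResult(
        biomarker=biomarker,
        axis="age",
        divergence_age=divergence,
        ci_low=ci_low,
        ci_high=ci_high,
        n_bootstrap=n_bootstrap,
        detection_fraction=detection_fraction,
        bootstrap_ages=rep_ages,
        grid=grid,
        ds_curve=ds_curve,
        control_curve=control_curve,
        band_low=band_low,
        band_high=band_high,
        seed=seed,
        n_ds=len(groups[GROUP_DS][0]),
        n_controls=len(groups[GROUP_CONTROL][0]),
        alpha=alpha,
        failed_replicates=failed,
    )
    if axis == "eyo":
        result = _relabel_to_eyo(result, aao)
    return result


def _relabel_to_eyo(result: DivergenceResult, aao: float) -> DivergenceResult:
    """EYO = AAO - age: flips the axis direction, so CI bounds swap."""
    conv = lambda v: None if v is None else aao - v
    return DivergenceResult(
        biomarker=result.biomarker,
        axis="eyo",
        divergence_age=conv(result.divergence_age),
        ci_low=conv(result.ci_high),
        ci_high=conv(result.ci_low),
        n_bootstrap=result.n_bootstrap,
        detection_fraction=result.detection_fraction,
        bootstrap_ages=aao - result.bootstrap_ages,
        grid=(aao - result.grid)[::-1],
        ds_curve=result.ds_curve[::-1],
        control_curve=result.control_curve[::-1],
        band_low=result.band_low[::-1],
        band_high=result.band_high[::-1],
        seed=result.seed,
        n_ds=result.n_ds,
        n_controls=result.n_controls,
        alpha=result.alpha,
        failed_replicates=result.failed_replicates,
    )


def compare_divergence_timing(
    result_a: DivergenceResult, result_b: DivergenceResult
) -> TimingComparison:
    """Two-sided bootstrap p-value for a difference in divergence timing.

    Replicates are paired by replicate index (shared seeds give paired
    resampling); replicates where either biomarker did not detect are
    dropped, with the dropped fraction reported.
    """
    if result_a.axis != result_b.axis:
        raise ValueError("compare_divergence_timing: results use different axes")
    if result_a.n_bootstrap != result_b.n_bootstrap:
        raise ValueError("compare_divergence_timing: replicate counts differ")
    if result_a.detection_fraction < 0.5 and result_b.detection_fraction < 0.5:
        raise ValueError(
            "compare_divergence_timing: both biomarkers undetected in >50% of replicates"
        )
    a = result_a.bootstrap_ages
    b = result_b.bootstrap_ages
    both = ~np.isnan(a) & ~np.isnan(b)
    if not both.any():
        raise ValueError("compare_divergence_timing: no replicate detected both biomarkers")
    deltas = a[both] - b[both]
    n = len(deltas)
    frac_le = np.mean(deltas <= 0)
    frac_ge = np.mean(deltas >= 0)
    p = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / result_a.n_bootstrap))
    return TimingComparison(
        biomarker_a=result_a.biomarker,
        biomarker_b=result_b.biomarker,
        p_value=float(p),
        n_used=n,
        dropped_fraction=float(1.0 - n / result_a.n_bootstrap),
        mean_difference=float(np.mean(deltas)),
        paired=result_a.seed == result_b.seed,
        differences=deltas,
    )
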