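# Methods

## Scientific setting

Adults with Down's syndrome (DS) develop Alzheimer's pathology early and
on a compressed timeline. The pipeline asks two questions of a
cross-sectional DS / sibling-control cohort with amyloid PET (Centiloid),
tau PET (Braak I/III/IV composite SUVR), plasma GFAP and plasma pTau-217:

* **When** does each biomarker in DS participants first exceed the
  control level, as a function of age (or estimated years to symptom
  onset, EYO)?
* **How much** of the amyloid–tau association is carried by astrogliosis,
  indexed by plasma GFAP?

## Synthetic cohort generator

Real cohort data are gated behind a data-request process, so the package
generates cohorts with the causal structure the analyses assume. For DS
participants, latent amyloid follows a four-parameter sigmoid in EYO,

    A(eyo) = floor + amplitude / (1 + exp(-rate * (midpoint_eyo - eyo)))

with additive Gaussian noise; GFAP responds linearly to amyloid
(`a` pg/mL per Centiloid), and each outcome (tau SUVR, pTau-217) responds
to amyloid directly (`c'`) and to GFAP (`b`), plus linear covariate
effects and noise. Controls draw every biomarker around its floor with no
age dependence. Concentrations are truncated at zero.

**EYO sign convention.** EYO = AAO − age with AAO = 52.5 years, so EYO
counts *down* toward 0 at expected onset and is negative afterwards.
(Other staging literatures use the opposite sign; all internal code uses
this one, and the reporting layer can relabel age ↔ EYO.)

Defaults (chosen once, for plausibility on each assay's scale):

| quantity | value | note |
|---|---|---|
| n (DS / controls) | 348 / 42 | study scale |
| ages | uniform 25–65 y | covers the divergence window |
| amyloid | floor 3, amplitude 90 CL, midpoint EYO 6, rate 0.30/y, noise 12 | positivity (>18 CL) from the early 40s |
| GFAP | floor 130 pg/mL, a = 1.5 pg/mL per CL, noise 45 | ≈135 pg/mL asymptotic rise |
| tau SUVR | floor 1.05, total slope 0.004/CL, noise 0.13 | positivity (>1.3) lags amyloid positivity |
| pTau-217 | floor 0.15 pg/mL, total slope ≈0.0071/CL, noise 0.07 | strong signal, early divergence |
| mediated fraction | 0.153 (tau PET), 0.421 (pTau-217) | b and c′ solve a·b/(c′+a·b) exactly |
| sex (female) | 78.6% controls / 45.1% DS | the cohort's sex imbalance |
| APOE ε4 | 23.6% | carrier probability, both groups |
| latency | uniform 0–540 days | PET up to ~18 months after plasma |
| missingness | DS 137/348 amyloid, 190/348 tau, 46/348 plasma; controls 8/42, 5/42, 5/42 | per-modality MCAR, per group |

The two outcome-specific mediation structures must share the
amyloid→GFAP path and mediator noise (GFAP is generated once); this is
validated at config time.

**What the generator does not emulate.** Missingness is completely at
random and independent across modalities, so the complete-case mediation
N (~70–90) is smaller than a real cohort's overlapping availability would
give; there is no within-person longitudinal structure, no assay
heavy-tails, no age–covariate correlation, and downstream biomarkers are
linear in amyloid rather than following their own lagged sigmoids.
Passing tests therefore demonstrate estimator correctness and calibration
under the assumed model, not robustness to real-data violations of it.

## Preprocessing

Amyloid positivity is Centiloid > 18 and tau positivity SUVR > 1.3, both
strict (a value exactly at threshold is negative). Missing PET gives an
`unknown` status. Controls are never assigned A/T labels: they are their
own comparison group, though their biomarker values feed the trajectory
reference curves. DS participants who are A−/T+ contradict the
amyloid-first cascade and are excluded from analyses, with every
exclusion (and every incomplete-case drop) written to a provenance log.
Complete-case filtering is per analysis, so one participant can appear in
the group comparison but not in mediation. The tau composite is the
unweighted mean SUVR over a configurable Braak I/III/IV region list
(default: entorhinal, parahippocampal, amygdala, fusiform, lingual,
inferior/middle temporal, insula, posterior/isthmus cingulate).

## Group comparisons

Kruskal–Wallis omnibus (tie-corrected, χ² reference with k−1 df) across
control / A−/T− / A+/T− / A+/T+, then all pairwise two-sided Wilcoxon
rank-sum tests. Small samples (n_a+n_b ≤ 20) can use full enumeration of
the permutation distribution (midranks, so ties are handled); otherwise
the tie-corrected normal approximation with continuity correction is
used — the two agree within 0.02 in the tested range. Bonferroni
correction uses the family of all pairs actually tested (6 for four
groups); the family size is reported, since published analyses rarely
state it. The shift estimate is the Hodges–Lehmann median of all
pairwise differences; its CI inverts the rank-sum test (exact critical
values for small samples, normal approximation otherwise), with a seeded
percentile bootstrap available as a fallback when heavy ties make
inversion conservative. Group comparisons are deliberately unadjusted
for covariates; adjustment enters the trajectory and mediation stages.

## Trajectories and divergence ages

Each biomarker is regressed on age separately for DS and controls using
a cubic B-spline basis (dimension k = 10, interior knots at empirical
quantiles) penalized by the exact integrated squared second derivative;
the smoothing parameter minimizes GCV, n·RSS/(n−edf)², over a log grid.
Constant and linear trends are unpenalized, so effective df ranges from
2 to k. Controls can alternatively be summarized by a flat reference via
a very large smoothing parameter; the spline fit is the default.

The bootstrap resamples participants with replacement within group
(knots and λ frozen at full-sample values) and evaluates the DS − control
difference on a 0.1-year grid over the overlapping age range. Because
"first significant elevation" is not a uniquely defined estimand, the
rule is explicit and swappable:

* **Cohort-level divergence age** — the smallest grid age at which the
  pointwise bootstrap percentile interval (α = 0.05) of the difference
  lies strictly above zero there and at every older age.
* **Replicate-level detection** — a replicate detects at the smallest
  grid age where its own difference minus z₀.₉₇₅ × (model-based pointwise
  SE of the difference) stays positive through the end of the grid.

The replicate-level ages give the percentile CI and the detection
fraction; the SE margin makes false detection α-calibrated under the
null (measured ≤ ~2× nominal over null cohorts). When fewer than half
the replicates detect, no divergence age is reported. Timing differences
between biomarkers use paired replicates (shared seed), dropping
non-detecting replicates with their fraction disclosed; the two-sided
p-value is 2·min(frac ≤ 0, frac ≥ 0), floored at 1/B.

The divergence age is a sample-size-dependent estimand: tighter bands
(larger n) detect earlier along the sigmoid's tail. The recovery test
therefore uses a steep trajectory (rate 2/y), for which the first
crossing is nearly threshold-independent, and checks study-scale
estimates against the same estimator run on a dense cohort
(n = 20,000/2,400) where sampling error vanishes. Covariate adjustment
(latency, sex, APOE ε4), when enabled, residualizes the response on
linear covariate terms with a group indicator retained so the group
contrast is untouched.

## Mediation

Product-of-coefficients linear mediation: M ~ T + X gives path a,
Y ~ T + M + X gives paths b and c′; ACME = a·b, ADE = c′, total effect
= c′ + a·b, which equals the treatment coefficient of Y ~ T + X exactly
(algebraic identity, asserted to 1e-10). Under linearity and no
treatment–mediator interaction this is the counterfactual ACME.
Covariates are latency (days, continuous) and binary indicators for
female sex and APOE ε4 carriage. Uncertainty comes from a seeded
case-resampling bootstrap (default 5,000 replicates) with percentile
CIs; the proportion mediated is reported raw (it can leave [0,1] when
the total effect is unstable) alongside a truncated convenience value,
and replicates with |total effect| below tolerance are dropped with
their fraction reported (a stability flag is set beyond 1%). A minimum
analysis n of 30 is enforced.

## Numerical and design choices

* Penalty matrices are computed by 2-point Gauss–Legendre per knot
  interval, exact for the piecewise-quadratic integrand.
* All bootstraps and the generator use `numpy.random.default_rng` with
  explicit seeds; identical config + seed reproduces output
  byte-identically across processes.
* Percentile (not BCa) intervals throughout, for determinism and speed.
* Bonferroni (not Holm) to match the analysis style being reproduced.
* The test and acceptance suites scale problem sizes to what the checks
  need: 500–2,000 bootstrap replicates and cohorts of 80–600 for
  calibration sweeps, 20,000 for the dense divergence oracle; the
  pipeline defaults remain 10,000 (trajectory) and 5,000 (mediation)
  replicates.

## Known limitations

* Divergence ages inherit the spline's boundary behavior: with strong
  effects and sparse young controls, GCV can near-linearize a fit and
  push the band above zero close to the grid edge (visible as CIs
  touching the youngest common age). Interpret divergence ages jointly
  with their CIs and detection fractions.
* The mediation estimator assumes no treatment–mediator interaction and
  no unmeasured confounding; no sensitivity analysis is provided.
* Group comparisons are cross-sectional and unadjusted; demographics
  tests treat participants as independent.
* The proportion mediated is only interpretable when the total effect is
  clearly nonzero; consult the stability flag.
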