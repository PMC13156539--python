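# Methods

`trialcea` implements the statistical and health-economic machinery of a
two-arm repeated-measures randomized trial evaluated from a societal
perspective: a seeded synthetic cohort generator, multiple imputation of
follow-up outcomes under a missing-at-random (MAR) mechanism, adjusted
between-group contrasts from generalized estimating equations (GEE), a
cost model combining amortized program fixed costs with direct medical
and human-capital indirect costs, quality-adjusted life years (QALYs) by
the area-under-the-curve method, and a stratified bootstrap
cost-effectiveness analysis producing the ICER, net monetary benefit,
BCa confidence intervals, the cost-effectiveness plane, and the
acceptability curve (CEAC).

## The synthetic cohort

The generator emulates a 1:1 randomized trial of 96 participants per arm
assessed at baseline (T0), 3 months (T1) and 6 months (T2).  Six
psychometric totals are simulated — body image distress (BIS, 0–30),
stigma (SIS, 24–96), sleep quality (PSQI, 0–21), social support (MSPSS,
12–84), and the SF-36 physical/mental component summaries (PCS/MCS,
0–100) — plus an SF-6D-style health utility in [0, 1].

Each outcome is drawn per participant from a multivariate normal over
the three assessments with an exchangeable within-subject correlation
ρ (default 0.5; the observed trial correlation is not reported, so this
is a package choice of a typical repeated-psychometric value).  The mean
at time t is `baseline_mean + control_drift_t + effect_t·1[intervention]`:
effects are additive on the score scale and act only at follow-ups.
Draws are then truncated to the instrument range and rounded on integer
scales.  Truncation after effect addition slightly biases marginal means
when parameters sit near a bound; the shipped defaults are mid-range
(for stigma the nearest bound is ≈3.4 SD away), where the bias is
negligible, and tests rely on those mid-range settings.

Default baseline means/SDs, control drifts and intervention effects are
the reported cohort values (e.g. stigma 52.58 (9.50) at baseline with
intervention effects −5.83 at T1 and −7.79 at T2; utility 0.663 with
cohort SD 0.1372, i.e. SE 0.014 at n = 96).  PCS and MCS are drawn
jointly with a cross-correlation of 0.3 (the package's calibration
choice), which makes the affine utility surrogate applied to baseline
scores reproduce the target utility mean and SE.  Endocrine-therapy
indicators are Bernoulli with per-arm prevalences 52.1% / 66.7%,
reproducing the baseline imbalance the analysis adjusts for.

Direct six-month medical costs are lognormal per arm with the reported
arm means (≈US $9,114 / $9,003) and SDs backed out of the reported
standard errors (SE·√96 ≈ $10,100): costs are non-negative and heavily
right-skewed, so a two-parameter lognormal is the natural minimal model.
Inpatient days and clinic visits are Poisson with rates (2.54/2.37 days,
2.0 visits) calibrated so that the human-capital formula below
reproduces the reported arm indirect-cost means (≈$144 / $137) to about
a dime.  App-usage totals (intervention arm) are a correlated bivariate
lognormal in (duration, logins), parameterized by median and IQR
(199.6 min, IQR 70.9–451.3; 39.5 logins, IQR 19–86.5) with a log-scale
correlation of 0.8, split across the three program modules by Dirichlet
shares proportional to the module medians.  Usage feeds only the
descriptive usage table, not the effectiveness or economic analyses.

What the generator does **not** emulate: item-level psychometrics (only
scale totals), floor/ceiling clumping beyond simple truncation,
cost–outcome correlation (costs are drawn independently of scores),
site or calendar-time effects, and informative dropout beyond the
single-index MAR model below.  Passing tests therefore demonstrate that
the *analysis machinery* is correct under the stated data-generating
assumptions, not that those assumptions hold in any real cohort.

### Missingness

Dropout is monotone at follow-ups: a dropout misses either both
follow-ups or only the final one (equal probability).  Baseline is never
masked, and cost/usage records stay complete (they come from records,
not questionnaires).  Under MCAR every participant drops with the target
rate (default 0.193, matching 37/192 lost).  Under MAR the dropout
probability is `logit⁻¹(c + 0.5·z(SIS at T0) + 0.2·1[intervention])`,
with the intercept `c` solved numerically so the expected dropout equals
the target rate; the positive stigma loading makes dropouts average
higher baseline stigma, the signature the imputation model must handle.

## Multiple imputation

Default engine: sequential regression with predictive-mean matching
(PMM), the monotone special case of chained equations.  T1 is imputed
from arm, endocrine therapy and the baseline score; T2 additionally from
the completed T1.  Coefficients and the residual variance are drawn from
their approximate posterior before prediction (proper imputation), and
each missing cell receives the observed value of a random donor among
the 5 nearest predicted matches, which keeps imputations in range and on
the instrument's integer grid automatically.

Sensitivity engine (`mcmc`): a joint multivariate-normal draw per
outcome — multivariate regression of the (T0, T1, T2) triple on arm and
endocrine therapy among complete cases, residual covariance drawn
inverse-Wishart and coefficients matrix-normal, missing components drawn
from the implied conditional normal and clipped to range.

m = 20 completed datasets by default (m is not dictated by the design;
20 keeps Monte-Carlo noise below reporting precision).  Point estimates
and sandwich covariances are combined by Rubin's rules
(`T = W̄ + (1+1/m)B`) with the classical small-sample degrees of
freedom; pooling applies to model coefficients and contrasts, never to
raw data summaries.  Costs and utilities at baseline are never imputed
(costs are record-based and complete; missing baselines violate the
design and raise).

## Effectiveness model

Identity-link Gaussian GEE on the follow-up responses with fixed effects
for group, the later-timepoint indicator, their interaction, endocrine
therapy, and the baseline score as a covariate; exchangeable working
correlation; robust (sandwich) covariance.  Baseline-as-covariate is the
parameterization under which the two reported per-timepoint contrasts
are directly identified: the group main effect is the adjusted
difference at T1, and group + group×T2 the difference at T2.  Fitting is
delegated to `statsmodels.GEE` (convergence: coefficient change < 1e-8
or 100 iterations; a non-converged fit refuses to yield contrasts).
Inference is Wald-type on the pooled robust SE, with Rubin degrees of
freedom when m > 1.

Per-outcome p values for the two follow-up contrasts are
Bonferroni-adjusted with family size k = 2 (configurable; whether the
family should also span outcomes is a judgment call — k = 2 matches a
"pairwise comparisons per outcome" reading).  Cohen d divides the
adjusted mean difference by the pooled unadjusted baseline SD, and the
distribution-based minimally important clinical difference (MICD) is
half the baseline SD; a contrast is flagged clinically meaningful when
it exceeds that threshold in absolute value.

## Cost model

Fixed program costs (one-time development/production US $15,761.19 plus
annual therapist consultation US $4,298.51) are amortized over a 5-year
horizon at a 3% annual discount rate as an **annuity-due** — the first
recurring payment falls at the start of year one, undiscounted:

    PV = one_time + Σ_{t=0..4} annual / 1.03^t  ≈ US $36,037.68

The annuity-due convention is this package's reconstruction: it is the
discounting scheme that reproduces the reported five-year total, where
ordinary-annuity (end-of-year) discounting does not.  The PV divides
into equal six-month shares across 5 years × 2 periods × 96 program
participants: US $37.54 per intervention participant per six months; the
control arm's share is identically zero.  A constant annual consultation
fee is assumed (the first-year figure is taken as recurring), again
because it reproduces the reported total.

Indirect costs follow the human capital approach:
`(inpatient_days + 0.5·clinic_visits) × daily_income`, with daily income
= annual income / working days.  The working-day convention is 260/year
(default), under which US $10,606.27/year gives US $40.79/day; the
reported rounded daily figure is a cent higher (US $40.80), a
documented sub-cent convention gap, not hidden — the package reports the
computed value.  Currency conversion divides by a configurable CNY-per-
USD rate (defaults to 1: amounts are already 2023 US$).  Money is
carried at full precision; display rounding is decimal half-up to cents
at render time only, under which the arm totals satisfy
`total = fixed + direct + indirect` to the cent.

## Utilities and QALYs

The licensed SF-6D tariff is not bundled.  `map_utility` dispatches to a
registry so the real tariff can be plugged in; two mappings ship:
`identity-clip` (clip to [0, 1]) and `sf36-affine-surrogate`,
`u = 0.0334 + 0.0164·(PCS + MCS)/2` clipped to [0.29, 1] (the SF-6D
floor).  The surrogate is monotone in each component by construction and
is labelled non-tariff; it is calibrated only to the baseline utility
mean/SE of the study cohort.  The generator also draws utilities
directly from their own configured trajectory (baseline 0.663, control
drift +0.004/+0.011, intervention shifts +0.018/+0.007), and the
pipeline analyses those, so utility effects are not tied to the
component-score effects.

QALYs per participant are the trapezoid area under the utility
trajectory with times in years (0, 0.25, 0.5); no within-horizon
discounting (horizon < 1 year).  One documented inconsistency in the
study this package emulates: the trapezoid AUC of the reported utility
trajectory (0.663, 0.685, 0.681) is ≈0.339 QALYs over six months, while
the reported six-month QALY level is 0.377; the time scaling behind the
latter is unstated.  The standard trapezoid is
implemented and the reported QALY *levels* are not used as calibration
targets anywhere (the QALY *difference* scale is unaffected by such a
rescaling up to a constant factor).

QALY and cost arm differences are covariate-adjusted (endocrine therapy;
QALYs additionally for baseline utility), mirroring the adjusted
analysis of the outcome scales.

## Bootstrap cost-effectiveness analysis

Participants are resampled with replacement **within arm** (stratified —
preserving the 1:1 design; an unstratified variant is not offered) and
each replicate recomputes the adjusted arm differences (ΔC, ΔE) by least
squares; 10,000 replicates by default.  With multiple imputation the
replicates are split evenly across the m completed datasets and
concatenated (`mi_mode="concat"`), so imputation uncertainty propagates
into the cloud; `mi_mode="first"` restricts to the first completed
dataset.  The point estimate averages the per-dataset adjusted
differences; the jackknife for the BCa acceleration uses the first
completed dataset (the acceleration is a smooth functional and is stable
across imputations).

BCa intervals: bias correction z₀ = Φ⁻¹(fraction of replicates below
the point estimate, ties counted half), acceleration
a = Σd³ / (6 (Σd²)^{3/2}) from jackknife deviations d, endpoints read
off the replicate distribution at the adjusted quantiles
Φ(z₀ + (z₀ + z_α)/(1 − a(z₀ + z_α))).  Fewer than 100 replicates
refuses to report an interval; an all-constant replicate set collapses
to a degenerate interval at the point.

ICER labelling covers the plane: ΔE > 0 with ΔC > 0 gives the ratio
ΔC/ΔE; ΔE > 0 with ΔC ≤ 0 is intervention-dominant; ΔE < 0 with
ΔC ≥ 0 is control-dominant; |ΔE| < 1e-9 QALYs is labelled
indeterminate and decisions fall back on net monetary benefit
NMB(λ) = λ·ΔE − ΔC.  The decision threshold defaults to
λ = US $37,530/QALY (3 × 2023 GDP per capita of US $12,510).  CE-plane
quadrant proportions use the tie rule ΔE = 0 → east, ΔC = 0 → south, so
the four proportions always partition the replicates.  The CEAC reports
P(NMB(λ) > 0) over λ from 0 to 200,000 in steps of 500; its analytic
limits are P(ΔC < 0) at λ = 0 and P(ΔE > 0) as λ → ∞.

## Numerical and reproducibility choices

- One global seed expands through `numpy` `SeedSequence` children into
  independent per-stage streams (generate / missingness / impute /
  sensitivity-impute / bootstrap), so any stage is reproducible alone
  and identical config+seed yields byte-identical data tables.
- GEE convergence tolerance 1e-8, max 100 iterations; exchangeable α is
  reported and must lie in (−1/(T−1), 1).
- PMM donor pool k = 5; posterior draws use a χ² draw for σ² and a
  normal draw for β (the standard large-sample approximation).
- Degenerate inputs fail loudly: empty pools, non-positive variances,
  missing baselines, unknown timepoints or mappings, empty bootstrap
  arms, non-increasing assessment times.
- Problem sizes in the shipped studies: parameter-recovery uses 200
  simulated trials at 96/arm with m = 5 imputations (m is not part of
  the criterion; 5 exercises Rubin pooling with modest Monte-Carlo
  cost); bootstrap-coverage uses 200 cohorts of 50/arm at B = 1,000 via
  the unadjusted fast path.  The pipeline defaults remain m = 20 and
  B = 10,000.

## Known limitations

- The utility surrogate is affine; it cannot reproduce tariff-specific
  nonlinearity, only the baseline mean/SE it was calibrated to.
- Costs are generated independently of outcomes, so the synthetic ICER
  scatter understates any real cost–effect correlation.
- The MAR mechanism loads on a single baseline score; the imputation
  model is congenial with it by construction, which real data do not
  guarantee.
- Single-seed trial-scale quantities (contrasts, ΔC, ΔE, CEAC
  probability) carry their full sampling noise — the cost SD is ~$10k
  against a true incremental cost of ~$155, so per-seed ICERs swing
  widely; only their distribution across seeds is calibrated.
- Between-outcome correlations (beyond PCS–MCS) are not modelled.
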