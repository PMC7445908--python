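# Methods

## Model

The package fits the additive age–period–cohort decomposition of
log mortality rates

    D_ijk ~ Poisson(N_ijk · exp(μ + α_i + β_j + γ_k)),   k = (A − i) + j,

with sum-to-zero constraints on each effect block. The Poisson form
treats death in a cell as a rare event relative to the person-years at
risk, which holds for the intended regime (rates of order 10⁻⁵–10⁻⁴);
no binomial correction or overdispersion term is included.

The grid must consist of closed five-year age intervals and modelled
periods spaced exactly five years apart. Under that matching, women in
one age group observed in one period were all born within a single
five-year window, so each grid diagonal is a genuine five-year birth
cohort; with annual input data the matching is achieved by keeping
single years five years apart (`subsample_periods`), not by averaging
five-year blocks (averaging would smear each cohort over ten birth
years and halve the time resolution of the cohort curve). Open-ended
age groups ("85+") are rejected because they have no bounded birth-year
range.

## Identification and the intrinsic estimator

In effect coding (last category of each dimension as reference,
recovered as minus the sum of the others), the design matrix `X` has
`q = 1 + (A−1) + (P−1) + (C−1)` columns and rank `q − 1`. The missing
rank is the structural relation cohort = period − age: the null
direction, in full category coordinates, is the centred linear-trend
trade-off `δα_i = i − (A+1)/2`, `δβ_j = −(j − (P+1)/2)`,
`δγ_k = k − (C+1)/2`. The implementation finds the null vector `b0`
by full SVD with threshold `max(m, q)·eps·σ_max`, verifies the null
dimension is exactly one, zeroes the (analytically zero) intercept
coordinate, normalises to unit length and fixes the sign so the first
coordinate above 1e−12 is positive; the closed-form trend direction is
kept as an independent cross-check, not the implementation.

The intrinsic estimator restricts the coefficient vector to the
orthogonal complement of `b0`: with `V` an orthonormal basis of that
complement, the Poisson GLM is fitted with design `X·V` and offset
`ln N`, and the estimate is `θ = V·w`. Among all vectors `θ + c·b0`
producing identical fitted rates this is the one of minimum Euclidean
norm, and it coincides with the Moore–Penrose solution of the
converged weighted least-squares system. The estimand is therefore the
projection of any "true" parameter vector onto the complement of
`b0` — the tests assert explicitly that a non-orthogonal simulation
truth is recovered as its projection, not as itself. Interpreting IE
output still requires the usual APC caution: the linear-trend split
between age, period and cohort is a convention, not data-driven.

## Fitting

IRLS on the reduced design: intercept initialised at the crude log
rate `ln(ΣD/ΣN)`, all other coefficients zero; weights `μ`, working
response `η − offset + (y − μ)/μ`; stop when the deviance changes by
less than 1e−10 in relative terms, cap at 100 iterations (exceeding
the cap raises an error carrying the deviance trace). The weighted
least-squares step uses `lstsq`; the reduced design has full column
rank so the step is unique. Zero-death cells are legal and enter the
deviance as `2·D̂` (no continuity correction). No standard errors are
computed anywhere.

Fit statistics: deviance `2·Σ[D ln(D/D̂) − (D − D̂)]`; per-observation
AIC `(−2 lnL + 2(model_rank + 1))/n` with the full Poisson
log-likelihood; `BIC = deviance − (n − model_rank)·ln n` with
`model_rank = q − 1` (34 for the 13×6 grid; the convention reproduces
the published value −190.449 from the published deviance 1.246 at
n = 78). Per-observation AIC conventions vary across software; the
one used here is stated exactly so its numbers are comparable only to
themselves. The effects table always reports the 37 expanded category
effects (13 + 6 + 18) with the intercept reported separately.

## Synthetic data generator

`make_true_params` draws each effect curve as a centred Gaussian random
walk (innovation SD = `effect_scale`, in log-rate units per category
step). Random walks, rather than white noise, make the synthetic
curves smooth the way real age and cohort curves are, so numerical
differentiation of fitted effects produces plausible-looking change
curves and recovery is stable. One integer seed feeds two independent
substreams (parameter draws, Poisson noise), so a whole experiment is
reproducible from a single number.

Defaults emulate the magnitudes of the motivating setting: baseline
rate 8.5 per 100,000 (intercept `ln 8.5e−5`), 2×10⁷ person-years per
cell, `effect_scale` 0.1 (0.08 for the study-layout preset, keeping
crude rates inside 5–15 per 100,000). The study preset
(`study_config`) generates 13 age groups (20–24 … 80–84) by 26 annual
years 1990–2015; the modelled 13×6 grid is obtained by explicit
subsampling, mirroring the intended workflow on real annual extracts.

What the generator does *not* emulate: the annual truth uses one
period effect per calendar year and one cohort effect per annual
diagonal, so after subsampling to five-year periods the fitted 5-year
APC model is (mildly) misspecified — deviances on study-preset fits
are therefore large, unlike a generator wired to the exact 5-year
model. This is intentional: real mortality data never satisfy the
model exactly either. Exact-recovery experiments instead simulate
directly on the modelled grid (e.g. A = 5, P = 4, N = 10⁸/cell, truth
orthogonalised against `b0`, maximum absolute effect error < 0.01).
There is no overdispersion, no age misreporting, no migration or
population-projection error, and cells are independent — passing
recovery tests demonstrates correctness of the estimator, not
robustness to those real-data features.

## Numerical and design choices

- Cohort labels are closed birth-year ranges from interval arithmetic:
  diagonal 1 of a grid starting in 1990 with oldest age group 80–84 is
  1906–1910 (`1990 − 84` to `1990 − 80`), advancing five years per
  diagonal up to 1991–1995 for the youngest cohort of the 13×6 grid.
- First differences are labelled at the earlier category ("change from
  t to t+1, plotted at t").
- Rate ratios and percent declines are exact in machine output and
  rounded to two decimals only in human-facing summaries.
- Narrative phase labels (e.g. a "gradual decline phase") are never
  computed — no change-point machinery exists; they can only be
  supplied as annotation configuration.
- Degenerate inputs fail loudly: fewer than two age groups or periods,
  non-five-year period spacing at fit time, single retained period
  after subsampling, a null space of dimension ≠ 1, zero or negative
  population, non-integer deaths.
- The CLI is deterministic byte-for-byte given (input, config, seed),
  and uses exit codes 2/3/4 for validation, identification and
  convergence failures respectively.

## Problem sizes

Unit and property suites run on grids up to 13×6 (78 cells) plus an
exhaustive null-space sweep over all 2 ≤ A, P ≤ 10; recovery
experiments use A = 5, P = 4 with 10⁸–10⁹ person-years per cell, and
the mean-recovery check uses 1000 replicates of a 3×3 grid. The whole
suite completes in a few seconds on one CPU.

## Known limitations

- No inference: no standard errors, bootstrap, or model comparison
  against two-factor submodels.
- No age standardisation, interpolation of missing cells, or
  redistribution of open-ended intervals — such inputs are rejected,
  not repaired.
- The estimator's output depends on the minimum-norm convention; two
  datasets differing by a pure linear trend in log rates are
  indistinguishable to it by construction.
- Corner cohorts (oldest and youngest diagonals) are identified by a
  single cell each and are correspondingly noisy.
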