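# Methods

## The choice model

Households face repeated choice tasks with three alternatives: a status quo
at $0 and two priced salmon-recovery programs. Program utility is linear in
price (in $100s/household/year), official recovery status, the increase in
returning adult fish above the 150,000-fish baseline (in 100,000s), a
quick/slow indicator for the rate of increase, two mutually exclusive
fishing-season indicators, and the status×fish and speed×fish interactions;
the status quo carries only an alternative-specific constant (ASC). Choice
follows random-utility maximization with independent Gumbel errors, i.e.
logit probabilities conditional on the taste vector.

All nine coefficients are random across respondents and constant within a
respondent (panel mixing). Mixing distributions are independent normals;
the price coefficient enters as `-exp(b1)` so that the marginal utility of
money is log-normal and strictly positive for every draw — no respondent
can enjoy paying more. Correlated random coefficients are deliberately out
of scope.

### Estimation

The panel simulated likelihood averages, per respondent, the product of
task-level chosen-alternative probabilities over draws of the coefficient
vector, and sums log averages over respondents. Draws are scrambled Halton
points (9 dimensions, one consecutive block of `n_draws` per respondent,
normal scores via the inverse CDF); a pseudo-random option exists for
diagnostics. Default `n_draws` is 500 for production fits; the likelihood
is deterministic given (data, seed, draw settings).

The optimizer is L-BFGS-B on the negative simulated log-likelihood with
analytic gradients (chain rule through the exponentiated price
coefficient); convergence requires a projected-gradient norm below 1e-5.
SD parameters are estimated unsigned and reported as absolute values (the
usual mixed-logit sign invariance). Standard errors invert a
finite-difference Hessian of the simulated log-likelihood (central
differences of the analytic gradient); a sandwich option combines that
inverse with the outer product of per-respondent scores. A rank-deficient
Hessian falls back to a pseudo-inverse with the affected standard errors
reported as NaN. Starting values are the conditional-logit estimates for
the means and 0.5 for every SD — informative about location, agnostic about
heterogeneity.

Numerical guards: the log-price coefficient is clipped at ±30 inside the
exponential; per-respondent likelihoods are floored at 1e-300 before logs
(with a warning); the within-respondent mixture is computed with
log-sum-exp. The likelihood/gradient kernel is a fused numba routine; an
equivalent vectorized numpy implementation is retained as the reference
path and the two agree to machine precision (tested).

### Conditional logit and LR tests

The no-heterogeneity baseline keeps the `-exp(b1)` price parameterization
so the models are strictly nested parameter-by-parameter. LR statistics use
2·ΔLL with chi-square reference; tiny negative statistics from simulation
noise are clamped to zero with a warning. Nested *simulated* fits (e.g. the
interaction tests) always share the same Halton draws and seed so the
statistic is not contaminated by simulation noise.

### A finite-sample caution

With only three tasks per respondent and nine random coefficients, small
samples admit a spurious "separation" optimum in which all means and SDs
inflate together and each respondent's likelihood is carried by the few
draws that rationalize all of their choices perfectly. In experiments this
plateau dominates below roughly 300 respondents (at 40–100 draws) and
disappears by ~600 respondents; at the study scale (926 respondents, 500
draws) the interior optimum is comfortably preferred and generating means
are recovered within reported confidence bounds. Recovery tests in this
package therefore use ≥600 respondents; users fitting smaller panels should
watch for exploding SD estimates.

## Synthetic populations

The generator's defaults are the study conditions: 926 respondents, 3
tasks each, generating taste parameters equal to the published RPL point
estimates, task nonresponse of 1.6% (926·3 tasks minus 1.6% ≈ the 2,734
usable responses reported), and Bernoulli demographics at the survey-sample
shares (college 0.540, age-65+ 0.385, male 0.611, white 0.877). The Oregon
share (0.167) matches the census household counts used in aggregation, and
the cluster-box mail-delivery share (0.20) is an assumption — the survey
does not report it. Choices are sampled directly from the conditional
logit probabilities implied by each respondent's realized tastes, which is
distributionally identical to drawing Gumbel errors and maximizing, and
cheaper.

Response propensities are logistic in the demographics with an intercept of
−1.45 and an Oregon shift of +0.45, reproducing the survey's 25.4%
(Oregon) / 17.8% (elsewhere) response rates, and a cluster-box coefficient
of −0.5 capturing the survey's finding that such households respond less.
An optional college shift on the fish-coefficient mean reproduces the one
demographic preference difference the survey found; sizing it as
`31·exp(0.85)/100` yields the reported $31/household/year premium per
100,000 fish in the zero-SD limit.

What the generator does *not* emulate: correlation among demographics,
mailing waves and reminders, item nonresponse within a task, protest
responses, and attribute non-attendance. Passing recovery tests therefore
show that the estimator inverts the assumed data-generating process at the
study's scale — not that the original survey was free of those
complications.

## Experimental designs

Designs are random draws from the restricted attribute grid: fish levels
{1.0, 1.75, 2.25, 3.75} (100,000s) as in the published scenario table,
"recovered" status only at 175,000 fish and above (inferred from the same
table), both rates everywhere, and at most one fishing indicator per
alternative. Price levels are not published; the configurable default
{0.25, 0.5, 1.0, 1.5, 2.5, 3.5} ($25–$350/y) brackets the scenario costs.
Design quality is measured by the utility-neutral D-error
`det(I(β=0))^(-1/K)` of the conditional-logit information matrix with
equal choice probabilities; `generate_design(..., optimize_steps=n)`
applies greedy random swaps that accept D-error reductions. Reproducing
the original D-optimal design search is a non-goal.

Returning-fish trajectories shown to respondents are modeled with the
determinate-growth beta sigmoid (Yin et al. 2003): completed fraction
`(1 + (te−t)/(te−tm))·(t/te)^(te/(te−tm))` up to the growth-completion
time `te`, flat afterwards, with inflection at `tm`. The quick/slow presets
(tm=8, te=20 vs tm=25, te=50 years) share the 50-year endpoint and are
illustrative — the survey's exact parameter values are not published — so
only ordinal properties (monotonicity, quick dominating slow at equal
endpoints) are relied upon.

## Welfare and aggregation

Per-draw compensating variation divides the non-price systematic utility of
a scenario (relative to no change; the ASC is excluded) by `exp(b1)` and
multiplies by 100 to return to dollars. Because the denominator is
log-normal, the simulated WTP distribution is heavy-tailed: the mean is
finite but can sit far above the median (the package warns when the ratio
exceeds 5), so mean and median are both always reported. The study's own
compensating-variation estimator is described only in unpublished
supplementary material; this package does not attempt to re-derive the
printed scenario WTP values from the coefficient table and instead treats
them, the printed WTP surfaces, and the census household counts as inputs
(`cohowtp.defaults`).

Krinsky–Robb intervals resample parameter vectors from the asymptotic
normal distribution of the estimates and recompute the WTP statistic per
resample with common mixing draws, reporting percentile bounds.

Aggregation follows the two published rules. Lower bound: sample WTP times
`round(0.254·1,570,430) + round(0.178·7,837,629) = 1,793,987` households
(term-wise rounding matches the printed counts). Upper bound: WTP adjusted
to the census college-graduate share (0.358 vs the sample's 0.540, mean
shifts on the recovered/fish/quick coefficients via the fitted interaction
terms; SDs unchanged — whether the original adjustment also touched
variances is not published) times all 9,408,059 households. Presentation
rounding is cents for surface evaluations, nearest dollar (half away from
zero) for marginal values, and nearest $million / two-decimal $billion for
aggregates.

## Selection diagnostics

The selection equation is a logistic (optionally probit) regression of
response on demographics and the cluster-box exclusion variable; constant
covariates are dropped rather than breaking the fit. `pdiff` centers the
fitted propensities on their frame mean (zero-sum by construction).
Interaction tests add fixed mean-shift columns `moderator × attribute` for
the three conservation attributes to either the conditional logit or the
RPL and compare nested fits by LR with df = number of interactions;
interactions shift coefficient means only, not SDs. Moderators must vary
across respondents (a constant moderator is collinear with the main
effects and is rejected).

## Problem sizes used in the shipped checks

Statistical checks are sized to what they need: parameter recovery runs at
the study's own scale (926 respondents, 500 Halton draws); the type-I-error
simulation uses 500 replications of 150 homogeneous respondents with the
conditional-logit interaction test (testing an SD of zero in the RPL would
sit on a parameter boundary where the LR statistic is not chi-square, and
the homogeneous null makes the conditional logit the true model); the
selection-null uniformity check uses 200 replications of an 800-person
sampling frame; Krinsky–Robb coverage uses 60 replications of 250
respondents. The quadrature oracle compares 10,000-draw MSL against
80-node Gauss–Hermite integration on a one-random-coefficient problem.

## Known limitations

- Independent (uncorrelated) mixing distributions only; no WTP-space,
  latent-class, or Bayesian estimation.
- The small-sample separation plateau described above is inherent to
  short-panel mixed logits; the package reports non-convergence and
  exploding SDs honestly rather than constraining them away.
- Population adjustment implements mean shifts for a single moderator at a
  time (college by default), matching the one significant interaction the
  survey reported.
- The printed upper-bound benefit of the least aggressive scenario
  ($518M) is not exactly the product of its printed inputs
  ($55.13 × 9,408,059 = $518.7M, which presents as $519M); the package's
  presentation rule reproduces the other printed aggregates exactly and
  this one to within $1M.
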