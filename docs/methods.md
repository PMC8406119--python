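# Methods

This note documents the models, conventions, defaults and known limits of
`datashare_dce`. It describes what the code computes; every number quoted
here is produced by the test suite or by `scripts/acceptance.py`.

## Study structure and coding

A study is five categorical attributes describing a hypothetical
health-data-sharing situation — collector (3 levels), new user (4), reason
for use (4), information/consent mechanism (4), review process (3) — with
the last listed level of each attribute as the reference. Effect coding
gives K = Σ(Lₐ−1) = 13 columns: a non-reference level sets its indicator to
1, the reference level sets the attribute's whole block to −1. Level
effects therefore sum to zero within an attribute, and reference-level
estimates are *derived* as minus the sum of the estimated ones, never
estimated. Column order is fixed (attributes in configuration order,
non-reference levels in listed order), so two runs of any stage produce
identically ordered outputs.

**Intercept sign convention.** The reported "Intercept" enters the
*acceptance* utility: P(accept) = logistic(intercept + β'x). This is the
convention under which the bundled reference estimates reproduce their own
published uptake arithmetic (the least-preferred scenario's utility
−0.19−0.26−0.47−0.90−0.52+0.51 = −1.83 gives 13.8 % ≈ 14 % uptake, the
most-preferred 1.78 gives 85.6 %); describing the constant as a rejection
utility is inconsistent with that arithmetic. Positive intercepts still read
as "the average respondent tends to accept"; the class with a negative
intercept is the sharing-averse one under this convention, and the sign
convention is stated wherever the intercept is printed.

## Design generation

The binary-logit Fisher information of a design is M = Σₜ pₜ(1−pₜ)xₜxₜ' and
its D-error det(M⁻¹)^(1/K); the Bayesian D-error averages the D-error over
draws β ~ N(mean, sd²) taken from a scrambled Halton sequence
(`scipy.stats.qmc.Halton`, first 10 points dropped, inverse-normal
transform). Zero prior sds reduce exactly to the fixed-prior D-error.
Search is coordinate exchange: single-task, single-attribute level swaps
accepted when they lower the penalized objective

    Bayesian D-error + λ · level-balance deviation,

where the deviation is Σ|count − n_tasks/Lₐ| over attribute levels and λ
defaults to 1 % of the initial design's D-error, making one imbalance unit
cost about one percent of efficiency (balance is a soft target, not a
constraint — with 32 tasks a 3-level attribute cannot be perfectly
balanced). The iteration budget counts candidate evaluations (default
1000). Blocking is greedy pairwise swapping that balances per-block level
frequencies; block counts must divide the task count (28/4 → 7 per block,
32/4 → 8). An optimized 32-task design's Bayesian D-error comes out around
0.34 with priors at the bundled pooled estimates, ~15 % below the mean of
random 32-task designs.

## Synthetic data

The generator's defaults are the study conditions the package is built
around: ~5,199 respondents drawn from the four countries in the retained
sample's proportions; four latent classes whose coefficients and
country-membership model are the bundled reference set (these defaults
reproduce average class probabilities of 27/32/23/18 % under the default
country mix); 16 accept/reject tasks per respondent (8 per information
type, from the respondent's randomly assigned design block); screening
fields drawn so 2 % of respondents finish under five minutes and 60 %
(disjointly) fail to complete, mirroring the survey's attrition shape; and
8 five-category eHealth-literacy items with per-item response probabilities
(0.015, 0.029, 0.107, 0.55, 0.299) chosen to yield roughly 30 % inadequate /
43 % problematic / 27 % sufficient literacy. Ages are truncated-normal
(49 ± 17, 18–90), durations lognormal above the speeder threshold.

What the generator does *not* emulate: panel-recruitment bias,
country-specific response styles beyond the membership model, dependence of
age/gender/eHealth literacy on the latent class, serial correlation across a
respondent's tasks beyond the shared class, and item-level structure in the
literacy battery. Passing recovery tests therefore show the estimators are
correct and well calibrated under the assumed model, not that the model
captures every feature of real survey data.

## Screening and literacy scoring

Speeders (duration < 5 minutes, total survey time) are removed first, then
incompletes among the remainder, so an overlapping respondent is counted
once, in the speed bucket; counts are conserved exactly
(received = speeders + incompletes + retained). Literacy: any
disagree/strongly-disagree response → inadequate; otherwise any neutral →
problematic; all-agreement → sufficient. When rules overlap the weakest
response dominates — the conventional screening posture of flagging the
least literate signal.

## Estimation

**Pooled logit.** Newton–Raphson with step-halving on the concave Bernoulli
log-likelihood; stops when the gradient max-norm falls below 1e−8 or the
Newton step below 1e−10 (the gradient's floating-point noise floor at
n ≈ 30,000 sits above 1e−8), 200 iterations maximum, non-convergence
flagged. Wald SEs from the inverse observed Hessian, 95 % CIs, two-sided
p-values, no multiplicity adjustment, no clustering on respondent by
default. All-accept/all-reject data and diverging coefficients (|θ| > 30)
raise a separation error naming the offender. Tests cross-check
coefficients against an independently optimized statsmodels fit to 1e−5.

**Latent class.** EM on respondents' class-conditional likelihoods
(a respondent's 16 tasks are independent given class). The E-step is
log-sum-exp stabilized; the class M-steps are posterior-weighted Newton
logits warm-started at the previous parameters (ridge-stabilized, with a
warning, if a class's posterior mass falls below 0.1 % of respondents);
the membership M-step is closed-form because country — the only membership
covariate — yields a saturated model (constant + 3 dummies per non-reference
class over 4 country patterns): per-country log-odds of mean posteriors.
EM runs from seeded random Dirichlet responsibilities until the
log-likelihood improves by less than 1e−7 (max 500 iterations), the best of
`n_starts` initializations is polished by L-BFGS on the observed
log-likelihood with the analytic (Fisher-identity) gradient, and classes are
reported in descending average-posterior order, re-expressing the membership
block against the new reference class. "Average class probability" is the
mean posterior (the prior-share alternative is exposed as
`prior_shares(country)`). Standard errors, when requested, come from a
central-difference Hessian of the observed log-likelihood. Parameter count:
C(K+1) + (C−1)·n_countries — 68 for four classes, K=13 and four countries.

Default `n_starts` is 100; the bundled tests and the acceptance script use
4–20 starts at n ≈ 2,000 respondents, which the label-invariance and
recovery checks show is ample for this well-separated four-class truth
(recovered class shares within half a point, class-coefficient MAE < 0.10).

**Model selection** reports log-likelihood, AIC and BIC per class count and
flags the AIC minimum; per-C failures are recorded in the table rather than
aborting it.

## Post-estimation

Scenario utility is the intercept plus the (derived-where-reference) level
estimates of the scenario's levels; uptake is its logistic; class-adjusted
uptake weights per-class uptakes by average class probabilities (weights
are overridable, e.g. with degenerate or posterior-based weights). The
uptake grid fixes collector and new user and sweeps review × reason rows
against information columns (48 cells). Relative importance is the level
range per attribute normalized by the maximum range.

The scale test fits both samples separately, then a pooled logit in which
sample B's design matrix (including the intercept column) is multiplied by
a scale λ; λ is profiled over a log grid on [0.1, 5] and refined by
golden-section search. LR = −2(LL_pooled(λ̂) − LL_A − LL_B) is referred to
χ²(K+1). Strict parameter counting would give K degrees of freedom (2(K+1)
free parameters against K+2 pooled); the implementation keeps the
conventional K+1, which is marginally conservative — the null calibration
in the acceptance suite (p > 0.05 in ≥ 45/50 same-process replicates,
λ̂ ∈ [0.8, 1.25]) holds under it, and λ̂ recovers a true doubling of all
utilities within a few percent.

## Numerical and degenerate-input choices

Tolerances: Newton gradient 1e−8, EM log-likelihood 1e−7, posterior row
sums exact to 1e−10, golden-section width 1e−3 on λ. Ties in level-balance
or blocking swaps resolve by seeded iteration order, making every search
deterministic given its seed. Singular information matrices raise an
identification error naming the collinear columns; a singular prior draw in
the Bayesian D-error contributes +∞ with a warning instead of aborting.
Degenerate datasets (single respondent and C ≥ 2, all-same choices,
non-overlapping level usage between scale-test samples) raise descriptive
errors rather than returning silently wrong numbers.

## Known limitations

Only binary accept/reject tasks (no multi-alternative sets, no dual
response), no interaction-effect designs, no mixed (random-parameter)
logit, no covariates other than country in the membership model, and no
delta-method intervals on uptake. The bundled uptake-grid reference
contains one internally inconsistent printed cell (its consent column
exceeds its opt-out column although every class's opt-out coefficient
exceeds its consent coefficient); the corresponding reproduction check
reports 47 of 48 cells within five percentage points and the one outlier at
~11, and the package does not adjust its arithmetic to match that cell.
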