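# Methods

This note documents the models implemented in `isletprog`, the assumptions
behind them, the defaults of the synthetic-cohort generator, and the
numerical choices that matter. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## 1. Model

### States and time scale

Progression is a continuous-time process over four states — single GADA
(1), multiple islet autoantibodies without IA-2A (2), multiple with IA-2A
(3), type 1 diabetes (4, absorbing) — with six forward transitions
(1→2, 1→3, 1→4, 2→3, 2→4, 3→4). The clock is *time since confirmed GADA
positivity* for every transition; there is no clock reset at intermediate
states (a "clock-forward" Markov structure conditional on the covariate
paths). IA-2A is singled out because its appearance marks a faster route to
clinical disease, which is why states 2 and 3 are distinguished.

### Longitudinal submodel

Nine variables are modelled jointly: fasting and 2-h glucose, fasting and
2-h C-peptide (from OGTTs), HbA1c, and the four autoantibody titer z-scores
(GADA, IA-2A, IAA, ZnT8A). OGTT measures and titers are analysed as
log(1+x); HbA1c stays on its NGSP percent scale. For subject i and variable
j,

    y_ij(t) = x_j(t)' beta_j + z_j(t)' b_ij + eps_ij,
    b_i ~ N(0, Sigma_b),  eps_ij ~ N(0, sigma_j^2)

with spline bases x_j: natural cubic (interior knots at 2 and 6 years,
linear beyond the boundary) for the five metabolic variables, piecewise
linear with hinge knots at 1 and 3 years for the titers — titers shift
abruptly around seroconversion events, metabolic variables drift smoothly.
Random effects are intercept + slope per variable (18 in total).

Sigma_b structure. A fully unstructured 18×18 covariance is not
identifiable at realistic cohort sizes (~400 children). The default is
block-diagonal (unstructured 2×2 within each variable); an `"unstructured"`
option estimates the full matrix and is what the cross-variable-correlation
test exercises. We chose this over a low-rank cross-variable coupling
because the block/unstructured constraints admit *exact* conditional
M-steps (see §3), while blockdiag-plus-low-rank does not.

### Multistate submodel

Each transition k has intensity

    h_ik(t) = h0_k(t) * exp( gamma_k' w_i + alpha_k' m_i(t) )

where w_i are baseline covariates (age at GADA positivity in years,
first-degree relative status, HLA indicator DQ8/X and DQ2/X with DQ2/8 as
reference) and m_i(t) are *current values* of the noise-free longitudinal
trajectories (current-value association; no slope or cumulative forms).
Each transition has its own covariate roster, mirroring clinical
availability: OGTT variables enter only transitions out of states 2 and 3,
IA-2A titer only the 3→4 transition. Baseline hazards h0_k are
piecewise-constant; in fitting, cut points sit at tertiles of that
transition's observed event times and the levels are profiled out in closed
form.

The likelihood is a full (not partial) likelihood. Sojourn exposure is split
into cells at the baseline cut points and a sub-grid (default 1 month);
covariates are evaluated at cell midpoints, making the integrated intensity
exact for piecewise-constant paths and O(step²) accurate for smooth ones.
This exposure-split representation is a Poisson likelihood, so unpenalized
fits and Wald standard errors go through an ordinary Poisson GLM.

LASSO selection. Covariate selection per transition maximizes
ell(theta) − lambda * sum_j sd_j |theta_j| (penalty on the standardized
scale, baseline levels unpenalized) via FISTA proximal gradient with
backtracking; coefficients below 1e-8 are reported as exact zeros. The
penalty is chosen per transition by subject-level K-fold cross-validation
(default 5 folds) on the held-out unpenalized log-likelihood, over a
glmnet-style grid from the data-derived lambda_max downward; the default
selection rule is the one-standard-error rule, which we prefer to the
CV-maximum because the latter systematically over-selects noise covariates.
After selection, the selected set is refit without penalty; its SEs and
p-values are post-selection Wald quantities. Excluded covariates are shown
with coefficient 0 and no p-value; the SE printed for them comes from a
one-at-a-time re-entry refit and is descriptive, not inferential.

### Joint model and dynamic prediction

The random effects b_i are shared between the submodels through the
current-value terms, giving the subject-level marginal likelihood

    L_i = Int p(y_i | b) * L_ms(path_i | m_i(.; b)) * N(b; 0, Sigma_b) db.

Integration: Laplace approximation by default (the 18-dimensional b makes
quadrature infeasible), adaptive Gauss–Hermite for 1-D toys, and antithetic
Monte Carlo as a reference implementation; the three agree to <1e-2 on the
1-D benchmark in the acceptance suite. `fit_joint` initializes two-stage
(longitudinal fit, then multistate fit on posterior-mean trajectories) and
then refines the hazard parameters by maximizing the summed Laplace
likelihood. The refinement loop is practical for reduced models (few
variables / random effects); at the full 18-dimensional default the
two-stage estimates are the intended operating point, and the test suite
demonstrates on a toy that the joint refinement (i) coincides with
two-stage when the association is zero and (ii) is less attenuated than a
last-observation-carried-forward covariate fit under measurement noise.

Prediction for a subject with history up to landmark s (longitudinal
records plus the observed state path, ending "still in state q at s"):

1. draw b from the posterior by importance sampling — proposal = the exact
   Gaussian posterior given the longitudinal records; weight = the
   multistate likelihood of the observed state history (survival in q,
   earlier transitions at their detection times; transition times inside
   visit intervals are not imputed). The effective sample size is reported
   and a warning is raised below 5%.
2. for each draw, build m(·; b) and propagate the state distribution from
   unit mass at q(s) by the product integral with step 1/120 year;
3. average over weighted draws; report per-state Monte-Carlo SEs.

Updating with new data is recomputation on the concatenated history — no
incremental state is kept, so updated forecasts are exactly what a fresh
call would produce.

## 2. Synthetic-cohort generator

The generator emulates the GADA-first subcohort of a prospective high-risk
birth cohort and is the test bed for every stage; its defaults are the
study conditions.

* Baseline covariates: female 45.9%, FDR 17.4%, DQ2/8 48.8%, DQ8/X 29.6%,
  DQ2/X 21.6%. Age at GADA positivity: median 5.1, IQR (2.4, 9.0) years.
  A two-parameter log-normal cannot reproduce that asymmetric IQR together
  with the median (its implied upper quartile misses by ~0.9 y), so age is
  drawn through a piecewise-linear quantile function in log-age anchored at
  those three quantiles, with support (0.3, 14.5) y; the printed summaries
  are matched by construction.
* Longitudinal truth: intercepts are the analysis-scale baseline medians of
  the emulated cohort (e.g. fasting glucose 88 mg/dL → log 89 ≈ 4.49;
  HbA1c 5.2%, a standard non-diabetic childhood value, as no published
  baseline exists); slopes encode the reported qualitative trends (slow
  metabolic rise with growth, early GADA rise then flattening, late IA-2A /
  ZnT8A rises). Between-subject SDs are set so that total cross-sectional
  spread matches the published baseline IQRs, split roughly evenly between
  random effects and residual noise; a rank-1 loading on the four titer
  slopes adds a shared "autoimmune drive" correlation. These are one-time
  realism choices, not fitted quantities.
* Transition truth: the published log hazard ratios, with LASSO-excluded
  entries kept at exactly 0, and covariates centered at reference values
  (variable intercepts; age 5.1) — centering only reparameterizes the
  baseline hazard, which the source does not print. Baseline hazards are
  two-piece constants (cut at 3 y) chosen once so that all four states are
  occupied at 10 years and every transition accrues events at study scale.
* Event times are drawn by Lewis–Shedler thinning with a piecewise
  dominating rate (1.2 × the running maximum of the total intensity over
  one-year windows of a 0.05-y grid); a closed-form inverse-CDF sampler for
  piecewise-constant hazards serves as the distributional oracle in tests
  (two-sample KS).
* Observation: quarterly visits from GADA confirmation to age 15 with
  ±2-week uniform jitter (disablable), an end-of-study assessment at the
  censoring time; titers and HbA1c at every visit; OGTT variables
  biannually once the *observed* state is 2 or 3 and age ≥ 3; nothing after
  diabetes onset. Transitions are detected at the first visit at or after
  they truly occur (right-endpoint convention); a passage through an
  intermediate state completed between two visits collapses into the direct
  observed transition, exactly as interval observation would.
* Reproducibility: each subject has a named RNG stream derived from
  (master seed, subject index); identical configs produce byte-identical
  written tables.

What the generator does *not* emulate: pre-seroconversion life, reverting /
transient autoantibodies, country effects, state-dependent titer dynamics
(titers evolve by their random effects, not by the state actually entered),
and informative dropout. Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to these
real-data features.

## 3. Estimation details

* Mixed model: ML (not REML — the joint model requires comparable
  likelihoods) by ECM. E-step posteriors and all M-steps are exact given
  the block structure, so the marginal log-likelihood is non-decreasing by
  construction — this is asserted in tests. The implementation runs on
  per-variable sufficient statistics with one batched (N×18×18) inverse per
  iteration. Convergence: relative log-likelihood change < 1e-8 or 500
  iterations (the EM tail is slow; the 500-iteration cap is reported via
  `converged=False` with the full trace). Residual variances are floored at
  1e-12 for degenerate noiseless inputs.
* Multistate fit: covariates are internally centered at exposure-weighted
  risk-set means (pure reparameterization; improves conditioning),
  coefficients are reported on the analysis scale. Coefficients above 50 in
  absolute value trigger a separation warning and are capped.
* Product integral: Euler scheme P ← P(I + A Δ); in the per-draw prediction
  loop the outflow of a state is rescaled to its within-step exponential
  1−exp(−hΔ) whenever hΔ > 0.05, so extreme posterior draws cannot drive
  occupancy out of [0,1]. Step 1/120 y by default; the closed-form
  competing-risks benchmark is met to <1e-4 at step 1e-3 and
  Chapman–Kolmogorov discrepancies stay below 10×step.
* Ties: visit jitter makes exact event-time ties measure-zero; the full
  likelihood needs no Breslow/Efron correction.

## 4. Problem sizes used in the test suite

Simulation sizes were chosen as the smallest that make each check sharp:
coefficient recovery on one cohort of n=2000 (the rare direct 1→4
transition is re-run at n=5000 if it accrues fewer than 30 events; at the
default truth it accrues ~200); LASSO selection over 25 replicates of
n=1000 with 5-fold CV (penalty search on a 2-month likelihood sub-grid,
final fits on a 1.5-month grid); mixed-model recovery at n=500; simulator
calibration at n=5000 baseline draws; dynamic-prediction self-consistency
against 2000 forward-simulated futures. Coefficient-recovery checks use the
generator's latent data (exact transition times and noise-free covariate
paths): recovery through the visit-detection layer instead measures the
attenuation of the right-endpoint interval convention (~10–15% on the
largest coefficients at quarterly visits), a property of the observation
design rather than of the estimator.

## 5. Known limitations

* The interval-censored detection times are treated as exact at the
  likelihood level (right-endpoint convention); a proper interval
  likelihood (or midpoint imputation) would reduce the attenuation noted
  above when fitting observed cohorts.
* Post-selection SEs/p-values are conditional on the selected model; the
  re-entry SEs for excluded covariates are descriptive only.
* Joint refinement of the full 18-dimensional model is computationally
  impractical with the generic optimizer; two-stage estimation is the
  operating point at full scale.
* The predictor conditions on "still in q at s" but not on the exact
  within-interval timing of earlier transitions.
* No semi-Markov (clock-reset) variant, frailties, competing mortality, or
  non-Gaussian longitudinal outcomes.
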