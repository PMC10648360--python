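# Methods

## The mapping problem

A preference-based utility index (here the SF-6D, six dimensions with
(6, 4, 5, 6, 5, 5) levels, 18,000 states, utilities in [0.315, 1] under
the Hong Kong tariff) is predicted from a disease-specific profile
instrument (the FACT-L, 36 items in five domains; 34 items scored;
analysis total = sum of domain scores, maximum 136). Two families of
approach are implemented:

- **Direct mapping** regresses the observed utility on FACT-L scores.
- **Response mapping** models each SF-6D dimension's ordinal response and
  converts the predicted level probabilities to an expected utility
  through the tariff.

Both use the design matrices M1–M5 (total; total + total²; domains;
domains + squares; + age and sex). Utility data are awkward for ordinary
regression: bounded above at 1 with a ceiling spike (many respondents at
full health), bounded below by the tariff minimum, and often multimodal.
The estimator families target exactly these features.

## Estimators

**OLS** (`LinearUtilityRegression`). Least squares with a Gaussian
log-likelihood evaluated at the ML (n-divisor) variance so AIC/BIC are
comparable across families. Predictions are the unclamped linear index —
they may leave the feasible utility range, which is part of the standard
comparison against the bounded families.

**Tobit** (`TobitRegression`). A latent-normal model upper-censored at the
ceiling (default limit 1): observations at or above the limit contribute
the upper-tail probability, the rest the normal density. Fitted by
L-BFGS with analytic gradients plus a full-BFGS polish. Predictions are
E[min(Y\*, limit)], the expected censored outcome.

**Beta mixture** (`BetaMixtureRegression`). The utility is rescaled to
y\* = (y − lb)/(ub − lb); by default (lb, ub) = (tariff minimum, 1).
Observations exactly at ub follow a logit boundary probability p(x) on the
full design; interior observations follow a C-component mixture of beta
densities with logit-linked component means μ_c(x), intercept-only log
precisions ln φ_c, and intercept-only multinomial-logit weights. No
lower-bound mass is modelled (cohorts of this kind do not reach the tariff
floor). The truncated variant renormalises each component density to
y\* ≤ 1 − gap/(ub − lb), excising the infeasible interval between full
health and the next feasible tariff value; the default gap is that
tariff distance. The mean prediction is
p·ub + (1 − p)·(lb + (ub − lb)·Σ_c π_c μ_c), with the truncated-beta mean
under truncation. Estimation is direct quasi-Newton maximisation over the
joint parameter vector from a deterministic start (logit-linear fit with
component intercepts spread over the interior quantiles) plus seeded
random restarts (10 by default; 3 inside the study pipeline); components
are relabelled by ascending mean at the covariate mean. The convergence
flag is honest: it requires optimiser success, at least three observations
per parameter, and no precision at its numerical bound — a three-component
mixture on ten observations is reported as non-converged rather than
silently returned.

**Ordered probit** (`OrderedProbit`, `ResponseMappingModel`). One
equation per SF-6D dimension, intercept-free (the cutpoints absorb
location), cutpoints parameterised as κ₁ plus exponentiated increments so
monotonicity holds by construction. Levels never observed in training are
collapsed onto the nearest observed level with a warning, recorded in the
fit, and receive zero predicted probability. Expected utilities assume
independence across dimensions conditional on the covariates — the six
equations are estimated separately, so no dependence is identified anyway.
For a purely additive tariff the expectation is computed in closed form;
tariffs with indicator terms use exact enumeration of the joint state
distribution (chunked; up to 20,000 states) and seeded Monte Carlo beyond
that. Expected-value aggregation is the default; modal-state aggregation
is available as an option.

All parameter counts (for AIC/BIC) include every estimated quantity:
regression coefficients, σ, precisions, mixture weights, boundary-mass
coefficients, cutpoints.

## Numerical choices

Likelihood optimisation runs in the orthonormal column basis of a thin QR
decomposition of the design: raw FACT-L designs mix an intercept, scores
up to 28 and squares up to 784, and a domain score correlates with its
own square at ≈ 0.99, which both cripples quasi-Newton steps and raises
the attainable gradient floor. Coefficients are mapped back through the
triangular factor; the linear predictor is identical in both bases, so
log-likelihoods and cutpoints transfer unchanged. Reported gradient norms
are in the orthonormal basis (the raw-basis gradient is the same quantity
amplified by the column scales); convergence requires optimiser success
and gradient norm < 1e-5. Interior beta observations exactly at the lower
rescaling bound are nudged inward by 1e-6 of the range with a warning
(the beta support is open). Ties in ranking receive mean ranks; this is
what reproduces the published average ranks exactly wherever ties occur.

## Evaluation conventions

- Errors are e = observed − predicted; exceedance rates use strict
  inequality (|e| > 0.05, |e| > 0.10), reported as percentages.
- CCC uses population (n-divisor) moments; Bland–Altman limits use the
  sample SD (n − 1) and mean ± 1.96·SD with closed-interval membership.
- ARV is computed within estimator class over all seven indicators
  (AIC/BIC are only comparable within class); cross-class comparison — in
  particular after cross-validation — uses the five data-based metrics.
- Cross-validation partitions are seeded and near-equal (sizes differ by
  at most 1); fold metrics are averaged arithmetically, not pooled (a
  pooled variant is a one-liner over the stored fold metrics). CCC is
  undefined on single-observation folds and excluded from the average.
- The study pipeline pre-selects the top two models per class by
  full-sample ARV before cross-validating, then ranks the finalists on
  the five CV metrics.

## Synthetic cohorts

No patient-level dataset is publicly deposited, so a Gaussian copula
generator defines the test conditions. An 11-dimensional latent normal
(5 FACT-L domains + 6 SF-6D severities) is drawn from a correlation
matrix; FACT-L domain scores arise by affine transform, rounding and
clipping to instrument bounds; SF-6D levels by ordinal thresholding
(higher latent = worse level); the observed utility by scoring the state
under a tariff; age (truncated normal, 58.29 ± 9.87, range 24–82) and sex
(Bernoulli, 45.8% female, coded 1 = male) enter as centred latent mean
shifts (males shifted modestly toward better health, matching the
published sex/utility association; age loadings default to zero, matching
its non-significance).

Calibration, fixed once: latent affine parameters per domain are
pre-adjusted so the realised post-rounding moments equal the published
domain means/SDs; the FACT-L↔SF-6D cross-correlation block uses the
published domain-by-dimension rank correlations (negated for the severity
orientation) inflated by a common factor 1.06 to undo discretisation
attenuation; the FACT-L inter-domain block (not published) is chosen to
reproduce the published total-score SD with the published pattern
(physical/functional strongly related, social weakest); the SF-6D
inter-dimension block (not published) reflects a shared physical-health
factor. Level thresholds are probit cutoffs of ceiling-heavy level
distributions tuned to the published utility mean/SD and right-shifted
shape; no per-level frequencies are published, so the thresholds are
calibrated to the utility distribution only. At defaults the generator
yields total ≈ 103.0 (SD ≈ 15.6), utility ≈ 0.777 (SD ≈ 0.157), Spearman
(total, utility) ≈ 0.81 at large n.

The shipped synthetic tariff has the instrument's level counts and bounds
exactly (0.315, 1): per-dimension worst-level decrements are fixed
plausible weights summing to 0.685, and within-dimension spacing is a
seeded Dirichlet draw (concentration 8, keeping the implied utility mean
stable across seeds). It is synthetic — its coefficients are not a
valuation study's, and analyses run through it say nothing about the real
Hong Kong tariff beyond structure.

What passing tests therefore show: the estimators recover known
generating parameters, the machinery reproduces every published quantity
that is derivable from published inputs, and the pipeline behaves
coherently on data with the published first- and second-moment structure.
What they cannot show: agreement with the study's headline fitted metrics
(e.g. its cross-validated RMSE), which depend on the unavailable patient
data; item-level FACT-L response structure (the generator works at domain
level); SF-6D level marginals; or clinical covariate effects beyond age
and sex.

## Published coefficient resources

Two coefficient tables ship verbatim as JSON: the ordered-probit M5
system (six equations over domains, squares, age, sex; cutpoint counts
match the instrument's level counts exactly) and the one-component
beta-mixture M3a (logit mean coefficients, log precision, boundary-mass
logit). Two documented interpretation choices: the gender regressor is
taken as 1 = male (consistent with the published positive male/utility
association, and with this package's sex coding), and the beta-mixture
rescaling bounds are fixed at (0.315, 1) — evaluating the published mean
coefficients at the published mean domain scores then reproduces the
published mean utility 0.774, which pins the rescaling. The boundary-mass
intercept (−29.13) implies a near-zero ceiling probability at zero
covariates; whether covariates were centred in the source fit is not
stated, so the coefficients are stored exactly as printed and applied to
raw scores. The response-mapping resource requires a user-supplied tariff
(the real tariff is licensed and not redistributable here); the shipped
synthetic tariff exercises the code path in tests. OLS/Tobit published
coefficients live in supplementary files that are not redistributable;
the JSON schema accepts user-supplied tables of the same shape.

## Problem sizes and defaults

Default study conditions mirror the published design: cohorts of n = 625,
5-fold cross-validation, top-2-per-class preselection, all four families
over M1–M5 with one-component non-truncated beta mixtures as the default
variant set. Recovery checks run at n = 5000 (linear/probit families) and
n = 2000 (beta mixture, generator calibration); the acceptance script
uses the same sizes.

## Known limitations

- Mixture weights are intercept-only; covariate-dependent weights are not
  implemented (the shipped published model has a single component).
- No lower-bound probability mass and no normal-mixture (ALDVMM) family.
- Standard errors / inference are not provided; the package targets
  prediction and model selection, not coefficient inference.
- The item-level FACT-L polarity and unscored-item maps are shipped
  defaults (the standard v4.0 layout) and configurable; users with the
  official scoring manual should verify them before item-level scoring.
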