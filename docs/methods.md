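# Methods

`preyscape` implements a two-stage inference chain for Arctic raptor-prey
surveys: herbivore abundance from time-removal point counts, spatial
density prediction with masking, and a stacked multi-year occupancy model
linking predator territory occupancy to prey densities. This note records
the models, the numerical choices, and what the synthetic data do and do
not establish.

## Covariate preparation

Continuous predictors are standardized by subtracting the mean and
dividing by **two** sample standard deviations (n−1 denominator), so a
one-unit change spans roughly the central 95% of the predictor and
coefficients are comparable with those of binary predictors. The fitted
`Scaler` travels with every model: prediction-time layers are always
standardized with the *training* statistics, never refit. Collinearity is
screened by flagging covariate pairs with |Pearson r| ≥ 0.70; a constant
column is reported as undefined rather than silently passed. Sites whose
windowed mean elevation exceeds 500 m a.s.l. are dropped, with the
boundary inclusive (exactly 500 m is retained). Window aggregation of
percent covers is an arithmetic mean over equal-area cells, which
preserves compositional sums; on the synthetic lattice the DEM aggregation
of the field workflow reduces to block averaging.

## Removal abundance model

Site abundance is Poisson, N_i ~ Poisson(λ_i) with
log λ_i = β'x_i + log A, where A (default 0.5024 km², the printed
survey-area constant for a 400 m radius; configurable) enters as an
offset so exp(β'x) is a density per km². A 10-min count is split into
J = 5 intervals of 2 min; an individual present is first detected in
interval j with probability π_j = p(1−p)^(j−1), logit p = α'w (detection
covariates are site-level, so p is constant across intervals within a
survey), and missed entirely with probability (1−p)^J. Observers enter
detection as a reference-coded factor (first level alphabetically).

With Poisson mixing the interval counts are independent Poisson with
means λ_i π_ij (the multinomial–Poisson factorization); that closed form
is the production likelihood. The explicit latent-N sum truncated at K is
retained purely as a test oracle: the two agree to machine precision once
K is large, and the suite asserts |Δ| < 1e−8 at K = 300. Year is not an
abundance covariate; spatial variation is attributed to habitat.

Optimization is L-BFGS-B on the analytic score from a moment-based start
plus random restarts, followed by a Newton polish (the optimizer's
relative-improvement stopping rule can otherwise leave the score around
1e−4 on large datasets) and automatic re-starts if the score remains
large. Convergence requires sup|score| < 1e−5, no active box bound, and a
positive-definite observed information (finite differences of the
analytic score); all-zero count tables are flagged as boundary fits.
Wald intervals are reported on the link scale; a predictor is called
significant when its 95% CI excludes zero. Marginal-effect curves hold
other covariates at training means (factors at reference) with bands from
the delta method or multivariate-normal coefficient draws — the two are
cross-checked against each other in the tests.

Goodness of fit is a parametric bootstrap of Pearson's χ² over
site × interval cells (expected λ̂_i π̂_ij; cells with expected < 1e−10
excluded, count recorded). Replicates are refitted warm-started from the
original optimum for cost control; the p-value counts ties toward the
null, and ĉ = observed/mean(bootstrap) measures over- (>1) or
under-dispersion (<1).

## Density mapping and territories

Prediction happens on the 800 m lattice (cell area 0.64 km²). Cells with
mean elevation above 500 m, or with any abundance covariate outside the
training range, are masked with recorded reason codes. Per-cell expected
count is exp(β̂'x + log 0.64); intervals come from multivariate-normal
draws of β̂ (default) or the delta method. The study-area total is the sum
of valid-cell expectations with a CI from summing per-draw surfaces —
consistent with an asymmetric log-scale interval. "Summed expected
density divided by corrected area" is implemented as summed per-cell
expected *counts* divided by the area of the unmasked member cells
(summing literal densities and dividing by area again would be
dimensionally inconsistent). Territory membership is by cell center
within a configurable radius of the territory center; the radius has no
silent default because the field protocol's aggregation extent is a study
choice. Masking is applied per species model (each has its own covariate
ranges), so corrected areas are species-specific. All geometry is planar.

## Stacked occupancy model

Each territory-year is an occupancy unit: z_it ~ Bernoulli(ψ_it) with
logit ψ_it = γ'd_i + u_t (d_i = per-territory prey densities, 2-SD
standardized, time-constant; u_t ~ N(0, σ_year²)), and survey detections
y_ijt | z_it ~ Bernoulli(z_it p_ijt) with
logit p_ijt = δ₀ + δ_day·day + v_i, v_i ~ N(0, σ_territory²). A stacked
design with random intercepts was chosen over a dynamic
colonization-extinction model because the series is short and the prey
densities are time-constant. Missing surveys contribute nothing (an
all-missing survey column leaves the likelihood bit-identical, which the
suite asserts); territory-years with no completed survey are dropped and
counted.

The year × territory random effects are crossed, so the marginal
likelihood is computed by a nested scheme: conditional on the year
effects u the likelihood factorizes over territories, and each v_i
integral is evaluated by adaptive Gauss–Hermite quadrature (15 nodes by
default, centered and scaled at the conditional mode found by a damped
Newton iteration). The remaining low-dimensional u integral — one
dimension per season, each informed by ~100 territories and hence nearly
Gaussian — is handled by Laplace. The quadrature rule is frozen while u is
optimized (only the occupancy side then depends on u, making those Newton
steps cheap and their gradients exact) and re-adapted until the
conditional modes stabilize to 1e−5. The scheme is exact when both
variances are zero, reduces to pure adaptive quadrature when one variance
is zero, and a plain joint Laplace approximation is retained as
`method="laplace"` for cross-checks. A pure joint Laplace was rejected as
the production path because at territory SDs near 2.7 its error is
~0.05 log-likelihood units per territory, which cannot meet the package's
own accuracy contract (single-factor marginals within 1e−4 of a 61-node
adaptive Gauss–Hermite oracle). Fifteen nodes keep small instances within
~1e−5 of the oracle; on hundreds of territories at σ ≈ 2.7 the absolute
log-likelihood error is ~3e−4 per territory, negligible against parameter
curvature. Hot kernels are numba-compiled with vectorized numpy
fallbacks.

σ parameters are estimated on the log scale with a floor at 1e−6;
because the profile in log σ is nearly flat near zero, a small estimate
triggers a refit with that variance pinned at the floor and the better
optimum is kept; estimates below 1e−4 are reported as exactly 0 with a
boundary flag (the expected pattern when occupancy does not vary across
years). Wald covariance comes from a central finite-difference Hessian of
the marginal log-likelihood over the free parameters (step 1e−3,
boundary variances excluded); if the matrix is indefinite the
nearly-flat year-variance row is profiled out, and a persistent
near-singular information matrix raises a flat-ridge flag (e.g. one
survey per season with no covariates, where occupancy and detection are
confounded).

The MacKenzie–Bailey GOF tallies detection histories within cohorts
defined by missingness pattern. Expected tallies use the *marginal*
history probabilities (random effects integrated by fixed Gauss–Hermite
quadrature), not conditional modes — conditional expectations adapt to
the observed data and deflate the observed χ² relative to bootstrap
replicates. Cells with expected < 2 are pooled (configurable). With two
surveys the tally has few effective degrees of freedom, so a single
dataset's ĉ is a noisy ratio; calibration claims are made about its
average over datasets.

Prey-density uncertainty is *not* propagated into the occupancy stage:
densities enter as fixed plug-in covariates, matching the two-stage
design. "Marginally significant" is not a formal category; the
coefficient table reports CIs and leaves interpretation to the caller.

## Synthetic-data generator

The generator reproduces the survey design the analysis assumes: 983
point-count sites on an 800 m lattice restricted to terrain ≤ 500 m
(mirroring a protocol that excludes high terrain before placement), five
2-min removal intervals, 97 predator territories monitored over six
breeding seasons (2016–2019, 2021–2022) with two surveys per season and
60 of 1164 surveys missing uniformly at random (the field mechanism —
weather — is unspecified). Vegetation covers come from a spatially
smoothed Dirichlet-style allocation (an unreported "other" class keeps
the five modelled classes summing to ≤ 100%); elevation is smoothed
Gaussian noise rescaled to 0–800 m with a configurable correlation
length. Counts are individuals; group sizes (flocks, colonies) are not
modelled because their distribution is uncharacterized, and observer
movement, double counting and roadside bias are out of scope.

Default coefficients emulate the studied system: a common
willow-ptarmigan-like species (~0.5 detections per site, density driven
by tundra/tussock/tall-shrub cover), scarcer rock-ptarmigan- and ground
squirrel-like species tied to sparse vegetation, low shrub and elevation,
per-interval detection probability around 0.12 declining with season and
wind, three observers with ±0.4 logit offsets, mean occupancy and
detection near 0.5, strong among-territory detection heterogeneity
(σ_territory = √7.46 ≈ 2.73) and no year-to-year occupancy variance
(σ_year = 0). Passing tests on these data demonstrate the estimators are
correct and calibrated *within the model family*; they cannot speak to
field phenomena the generator omits (unmodelled covariates, group-size
clustering, non-random missingness, spatial autocorrelation between
territories).

## Calibration study sizes

The suite's frequentist checks use: 200 replicates of 1000 sites for
removal-model CI coverage and bias; 50 null datasets with 200 bootstrap
replicates each for removal GOF calibration; and 100 replicates of 500
territories × 6 years for occupancy CI coverage (fits warm-started at the
generating values; the removal study uses the production cold start).
Recovery of the zero year variance is judged by the boundary-adjusted
0.5·χ²₀ + 0.5·χ²₁ likelihood-ratio test: the point estimate of a variance
component whose truth is zero lands exactly on the boundary only about
half to two-thirds of the time (classic half-mixture asymptotics), so
"consistent with zero variance" is the meaningful recovery statement.

## Known limitations

- Poisson mixing only; negative-binomial or zero-inflated abundance is
  out of scope (squirrel-type underdispersion is reported by ĉ, not
  modelled).
- Wald intervals for the occupancy model can undercover slightly at
  extreme detection heterogeneity (σ_territory ≈ 2.7 with 12 binary
  observations per territory is a hard regime for quadratic
  approximations).
- Total-abundance CIs treat the coefficient sampling distribution as
  multivariate normal on the link scale.
- Geometry is planar throughout; inputs must share a projected CRS.
- GeoTIFF I/O is not provided; grids and surfaces are CSV.
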