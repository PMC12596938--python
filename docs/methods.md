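# Methods

`avian_itv` estimates how within-population phenotypic variation in bird
morphology (body mass, wing chord) is structured across space and among
species, using a three-stage hierarchical Bayesian pipeline on banding-station
capture records. This note documents the models, the samplers, the synthetic
data used to validate them, and the design choices that were genuinely open.

## Data cleaning

The raw unit is one capture: band id, species, station, coordinates, date,
age/sex codes, body mass (g), wing chord (mm). Cleaning proceeds in a fixed
order:

1. adult males only, captured inside the breeding-season window
   (April–August by default) — avoids age- and reproduction-driven mass
   variation;
2. first capture per band x species x station x year (repeat captures within
   a season are not independent);
3. per station x species x trait, values more than 5 raw median absolute
   deviations (MAD) from the group median are excluded as gross
   measurement/recording errors. The MAD carries no 1.4826 consistency
   constant (configurable). The rule is iterated within each group until no
   value is outside the threshold of the surviving sample; a single pass
   leaves borderline values that a re-run would remove (excluding outliers
   shifts the median and MAD slightly), and iteration makes the whole
   cleaning pipeline idempotent. With MAD = 0 (at least half the values
   tied) nothing is removed and a warning is emitted — removing every
   non-median value would be pathological;
4. inclusion thresholds, iterated to a fixed point: station x species groups
   need ≥ 15 individuals; species need ≥ 5 surviving stations spanning
   ≥ 5° of latitude. Dropping groups can break a species' coverage, hence
   the fixed point.

The MAD rule is applied per station x species group, on the raw trait scale:
within-population spread is the estimand, so outlyingness is judged against
the local population, not the species at large. Records missing one trait
remain available to the other trait's pipeline; the two traits are analysed
by separate, identical model chains. Records are never modified, and every
exclusion is recorded with its reason.

## Stage 1 — group-level CVs with uncertainty (`cv_model`)

Log traits are modelled hierarchically: for individual *i*, station *j*,
species *k*,

    y_ijk ~ Normal(mu_jk, sigma_jk)
    mu_jk ~ Normal(mu_mean_k, sigma_mean_k)      sigma_jk ~ HN(mu_SD_k, sigma_SD_k)
    mu_mean_k ~ Normal(gamma_mu_mean, phi_mu_mean)
    sigma_mean_k ~ HN(gamma_sigma_mean, phi_sigma_mean)
    mu_SD_k ~ HN(gamma_mu_SD, phi_mu_SD)         sigma_SD_k ~ HN(gamma_sigma_SD, phi_sigma_SD)

where HN(m, s) is a Normal(m, s) truncated to positive values. Hyperpriors
are weakly informative on the log-trait scale: Normal(0, 10) on the gamma
location parameters, HalfNormal(0, 5) on the phi scales (both configurable).

The coefficient of variation of a group is the *derived* quantity
CV_jk = sigma_jk / mu_jk, computed per posterior draw, so its posterior mean
(cv_hat) and SD (tau_hat) propagate the joint uncertainty of both
parameters — including its dependence on group sample size, which is what
makes CVs comparable across unequal n. Species-level CVs average the group
CV draws of a species per draw. Note the deliberate convention: this is the
ratio of the SD to the mean of the **log** trait, not the raw-scale CV; both
regressions below inherit it, and it is applied identically everywhere.

## Covariates (`covariates`)

Within-species predictors, one per station x species:

* **Lat** — station latitude, decimal degrees.
* **DistEdge** — km to the breeding-range edge. Range polygons contain
  spurious small gaps (lakes, rivers); the polygon is dilated by a 10-km
  buffer (erasing holes of radius under the buffer), the distance to the
  dilated boundary is measured, and the buffer subtracted. Stations outside
  the range get 0.
* **SpatVar** — spatial CV of a productivity raster (NDVI-like): per-cell
  cross-year averages over all cells whose centers fall within a 10-km
  radius; SD across cells over mean across cells.
* **TempVar** — temporal CV: per-cell CV across years, averaged over the
  cells in the buffer.

DistEdge, SpatVar and TempVar are right-skewed and enter as logs; DistEdge
as log(d + 1 km) because outside-range stations have exact zeros (offset
configurable; the alternative of dropping zeros would discard exactly the
marginal populations of interest). All four covariates are centered within
species (no scaling), so species coefficients are interpretable as local
departures. Species-level predictors — log generation time, log hand-wing
index, log range size, 0/1 migratory status — are centered *and* scaled
across species, including the binary one, so the zeta effects share a
per-SD scale. Variance inflation factors (OLS of each column on the rest)
guard against collinearity.

Sample SDs use n−1 throughout. Geometry is planar in km; lon/lat inputs are
projected by a local equirectangular approximation around each query point
(error far below a percent at 10-km scales). A raster cell belongs to a
buffer iff its center does.

## Stage 2 — within-species regression (`within_model`)

Group CV estimates (x1000, to keep the sampler away from tiny magnitudes)
are regressed on the four covariates with a measurement-error layer:

    cv_hat_jk ~ Normal(theta_jk, tau_hat_jk)        tau_hat treated as known
    theta_jk ~ Normal(alpha_k + x_jk' beta_k, sigma_theta)
    (alpha_k, beta_k) ~ MVN(mu, Sigma)

The reported cross-species effects are the slope components of `mu`. Priors:
Normal(0, 100) on the intercept mean (group CVs x 1000 sit near 25; a
Normal(0, 5) prior there would visibly bias the level), Normal(0, 5) on the
slope means, HalfNormal(0, 5) on sigma_theta, and a conjugate
inverse-Wishart(p + 2, I) on Sigma — the weakest proper conjugate choice.
An LKJ-correlation prior with half-normal scales is the common
Hamiltonian-Monte-Carlo formulation of the same structure; with a Gibbs
sampler the inverse-Wishart is the natural equivalent, and at 20+ species
the likelihood dominates either.

## Stage 3 — among-species regression (`among_model`)

Species-average CVs (x1000) are regressed on the life-history covariates
with phylogenetically correlated intercepts:

    cvsp_hat_k ~ Normal(xi_k, tausp_hat_k)
    xi_k ~ Normal(kappa + eta_k + z_k' zeta, sigma_xi)
    eta ~ MVN(0, sigma_phylo^2 P)

P is the Brownian-motion correlation implied by the tree: for an ultrametric
tree of depth T, P_ab = shared root-to-ancestor path length / T =
1 − d_ab / 2T with d_ab the patristic distance. Two conventions were open:
sigma_phylo is taken as an SD (covariance = sigma_phylo² P), and P is
computed from a single supplied tree (averaging over posterior tree sets is
out of scope). A non-ultrametric tree triggers a warning and uses the
maximum root-to-tip depth as T. An exponential-decay kernel would be an
alternative correlation construction; the shared-path form is the standard
variance-covariance-to-correlation construction under Brownian motion and
is what the identity-matrix (star tree) and 3-taxon oracles pin down.

## Samplers

All three models are fitted by blocked Gibbs sampling, built from three
primitives (module `sampling`): conjugate normal/MVN draws in precision
form, a univariate slice sampler (Neal 2003; stepping-out + shrinkage)
vectorised over conditionally independent scalars, and
Metropolis interweaving moves where a centered parameterisation creates
funnels. Specifics:

* **cv_model** — conjugate updates for all location parameters, slice
  updates for all scales (the half-normal truncation normaliser depends on
  both its arguments, so neither is conjugate). Two interweaving moves per
  species per sweep jointly rescale/translate the group SDs with
  (mu_SD_k, sigma_SD_k), which roughly doubles the effective sample size of
  the worst-mixing parameters.
* **within_model** — theta is integrated out analytically (marginally
  cv_hat ~ N(Xb, sqrt(tau² + sigma_theta²))), and the species coefficients
  are additionally integrated out of the `mu` update by per-species
  Woodbury blocks; Sigma is conjugate inverse-Wishart; sigma_theta is
  slice-sampled on the marginal likelihood. theta draws are reconstructed
  conditionally for recording.
* **among_model** — both latent layers (xi, eta) are integrated out;
  the Gibbs state is just (coefficients, sigma_xi, sigma_phylo), which
  mixes nearly independently; latents are reconstructed per kept draw.

Because draws are exact conditional samples, there is no step-size
adaptation and no divergence concept; the gate records 0 divergences for
report compatibility.

Default chain settings are 4 chains x 50,000 iterations (20,000 warmup,
thinning 20) for the CV model and 4 x 5,000 (2,500 warmup) for the
regressions. Tests and the acceptance script run 4 x 1,500–4,500 sweeps —
with conjugate blocking the chains reach the same gates at a fraction of
the sweeps an off-the-shelf sampler would need, and the suite stays within
desk-scale runtimes. Convergence gates are stage-specific: rank-normalised
split R-hat ≤ 1.05 and bulk ESS > 400 for the CV model's group parameters;
R-hat ≤ 1.01, ESS > 400 for both regressions. A failed gate flags the
result (and everything downstream) as not converged; it never silently
passes. Summaries report the posterior mean, the equal-tailed 89% credible
interval (5.5%/94.5% empirical quantiles, linear interpolation — quantile
conventions differ, so this is pinned), p(>0) as the fraction of draws
strictly greater than zero, R-hat and ESS (via arviz).

## Synthetic data (`synth`)

The generator is the pipeline's generative inverse. A pure-birth (Yule)
tree with strictly positive branch lengths is rescaled to a configurable
depth; species covariates are drawn in empirically observed ranges
(generation time 1.8–4.3 yr, hand-wing index 11.4–53, range size equal to
the generated polygon's area, ~88% migrants); phylogenetic intercept
deviations are drawn MVN(0, sigma_phylo² P) on that tree. Stations are
placed in a planar-km domain spanning 30–60° latitude; a productivity
raster is generated around each station with station-specific lognormal
spatial/temporal heterogeneity; range polygons are station bounding boxes
with random 5–400 km margins. Crucially, the covariates that drive the
truth are *computed from that landscape with the same code the pipeline
uses*, so the assembled design matrix equals the generator's by
construction and geometry bugs cannot cancel.

Each group's true CV follows the stage-2 structure
(theta = alpha_k + x'beta_k + noise, on the CV x 1000 scale, floored at 2);
group log-trait parameters are then set so that sigma_jk / mu_jk equals
that CV exactly, with log-mass means near log 30 g so CVs sit near the
0.02–0.03 magnitude typical of avian body mass. Wing values are generated
isometrically with exactly one third of the mass CV, giving the x3
mass-vs-length ratio oracle. Species intercepts follow the stage-3
structure, so one dataset grounds every stage. Defaults: 20–40 individuals
per group, effects (−0.15, 0.15, 0.28, 0.07) within and (−2, 0, 0.5, 1)
among on the CV x 1000 scale, sigma_theta = 1, sigma_xi = 1.5,
sigma_phylo = 2, grand mean 25.

Contaminants are injected with recorded band ids: gross outliers at ±8
group SDs (the 5-MAD threshold sits near 3.4 sigma, so all must be caught),
within-season repeat captures, and non-adult-male records — making filter
recall measurable, not assumed.

For tests that probe the regression stages in isolation,
`make_group_cv_observations` emulates stage-1 output by drawing
cv_hat ~ Normal(true CV, tau_hat) with tau_hat = 0.67 x cv/sqrt(2n); the
0.67 matches the measured ratio of the hierarchical model's posterior SD to
the naive SE at 20–40 individuals per group (partial pooling across a
species' stations buys about a third). This emulator feeds the regression
exactly the observation model it assumes.

What the generator does **not** emulate: migration phenology and
within-season mass dynamics, observation-effort variation, spatial
autocorrelation of stations beyond the raster construction, taxonomic
errors, and real range-map topology. Passing tests therefore demonstrate
correctness of the estimators under the stated model, calibration of the
uncertainty, and the deterministic data-handling rules — not robustness to
every failure mode of field data.

## Outlier trimming and CV coverage (known limitation)

The 5-MAD rule guards against measurement and recording errors, but at
moderate group sizes (15–40 individuals) the MAD itself is a noisy spread
estimate: whenever it comes out low, the threshold tightens to below three
standard deviations and legitimate tail values are trimmed. Trimming the
extreme fraction of a clean normal sample deflates its SD, so group CVs are
estimated slightly low, and the 89% intervals for true group CVs —
correctly sized around a slightly low center — cover at the lower end of
their nominal rate. The acceptance script's interval-coverage quantity
measures the net effect. Any protocol that excludes MAD-flagged values
before estimating a variance component inherits this; it fades as group
sizes grow.

## Two-stage attenuation (known limitation)

Feeding stage-1 *posterior means* into stage 2 attenuates covariate effects
toward zero: partial pooling shrinks each group's CV toward its species
mean, so the covariate-related variation in cv_hat is a shrunken version of
the variation in the latent truth, and the observation layer
cv_hat ~ N(theta, tau_hat) does not undo that bias. At 20–40 individuals
per group the measured shrinkage is substantial (regression slopes of
cv_hat on true CV around 0.6 within species); the acceptance script
reports a full two-stage latitude-effect estimate alongside the stage-2
recovery estimate so the attenuation is visible in numbers. The effect
weakens as group sizes grow (likelihood dominates the pooling prior). This
is a property of the two-stage design itself — any pipeline that summarises
a hierarchical posterior into (mean, SD) pairs before regressing inherits
it — and argues for interpreting within-species effect magnitudes from such
pipelines as conservative.

## Numerical notes and degenerate inputs

* Groups need ≥ 2 observations (fits refuse otherwise); production filtering
  guarantees ≥ 15.
* A non-positive posterior draw for a group's log-scale mean aborts CV
  derivation — log-gram/log-mm means of real traits are far from 0, so this
  only signals wrong units.
* P is eigenvalue-checked; exact singularity (zero-length splits) receives a
  1e-8 diagonal jitter and renormalisation.
* Zero MAD, constant covariate columns, missing stations/polygons/tips all
  raise with the offending identifier named.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawns; identical configuration yields
  byte-identical datasets and numerically identical reports.
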