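# Methods

This note documents the statistical model behind `msfr`, the defaults the
package ships with, what the synthetic study system does and does not
emulate, and the numerical choices a maintainer would want to know about.

## The functional response and its identifiability

The package models diet composition, not consumption rate.  Starting from a
Holling-type consumption rate `c_i = α_i N_i^m / (1 + Σ_j α_j t_j N_j^m)`,
taking proportions cancels the common denominator:

    c_i / Σ_j c_j = α_i N_i^m / Σ_j α_j N_j^m .

Three consequences shape the whole design:

- **Handling times cancel** and are unidentifiable from composition data;
  they appear nowhere in the package.
- **Catchability is absorbed.**  With survey index `B_i = N_i / q_i`, the
  proportion form becomes `a_i B_i^m / Σ a_j B_j^m` with
  `a_i = α_i q_i^m`.  Attack rate and catchability are confounded by
  construction, so `a_i` is interpretable only as preference *with respect
  to the index used*, and only ratios of `a` are meaningful.  One reference
  species (sandeel) is therefore pinned at `a = 1` and the rest get a wide
  uniform prior U(0, 10); the posterior summary reports the fraction of mass
  within 5% of the upper bound so an over-constraining prior is visible.
- **Subsets are consistent.**  Restricting to any subset of prey and
  renormalising gives exactly the subset-only model, so species without
  availability data (gobies and other small prey) can be pooled into an
  "other" category without biasing the ratios among the kept prey.  This
  identity is enforced to 1e-12 in the tests.

`m` is treated as fixed per model run — 1 (type II) or 1.5 (type III) — and
the two are compared by DIC; continuous estimation of `m` is out of scope.

## Observation model

The likelihood for an individual's composition `x` is Dirichlet with mean
`p(a, m, B)` and concentration `τ`: `x ~ Dir(τ p)`.  `τ` absorbs
overdispersion across individuals and gets a uniform prior on (1, 10³),
sampled on the log scale.  The density only ever consumes `log x`, and the
observation container stores log-proportions: when `τ p_i < 1` for a rare
prey — routine at realistic concentrations — most of that component's
probability mass lies below floating-point underflow, and any fixed floor
on `x` truncates the data and biases the small attack rates upward (our
calibration experiments showed 60% instead of 95% interval coverage for
the rarest prey before this was fixed).  Simulated compositions are
therefore drawn in log space via the log-gamma identity
`G = Gamma(α+1)·U^{1/α}`, and flooring (default 1e-6, then renormalise) is
applied only to structural zeros of real stomach data, which the Dirichlet
cannot represent; predicted proportions are floored the same way so a
zero-availability species cannot produce an infinite density.  The
Dirichlet itself is a modelling choice, not a derived result: composition
data aggregated from otolith counts have no canonical likelihood, and the
Dirichlet is the minimal exchangeable choice on the simplex with a single
dispersion parameter.

**Availability uncertainty** is propagated by per-iteration plug-in draws:
at every Metropolis step fresh availability matrices are drawn from
independent zero-truncated normals (mean and SD from the availability
stage) and the per-individual likelihood is averaged over them — a Monte
Carlo estimate of the availability-marginalised likelihood — before the
current and proposed parameters are compared on the same draws.  The
availabilities are *not* treated as latent variables with their own
posterior: the redraw scheme keeps the availability distribution fixed at
its estimated form, which is deliberate — the estimation uncertainty comes
from an upstream stage and should not be revised by the diet data.  The
default is four draws in antithetic pairs: a single draw per iteration
(the naive scheme) leaves a Monte-Carlo-within-Metropolis bias that
depresses rare-prey interval coverage to ~83%, while four antithetic draws
restore nominal coverage in the calibration experiments at about a third
of the cost of ten plain draws.

## Sampler

Adaptive random-walk Metropolis on `(log a_j, log τ)`, two chains by
default.  During burn-in the proposal is a multivariate normal whose
covariance is the running empirical covariance of the chain (updated every
25 iterations over a 500-iteration window) and whose overall scale follows
a Robbins–Monro recursion targeting 30% acceptance; both are frozen at the
end of burn-in, so the post-burn-in chains are valid fixed-kernel
Metropolis.  Chains start from a method-of-moments estimate (per-observation
`a_j` ratios, median over observations), which makes short burn-ins
(200–400 iterations) sufficient in practice.  Split R-hat is computed per
parameter; values above 1.1 produce a warning, and zero post-burn-in
acceptance is an error.  With a fixed seed the chains are bit-for-bit
reproducible; the seed stream is split per chain.

**DIC** uses deviance `D = −2 log L` with availability fixed at its means —
both along the trace and at the plug-in posterior mean of `(a, τ)` — giving
`pD = D̄ − D(ā)` and `DIC = D̄ + pD`.  Evaluating the trace deviance at the
availability means (rather than at each iteration's draw) keeps `pD` a
measure of parameter uncertainty rather than of injected availability
noise.  DICs within 2 units are reported as near-ties, with the smaller-pD
model preferred.

## Foraging range

Tracks are cut to the study population (positions south of 57.30°N *and*
east of 9.37°E are excluded), linearly interpolated to 6-hour steps in a
local azimuthal equidistant projection (gaps > 48 h split the track), and
summarised as minimum-enclosing-circle diameters over consecutive
non-overlapping windows of 2, 4, 6 or 8 days.  Non-overlapping windows are
the default to limit pseudo-replication; a sliding stride is available.
The MEC uses Welzl's expected-linear-time algorithm and is tested against an
exhaustive oracle over all 2- and 3-point support circles.

The range model is a gamma GLM with log link fitted by IRLS (for this
family/link the working weights are identically 1).  Timeframe enters as a
categorical factor; age, sex and calendar quarter complete the main
effects; all two-way interaction subsets are searched exhaustively by AIC
(the AIC uses the gamma log-likelihood at the ML shape, +1 parameter).
VIF is computed on the main-effects design with the conventional threshold
of 4; flagged columns are reported, and excluded from interaction
candidates only if configured — the balanced designs this model sees in
practice sit near VIF 1.  A GLMM with an individual random effect is
deliberately not implemented.

The buffer for a stranding takes the predicted MEC **diameter** as its
**radius** — a doubling that covers the unknown direction of travel before
stranding.  This is the contract; no further inflation happens anywhere.

## Prey availability

Catch counts per length class become biomass per unit effort via
`BPUE = Σ_{L<400} a ((L + 0.5e)/10)^b · CPUE_L` with lengths in mm, the
class midpoint converted to cm, and per-species allometric `(a, b)` and
class resolution `e ∈ {5, 10}` mm.  Only classes below 400 mm (consumable
size) are counted.

`log(BPUE + δ)`, δ = 1 g by default (zeros occur), is smoothed with a
penalized additive Gaussian model: a cubic P-spline in depth plus a
tensor-product B-spline basis over (lon, lat, year) with one
second-difference penalty per margin.  Each smooth is sum-to-zero
constrained; smoothing parameters minimise the Gaussian REML criterion
(Nelder–Mead over log-λ from two starts; GCV available).  The fitted object
carries the Bayesian posterior covariance `σ²(XᵀX + S)⁻¹`, which the buffer
integration resamples (200 draws by default) to attach an SD to each
availability index; on a fixed fit this SD agrees with the delta method
within sampling error.  Land is handled by masking: land cells are excluded
from every prediction and integration; no boundary-aware (soap-film-style)
basis is used, which is adequate here because the MSFR consumes only
buffer-integrated indices, not the fine structure of the field at the
coastline.  Predictions clamp the linear predictor to the range fitted at
the training hauls: the tensor basis extrapolates into unsurveyed corners
of the grid, and exponentiating an extrapolated log surface otherwise
produces arbitrarily large availability for a single buffer.

Sandeel is not sampled adequately by the trawl survey, so its availability
is an annual spawning-stock biomass index, spatially constant within each
year (SD 0 by default, a CV is configurable).  The "other" category has no
survey either and is assigned a constant level.

**Rescaling.**  All availability indices are rescaled so the maximum is
100.  The pipeline default is per-species (each species' maximum maps to
100): buffer-integrated grams, an SSB in tonnes and a dimensionless
constant are not on a common scale, and a single global factor would let
whichever source has the largest numbers dominate.  Per-species rescaling
preserves within-species ratios — the quantity the functional response
responds to — and pushes the per-species scale into `a_i`, which is already
index-relative.  A global single-factor rescaling (which preserves
cross-species ratios too) is available where all inputs share a scale.

## Diet composition

Measured otolith lengths are multiplied by wear-grade correction factors,
then an otolith-length→fish-mass power law gives prey mass per record.
Both tables are configuration (shipped examples live in `msfr/data/`); the
published sources for such factors do not print them, so nothing in the
package depends on specific values.  Carcasses with decomposition code ≥ 4
are dropped.  Species at or above 5% of pooled reconstructed mass are main
prey (boundary inclusive); everything else, plus any species configured as
unavailable (gobies), merges into "other" — mass-preserving by
construction.  Sampling error comes from a nonparametric bootstrap with
individuals as the sampling unit, stratified by season; strandings in
November–April count as survey quarter 1 and May–October as quarter 3,
matching the survey's coverage.  A single-replicate bootstrap returns SD 0
with a warning rather than failing.

## The synthetic study system

`synthetic_data` generates all four input tables from a `GroundTruth` whose
defaults mirror the harbour-porpoise study system: six prey categories with
attack rates (sandeel 1, sprat 0.238, whiting 0.120, herring 0.101, other
0.089, cod 0.058), a type III response (m = 1.5), 455 strandings, ~54
tagged animals, and a range GLM whose coefficients reproduce the reported
pattern (larger ranges for longer windows, females, adults, and spring).

- **Region**: a 4°×3° coastal rectangle with a diagonal coastline to the
  south-east, gridded at 5 km; synthetic bathymetry deepens offshore.
- **Prey fields**: sums of 2–3 Gaussian bumps (σ 25–60 km, amplitude
  50–400 counts/tow) over a baseline of 20, redrawn per (year, quarter) —
  so spatial pattern changes with time, as the space-time smoother assumes.
- **Surveys**: haul CPUE per length class is
  `w_L · f(x, t) · H · Z_L` with stationary class weights `w_L`, a mean-one
  lognormal haul effect `H` (σ = 0.6) shared across classes — catches of
  one tow rise and fall together — and mild class-level noise (σ = 0.3).
  Expected total CPUE equals the true surface.
- **Tracks**: correlated random walks at 6-h steps confined to sea, with
  gamma step lengths whose scale depends on age and sex through the same
  coefficients the range GLM is asked to recover.
- **Strandings/stomachs**: stranding locations sit on the coastline; each
  stranding's *true* availability is the true field summed over its true
  buffer (sandeel: the SSB index; "other": a constant, matching the fitting
  stage's assumption).  Diet-share probabilities follow the generative
  functional response; a lognormal total stomach mass (mean 1 kg, CV 0.5)
  is allocated to species with item-count probabilities ∝ p_i / (mean item
  mass)_i, so the *expected mass share* equals p_i exactly.  Each item
  becomes an otolith record whose observed length is the corrected length
  divided by a uniformly drawn wear-grade factor — reconstruction is
  exactly invertible.  Decomposition codes span 1–5 so the freshness filter
  is exercised.
- **Sandeel SSB** defaults to 4.8k–21.6k (uniform per year), the same
  magnitude as typical buffer-integrated field sums, so no species
  dominates availability by construction.

What the generator does **not** emulate: oceanography and tides, carcass
drift, ARGOS location error, otolith measurement error, survey gear
selectivity beyond the < 400 mm cut, and any real coastline geometry.
Passing recovery tests therefore demonstrate the estimators' correctness
under the stated generative assumptions, not robustness to these field
effects.

## Problem sizes and reproducibility

The statistical recovery checks run at deliberately chosen sizes: 400
strandings per dataset with chains of 2 × 2,000 iterations (300 burn-in)
for credible-interval coverage over 100 replicates, and 2 × 800 iterations
for the 50-replicate DIC shape-selection check — the model-comparison
signal is large (hundreds of DIC units at n = 400), so short chains
suffice there.  The full-study configuration (2 chains × 10,000 iterations
after 1,000 burn-in) is the default of `fit_mcmc` and is what an analysis
of real data should use.  Every stochastic component takes an explicit
seed; pipeline stage seeds are spawned from one root seed, and rerunning
any configuration reproduces outputs bit-for-bit.

## Known limitations

- The Dirichlet concentration is shared across individuals; stomach-size
  dependent overdispersion is not modelled.
- The availability-marginalised likelihood is estimated by finitely many
  draws per iteration, so a small Monte-Carlo-within-Metropolis bias
  remains in principle; at the default four antithetic draws it is
  undetectable in 60-replicate calibration runs, and the deviance trace
  (availability at means) is unaffected.
- The end-to-end synthetic pipeline attenuates the type II/III contrast
  relative to direct simulation, because estimated availabilities carry
  errors-in-variables; shape selection is therefore validated on the
  estimator-matched simulation, and the pipeline test asserts completeness
  and determinism.
- REML here assumes a Gaussian response on the log scale; a Tweedie or
  zero-inflated alternative for hauls with many zeros is not implemented
  (δ-offset logs are used instead).
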