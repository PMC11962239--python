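# Methods

This note records the models, numerical choices and known limitations of the
package, in the order the pipeline runs them.

## Synthetic study system

The generators define the conditions every test and the acceptance script
run under. They emulate the *statistical* structure of a boundary-current
shelf system, not its physics.

**Ocean fields.** Each day carries three co-registered 0.1° rasters over the
study box (36.6–35.8° S, 149.8–150.8° E; 8 × 10 cells). SST is a meridional
gradient (warmer toward the equatorward boundary) plus a warm tongue
intruding from the northeast whose daily strength follows a clipped AR(1)
process, plus white noise. The EAC-origin probability is a logistic
transform of the SST anomaly relative to the no-intrusion climatology, with
a configurable baseline probability at zero anomaly; across cell-days this
makes the SST–EAC correlation strongly positive (≈ 0.85–0.90 under the
default regimes, checked by a property test requiring ≥ 0.8). SST SD is
generated as its own field — thermally uniform inside the tongue, patchier
outside — giving the weak negative EAC–SST SD correlation the analysis
expects; deriving it as |cell − daily spatial mean| from a warm-tongue SST
field would force the wrong sign, so that derivation is reserved for real
SST rasters (`habitat.sst_sd_from_sst`). Three regimes ("2012" cool with a
weak tongue, "2013" coldest and most variable, "2014" warm and
EAC-dominated) set the interannual contrast; under them mean EAC dominance
spans ~1% to ~65–80% of cells.

**Tracks.** Birds run a biased correlated random walk at the tag's fix
interval: step length is gamma-distributed around
`step_scale · interval/720 s`, heading mixes persistence, an optional
compass bias, attraction to an optional terrestrial point, and a homing
pull that grows as the distance home approaches what the remaining steps
can cover — every bird ends every day at the colony (single-day trips, as
for chick-guarding penguins; the flyers use the same engine with larger
ranges). Habitat avoidance is a Metropolis acceptance on the log of a
logistic preference `1/(1 + exp(slope·(x − threshold)))` in EAC probability
and SST SD, so long-run usage follows the logistic curve itself — this is
what makes the injected avoidance recoverable by the downstream selection
models. Fixes are clipped to the grid. Defaults: 10 birds per species-year,
15-day windows, 6 h of foraging per day starting 06:00 UTC (the active-day
length is a free parameter of the system; 6 h is a typical central-place
foraging day during chick rearing), 4-min fixes in the first two years and
30-s in the third. The 15-day windows are the package's own scale choice
for a self-contained runnable study; the engine accepts arbitrary windows.

**Isotopes.** Species-year clusters are bivariate normals in (δ13C, δ15N).
Centres follow the fitted species contrasts (tern −16.8 ‰ δ13C, penguin
−1.1 ‰ and gull −1.9 ‰ below it; gull ~2.4 ‰ lower δ15N) with a small
year shift in δ15N only — so the two-element mixed models should find
species effects in both elements but a year (random) effect only in δ15N.
Covariances give the gull the widest, most stable niche and move the tern's
(largest in the first year) and penguin's (largest in the warm year) spread
across years. Laboratory replicate SDs (0.2 ‰ 13C, 0.3 ‰ 15N) are carried
as metadata and can optionally be added as measurement noise; they are not
propagated into the ellipse likelihoods.

**What the generator does not emulate** — and hence what green tests do not
show about real data: hydrodynamics, tides and wind; GPS measurement error
and irregular fix gaps; diving behaviour; inter-individual heterogeneity
beyond the archetype; land masking (the terrestrial attractor is a point);
diet-to-feather isotope dynamics and moult phenology.

## Track standardisation

Fixes are binned into half-open 12-min windows anchored at each bird-day's
first fix; the centroid is the arithmetic lon/lat mean and carries its fix
count (3 at 4-min sampling, 24 at 30-s sampling). Anchoring at the first
fix (rather than the clock hour) keeps the first window full regardless of
release time; half-open intervals prevent double counting. Plain coordinate
means are valid at this sub-degree extent but unsuitable near the
antimeridian. Trip statistics use the haversine with R = 6371.0 km.

## Utilisation distributions

The UD is a bivariate Gaussian product kernel evaluated at cell centres and
renormalised over the grid (boundary truncation is absorbed into the
normalisation). The default bandwidth is the reference rule
`h = σ̂·n^(−1/6)` per axis with σ̂ the mean of the two axis SDs — the same
philosophy as the href default of standard home-range software, made
explicit and overridable. Estimation is done in degrees on the lat/lon
grid; at this extent the ignored anisotropy (cos latitude ≈ 0.81) is small
relative to the bandwidth and is documented as a limitation. The 95%
contour is the greedy minimal highest-density cell set (ties broken by
stable cell order, with a 1e-12 slack so exact-tie uniform cases stay
stable); cell areas use the spherical formula
`(111.195·res)²·cos(latitude)`. Spatial overlap between two contours is the
area-weighted intersection-over-union × 100 — symmetric and bounded, chosen
because it treats both species symmetrically; directional (% of A in B)
overlaps are also available. A convergence test checks the 95% KUD area of
10⁵ normal draws against the analytic ellipse area π·χ²₂(0.95)·√det Σ
(within 10%; measured ≈ +2.6%, the KDE's bandwidth inflation).

## Habitat models

Presence/absence is defined per species-day over all study-area cells (the
full grid is "available"; no accessibility weighting). Both mixed models
use the fixed structure species × EAC probability + species × SST SD, a
random intercept on sampling day (continuous across years), and
log10(number of birds tracked that day) as an offset — log base 10 as the
model formula is written, an unusual offset for a binomial model but
followed as specified. Reported per-species slopes are linear combinations
of the treatment-coded coefficients with SEs from the coefficient
covariance.

The binomial random-intercept model is fitted in-package by maximising the
Gauss–Hermite marginal likelihood (25 nodes, analytic gradients, L-BFGS-B
with σ ≥ 0): no installed Python package provides a frequentist binomial
GLMM. Wald SEs come from the observed information of the fixed effects at
the optimum, conditional on σ̂ (the standard mixed-model convention); the
variance component is tested by a likelihood ratio against the plain GLM
with the 0.5·χ²₁ boundary mixture. Calibration is verified by simulation:
slope recovery within 2 SE in ≥ 90% of 100 replicates and a type-I error of
3–7% over 500 null replicates (the observed rate was ≈ 4–5%; the
simulation sizes — 20–25 days, 40–50 cells, two species — were chosen to
make 500 replicate fits routine). Gaussian models go through statsmodels
`MixedLM` (ML); because the mixed model nests OLS at zero variance, a fit
whose log-likelihood falls below the OLS fit (or is non-finite — both
happen on boundary cases) is replaced by the OLS solution, which is then
the exact ML estimate. "Deviance explained" is 100·(1 − residual/null
deviance) of the *fixed* linear predictor (random effects at zero), the
null being intercept-plus-offset; the method is recorded in the fit
metadata since several definitions circulate.

EAC dominance is the percentage of cells strictly above the 0.5
EAC-probability threshold; its natural log uses ε = half the smallest
nonzero observable percentage (0.5·100/n_cells) so zero-dominance days stay
finite and ordered below all others. Year comparisons are one-way ANOVA
plus Tukey HSD.

## Environmental niche

The PCA is calibrated on **all** cell-days of the comparison year (not just
occupied cells): axes are then identical for every species and iteration,
and per-species densities differ only through their occurrences. Variables
(lat, lon in degrees, EAC probability, SST SD) are centred and scaled to
unit variance (correlation PCA); component signs are fixed by making each
component's largest-magnitude loading positive, so scores are reproducible.
Occurrences are binned at 0.05° per day, attached to their 0.1° cell-day
covariates, projected, aggregated to occupied cell-days (so the density is
invariant to how occurrences split across individuals — this also makes
the full-population resampling identity exact), and smoothed with a
Gaussian kernel on a 100 × 100 grid spanning the calibration score extent
(+5% margin); the bandwidth uses the same reference rule as the UDs with
Kish's effective sample size for the weights. Schoener's D is computed on
the renormalised grids.

Resampling draws 8 individuals per species with replacement, 100 times;
when the requested subsample size reaches the number tracked, every
individual is used exactly once, so one iteration at full population
reproduces the unresampled pipeline exactly (a tested identity). Iteration
enters the sensitivity ANOVA as a categorical factor alongside pair and
year.

## Isotopic niche

δ values are `(R_sample/R_standard − 1)·1000` (‰, vs V-PDB for carbon and
air for nitrogen). SEA is π·√det of the n−1 sample covariance; SEAc
multiplies by (n−1)/(n−2), which is why n ≥ 3 is required throughout. The
Bayesian SEA_B uses the exact conjugate marginal posterior of the
covariance — inverse-Wishart(n − 1 + prior_df, S + 0.01·I) after
integrating a flat mean out of the likelihood (one observation is consumed
by the mean, hence n − 1) — sampled directly rather than by MCMC: exact,
fast and seed-stable. The default prior_df = 0 is the Jeffreys-reference
limit, chosen because it gives near-nominal (≈ 94–95%) frequentist coverage
of the 95% credible interval in simulation, whereas a proper
inverse-Wishart with 3 prior df concentrates the posterior enough to drop
coverage to ≈ 90% at n = 30; positive prior_df remains available. 95%
confidence ellipses use semi-axes √(λᵢ·χ²₂(0.95)) with the rotation of the
leading eigenvector. Ellipse overlap between species is not computed.

## Pipeline and reproducibility

One master seed drives everything through SHA-256-derived child seeds per
generator and stage (all below 2³¹). CSV outputs use fixed column orders
and 6-significant-digit floats, so a fixed seed reproduces byte-identical
files (a tested property). The manifest (config hash, package version,
per-stage output checksums and wall times) is written on success *and*
failure, with the failing stage and cause recorded. "Years" are labelled
date ranges, not calendar years, so real sampling windows can be
configured directly. NetCDF export uses the classic format via the scipy
backend; single-day rasters export as ESRI ASCII grids (a plain-text
raster format GIS tools read directly).

## Known limitations

- UDs and PC densities use a single isotropic bandwidth; no cross-validated
  or plug-in bandwidth selection.
- Habitat availability is the full study grid; no accessibility or
  distance-to-colony weighting beyond what the day random effect absorbs.
- The degree-space KDE slightly distorts east–west distances (cos latitude);
  acceptable at this extent, wrong for large or high-latitude domains.
- The binomial GLMM supports one random intercept only (all this analysis
  needs); no crossed or nested random effects.
- Schoener's D is the only niche-overlap index implemented; no
  equivalency/similarity permutation tests.
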