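# Methods

This note documents the models, algorithms and design choices behind
`cslink`, a package for linked population / health-facility analysis of
caesarean delivery: which quantities are computed, under which
assumptions, and what the synthetic-data experiments do and do not
demonstrate.

## The setting

The analysis design links two national surveys: a household survey of
women nested in sampled clusters (census enumeration areas with GPS
coordinates) nested in administrative regions, and a facility census
recording each hospital's location, caesarean provision, and service
indicators. Clusters are joined to the nearest caesarean-providing
hospital by straight-line distance in a projected planar frame, giving
each cluster a distance covariate and the nearest facility's
service-environment scores. All coordinates in the package are planar
kilometres; geodesic computation is out of scope by design, as the
source data are customarily projected before analysis.

## Three-level Bayesian logistic model

The binary outcome (most recent birth delivered by caesarean section)
follows

  logit P(y_ij = 1) = x_ij' β + u_c(ij) + v_r(ij) + Σ_k x_ij,k (a_k,c(ij) + b_k,r(ij))

with cluster random intercepts u ~ N(0, σ_C²), region random intercepts
v ~ N(0, σ_R²), and optional per-covariate random slopes a_k, b_k at
both levels with independent variances (no slope–intercept correlation;
this mirrors the per-variable cluster/region variance reporting the
analysis targets). Priors are weakly informative: N(0, 1000) on every
fixed effect, InverseGamma(0.01, 0.01) on every variance.

### Sampler

Posterior exploration is Metropolis-within-Gibbs:

* **Fixed effects** — component-wise Gaussian random-walk Metropolis.
* **Random effects** — blocked random-walk sweeps: all cluster effects
  are proposed and accepted/rejected simultaneously, which is exact
  because clusters are conditionally independent given the fixed and
  region effects (likewise regions given clusters). This gives the
  per-group acceptance behaviour of a scalar update at vectorised cost.
* **Variances** — conjugate inverse-gamma Gibbs draws from the full
  conditional IG(α + m/2, β + SS/2).

Step sizes adapt by a Robbins–Monro rule toward the 0.2–0.5 acceptance
band *during burn-in only*, so the retained chain comes from a fixed
transition kernel. Chain defaults are 175,000 iterations, 25,000
burn-in, thinning 25; a reduced 15,000 / 5,000 / thin-5 configuration
(`McmcConfig.test_scale()`) is used throughout the test suite and is
adequate for the synthetic-data problem sizes (effective sample sizes of
a few hundred for variance components).

Retained-draw accounting is ambiguous in common software: discarding
burn-in and then thinning gives floor((175,000 − 25,000)/25) = 6,000
draws, while thinning the whole run gives 175,000/25 = 7,000. Both
modes are implemented (`count_mode="post_burnin"` / `"total"`); the
default is post-burn-in thinning.

### Recentring of stored draws

With a centered parameterisation, the intercept and the means of the
random-effect blocks are only weakly identified jointly. The sampler
state is left untouched, but *stored* draws are recentred per draw:
cluster effects are centred within their region (means moved into the
region effect), region effects are centred overall (mean moved into the
corresponding fixed effect), and the same within-parent scheme applies
to random slopes. The map leaves every linear predictor — hence the
likelihood, the deviance and DIC — unchanged; it only fixes the
reported decomposition. A consequence for simulation studies: the
reported intercept estimates the generating intercept *plus the
realised mean of the random effects*, which is the identifiable
combination; the calibration tests therefore compare against that
quantity.

### DIC

Dbar is the mean posterior deviance over retained draws, Dhat the
deviance at the posterior means of all parameters (fixed effects and
random effects), pD = Dbar − Dhat and DIC = Dhat + 2 pD. For a chain of
identical draws pD = 0 exactly; this identity and the conjugacy of the
variance step are regression-tested.

### Model ladder

`model_ladder` fits the conventional four-model sequence — empty model
(random intercepts only); + individual-level fixed effects; + random
slopes; + the cluster-level distance covariate — and assembles a table
of variances, ICCs, PCVs and DIC per model, with the empty model as the
PCV reference.

## Variance partitioning

On the latent-response scale the level-1 residual of a logistic model
is standard logistic with variance π²/3, so

  ICC_C = σ_C² / (π²/3 + σ_C² + σ_R²),  ICC_R = σ_R² / (π²/3 + σ_C² + σ_R²).

The latent variant is the package's reporting default because it
reproduces the reference ladder exactly from its printed variance
components; an explicit-σ_e² variant is kept for completeness. PCV is
(V_ref − V_model)/V_ref against the empty model, and may be negative if
a richer model's variance grows. Values are held at full precision
internally; percentages are rounded to two decimals only at the
presentation layer.

## Geolinkage

Each cluster is linked to its nearest caesarean-flagged facility by
Euclidean distance; ties break to the smallest facility id so results
are order-independent. A 25 km buffer radius flags in-reach clusters —
a documented convention, configurable, not an estimate — while the
continuous nearest-facility distance is retained for all clusters
because the regression model uses it as a covariate (min–max scaled to
[0, 1], consistent with the covariate-scale convention below).

## Facility scores

Service-environment scores are principal components of binary indicator
sets: six general-readiness dimensions (communication equipment,
external supervision, client opinion/feedback, quality assurance,
emergency transport, client latrine), seven obstetric-care availability
items, and nine obstetric-care readiness items. PCA runs on the
correlation matrix (indicators are mixed binary/ordinal, so unit-variance
scaling is the defensible choice), the first two components per set are
retained, and the loading-vector sign is fixed so each component's
largest-magnitude loading is positive — a pure reproducibility
convention. Constant indicator columns are dropped with a warning; a
fully constant set yields zero scores (centred data are identically
zero). The exact indicator item lists are configuration, shipped with
defaults named after the six quoted dimensions; reproducing any
particular scoring software's output bit-for-bit is a non-goal.

## Spatial hotspot pipeline

The hotspot stages operate on per-cluster caesarean rates:

1. **Distance-band weights.** Binary weights w_ij = 1 iff d_ij ≤ band;
   optional row standardisation; isolated features retained with a
   warning. Gi* weights include self by construction.
2. **Global Moran's I** with the analytic z-test under the
   randomisation assumption (Cliff–Ord moments), the closed-form
   counterpart of a permutation test; its empirical type-I error at
   α = 0.05 is verified to lie in [0.03, 0.07] under 1,000 permutations.
3. **Incremental spatial autocorrelation**: Moran z-scores over bands
   starting at the mean nearest-neighbour distance (the distance at
   which the average feature has at least one neighbour), default 10
   bands with step equal to the start; the peak-z band is the critical
   clustering distance, ties going to the smallest band.
4. **Getis-Ord Gi*** with self-inclusive binary weights — the
   conventional fixed-distance-band hotspot recipe. Saturated
   neighbourhoods (zero denominator) return z = 0 with a flag.
5. **FDR classification**: two-sided normal p-values,
   Benjamini–Hochberg adjustment, and classes hot/cold at the 90/95/99%
   tiers signed by z.

An externally reported global Moran's I exceeding 1 is not reproducible without
the original data and the exact (unstated) weight construction; the
package makes no attempt to match that number and verifies its own
implementation against brute-force oracles instead.

## SNVC spatial regression

Cluster-level caesarean counts are Gaussianised and regressed with
spatially varying coefficients:

* **Transform.** y* = log(count + 0.5) (log-Gaussian approximation for
  counts that are not Poisson-like), optionally followed by a
  sinh-arcsinh ("SAL") adjustment z = sinh(τ·asinh((y* − μ)/σ) − ε)
  whose four parameters are fitted by maximum likelihood; skew 0 and
  tail 1 collapse to the affine-log case. The transform object carries
  its inverse.
* **Moran eigenvector basis.** Proximity C_ij = exp(−d_ij/r) with r
  fixed at the maximum nearest-neighbour distance (a common eigenvector
  spatial filtering convention), doubly centred, eigendecomposed;
  components with eigenvalue above 25% of the largest are retained —
  the smooth, positively autocorrelated map patterns.
* **Mixed model.** y* = Xb + Σ_k diag(x_k) E γ_k + Σ_k x_k∘δ_k + ε with
  γ_k ~ N(0, τ_k² Λ(α_k)) and δ_k ~ N(0, ψ_k²). Λ(α) grades shrinkage
  by eigenvalue (λ/λ_max)^α, trace-normalised, with a single fitted
  decay exponent per covariate — a deliberately small shrinkage family
  that stays identifiable at a few hundred locations. Variance ratios
  are estimated by REML with σ² profiled out (L-BFGS-B on log-ratios);
  the reported objective trace allows the monotone best-so-far check.
  Constant coefficients get GLS standard errors and t/p-values with
  df = n − rank(X), a simple documented convention. Per-location
  surfaces are b_k + (Eγ̂_k) + δ̂_k via BLUP; a variance at the zero
  boundary yields a constant surface.
* **Exposure.** Cluster birth counts enter as an optional log-births
  covariate (default on in the pipeline); it is dropped automatically
  when constant (balanced designs), where it is collinear with the
  intercept. Cluster-level covariates are aggregated as means.

## Synthetic-data generator

The generator is first-class, tested code. Its defaults emulate the
linked-survey scale the package targets: 11 regions tiling a
1500 × 1000 km window, 42–71 clusters per region (~620 total), 8–14
women per cluster (~7,000 births), 214 facilities of which 179 provide
caesareans, cluster/region intercept variances 1.04 and 2.19, and fixed
effects whose odds ratios match the motivating survey's adjusted
estimates (education 2.80, rich household 1.80, 1–3 ANC visits 2.91,
≥4 visits 4.67, and the continuous effects below). The default
intercept (−7.37) was calibrated once, by Monte-Carlo averaging over
replicates, so the marginal prevalence is ≈3.65%.

Continuous covariates (age, age at first birth, parity) are generated
from truncated normal / truncated Poisson marginals and carried min–max
scaled to [0, 1]. The reference per-unit odds ratios for these
covariates (e.g. 28.13 "per year" of age) are only plausible as
per-range effects, so the scale is explicit and configurable rather
than asserted; the generator's default log-odds effects are the
reference AORs interpreted on the [0, 1] scale. ANC category is
multinomial (0.37/0.31/0.32), education and wealth Bernoulli
(0.48/0.40).

Facility indicator items are driven by a latent facility-quality score
so indicator sets are positively correlated, which is what a principal
component summary presumes. Regions are rectangular tiles of the study
window; facilities are uniform over the window. GPS displacement noise
is not emulated (hook only, default off).

What the synthetic world does **not** emulate: survey sampling weights,
real geography and road networks, spatially clustered facility
placement, informative cluster sizes, and item non-response. Passing
calibration tests therefore show that the estimators recover the
generating process they assume — not that the assumptions hold in any
particular survey.

## Problem sizes and numerical conventions

The test suite runs the calibration study at the design scale the
package documents for desk verification: 20 replicates of ~620 clusters
/ ~7,000 women with the reduced chain for interval coverage; 1,000
permutations for the Moran type-I check; 100 replicates at 120
locations for the spurious-surface null; a 250-location planted-surface
recovery. Oracle-equivalence checks run on ≤30-point instances at 1e-8.

Numerical conventions worth knowing: logistic likelihoods use
log-sum-exp-safe softplus; Gi* treats fields constant to machine
precision as exactly constant (z = 0) and computes local sums from
deviations to avoid cancellation; Moran's I refuses constant values and
empty weights; PCA drops zero-variance columns rather than imputing;
the REML objective returns a large penalty on failed Cholesky so the
optimiser retreats. All randomness is seeded; identical seeds give
byte-identical outputs, and the pipeline derives per-stage seeds from
one global seed via `SeedSequence([seed, stage_index])`.

## Known limitations

* The Metropolis-within-Gibbs sampler is serial and
  likelihood-evaluation bound; paper-scale chains (175k iterations) on
  ~7,000 observations take tens of minutes. HMC/NUTS is a non-goal.
* Random-slope covariances (slope–intercept correlation) are not
  modelled, matching the per-variance reporting the package mirrors.
* The SNVC model fixes the kernel range at the maximum
  nearest-neighbour distance rather than estimating it.
* DIC is reported as defined above; alternative effective-parameter
  definitions (pV) are not implemented.
* Survey weights are intentionally out of scope throughout.
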