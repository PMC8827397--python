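# Methods

## The model

`treesam` models annual radial tree growth as a hierarchical Bayesian
regression with *stochastic antecedent* climate covariates. Measured ring
width `r` (mm) is analysed on the log scale, `G = log(r + 1)`; the `+1`
keeps missing rings (`r = 0`, locally absent at the sampled radius) in the
sample. For year `t` and core `c`:

    G_{t,c} ~ Normal(mu_{t,c}, sigma^2)

    mu_{t,c} = a1_c + a2_c * Age_{t,c} + a3_c * Pant_t + a4_c * Tant_t
             + a5_c * Pant_t * Tant_t + a6_c * G_{t-1,c}
             + a7_c * HI_t + a8_c * HI_t * Pant_t + a9_c * HI_t * Tant_t

The antecedent covariates are weighted averages of the past 60 months of a
climate variable,

    Xant_t = sum_{y=0..4} sum_{m=1..12} X_{t-y,m} * w_{y,m}

with one importance-weight vector per variable (precipitation in mm/month,
temperature in degC). The weights live on a simplex with two structural
constraints: October--December of the current year carry weight exactly
zero (climate after growth cessation cannot affect that year's ring), and
temporal resolution declines with lag — single months for the current and
prior year, then 2-, 3- and 4-month calendar blocks for years 2, 3 and 4
back (34 free blocks over 57 non-zero months). Within a block, mass is
split equally over its months; calendar blocks are aligned from January.
The exact grouping is a package choice (configurable via `WeightScheme`);
only the declining-resolution rule itself is fixed.

Core-level coefficients are exchangeable draws `a_k,c ~
Normal(mu_k, sigma_k^2)`; the age coefficient is truncated to `(-inf, 0]`,
consistent with the negative-exponential form of biological age trends.
Hyperpriors are weak: `Normal(0, 100^2)` on every global mean,
`Uniform(0, 100)` on every standard deviation, and a flat `Dirichlet(1,
..., 1)` on each block-weight vector.

**Truncated age hyper-mean.** The global mean of the age coefficient is
truncated to `(-inf, 0]` as well (configurable via
`PriorSpec.truncate_hyper_mean`). With the hyper-mean unconstrained, the
truncated-normal hierarchy admits a pathological ridge: when the core-level
age effects concentrate near zero, a huge positive hyper-mean paired with a
matched hyper-SD reproduces their near-exponential profile at *higher*
likelihood, and the hyper-mean posterior escapes to arbitrarily large
values. Bounding the hyper-mean removes the ridge without affecting the
core-level truncation.

**Centering.** Age, prior-year growth and harvesting intensity are centered
once by their sample means over all modelled records; the antecedent
covariates are re-centered at every likelihood evaluation (their values
change with the weights). Interaction covariates are products of
individually centered factors, so main effects are interpretable at average
conditions and the intercept is baseline growth at average age, climate and
management.

A year is modelled for a core when the core has a measured ring in that
year and the year before (the autoregressive covariate uses the observed
prior-year log growth, not a latent value) and the climate table covers the
full 60-month window; both cores of a tree enter as separate cores, with no
intermediate tree level (the hierarchy is core -> species-site).

## Inference

Adaptive Metropolis-within-Gibbs, several independent chains, burn-in,
thinning, Gelman--Rubin PSRF (threshold 1.1) and effective sample sizes
(via `arviz`) as diagnostics. Default protocol: 3 chains, 40,000 iterations
including a 10,000-iteration burn-in, thinned by 10 (3,000 retained per
chain). All tests and the acceptance script use reduced protocols noted
below.

Update kernels per scan:

* **Block weights** — collapsed Metropolis moves. When proposing a change
  to, say, the precipitation weights, the three coefficients multiplying
  the centered precipitation antecedent (its main effect, the P x T
  interaction and the HI x P interaction) *and their global means* are
  integrated out analytically. The marginal covariance is rank-3 per core
  plus a shared rank-3 term; because all collapsed covariates are
  year-level quantities, the Woodbury algebra reduces to two small
  mat-vecs and shared 3x3 operations per proposal for balanced designs
  (unbalanced designs fall back to a rank-1 collapse of the main effect).
  After each weight update the collapsed coefficients are redrawn from
  their exact joint Gaussian conditional, which makes the composition a
  valid partially collapsed Gibbs step. Collapsing matters: conditioned on
  coefficient draws that carry no signal, the weight likelihood is flat and
  chains lock into joint weight-coefficient configurations they cannot
  leave.
* Weight moves mix three proposal types: a coordinate sweep in
  stick-breaking logit space (step sizes adapted toward ~30% acceptance
  during burn-in), pairwise mass transfers and swaps between random or
  *echo-partner* blocks (blocks 12 lags apart — overlapping windows make
  year-shifted weight profiles plus a stronger autoregressive coefficient
  near-degenerate with the truth, and echo swaps jump between such modes),
  and a whole-profile exchange of the current-year and prior-year month
  weights.
* **Core-level coefficients** — coordinate-wise conjugate normal draws;
  the age coefficient uses its truncated-normal full conditional.
* **Global means** — conjugate draws; the age hyper-mean uses a
  random-walk step (the truncated core densities carry a `Phi(-mu/sigma)`
  normalization) restricted to the non-positive half-line.
* **Standard deviations** — random-walk Metropolis on the uniform support
  with adapted steps.

**Starting points.** Coefficients and SDs start from dispersed prior-like
draws; the initial observation SD is scaled to `sd(G)` so early scans do
not behave like a tempered likelihood. Starting weights are chosen by
screening: candidate profiles (uniform, +/- correlation screens of the
year-mean growth anomaly against each block's climate series, and
chain-specific Dirichlet draws) are scored by a year-level regression of
growth anomalies on the implied antecedent covariates, and each chain
starts at its best-scoring pair. The weight posterior is strongly
multimodal; unscreened chains can strand in modes hundreds of log-units
below the dominant one, which no practical number of local moves escapes.
Weight updates are then held for the first ~25 scans so the conjugate
coefficient draws lock onto the starting weights before the weight kernels
open. Adaptation of all step sizes stops at the end of burn-in.

Initialization retries up to 20 times if the log-posterior is non-finite;
per-chain seeds derive from one root seed and runs are bit-reproducible.

## Posterior products

* Coefficient table: pooled posterior mean and equal-tailed 95% credible
  interval per global coefficient; "significant" means the interval
  excludes zero.
* Weight profiles: monthly, annual (summed within each year into the past)
  and cumulative (running total over lag) weights with 95% CIs; memory
  lengths M50/M90 are the first lags at which the cumulative weights reach
  0.5/0.9 (ties resolve to the earliest lag), computed per draw and then
  summarized.
* Antecedent series: per-year *uncentered* antecedent values per draw,
  temperature in degC as-is, precipitation multiplied by 12 (weighted
  monthly mean -> annual-total scale) for comparison with recorded yearly
  sums.
* Net sensitivities: `dG/dPant = a3 + a5*Tant + a8*HI` and symmetrically
  for temperature, over covariate grids.
* Fit: posterior-predictive `R^2` is the squared Pearson correlation of the
  predicted mean replicate (averaged over a subsample of draws; averaging
  the means equals averaging infinitely many noisy replicates) against
  observed `G`. The autoregressive share of fit is computed
  counterfactually: `R^2` of the full replicate minus `R^2` of a replicate
  with the autoregressive coefficient zeroed at every draw, in percentage
  points.

## Synthetic data

The generator forward-simulates the full model so every stage can be
validated against known truth:

* **Temperature**: seasonal sinusoid (July peak) + a shared year-level
  anomaly (SD 0.6 degC) + AR(1) monthly anomalies (rho 0.3, marginal SD
  1.0 degC). The interannual and month-to-month coherence matters: with
  independent monthly noise the 57 free weight cells give the interaction
  terms enough freedom to assemble spurious covariates out of noise, an
  artefact real climate series do not permit.
* **Precipitation**: seasonal profile (January peak) x a year-level gamma
  multiplier (shape 25) x monthly gamma multipliers (shape 4), all mean 1
  — non-negative and right-skewed; configured drought years (default
  1986, 1994, 1995, 2012) multiply the year's profile.
* **Harvesting**: episodic pulses on a zero baseline, roughly one
  intervention per decade; by default event years and intensities
  (U(0.05, 0.20)) are drawn from the seed so replicate datasets differ in
  their management design as well as their noise (an explicit event list
  can be supplied). With one fixed design, coverage statistics of the
  HI-family coefficients would measure that design's idiosyncrasies — such
  as an event coinciding with a drought year — rather than estimator
  calibration.
* **Truth weights**: smooth seasonal profiles — exponential lag decay
  (16 months) times calendar-month emphasis (growing-season months for
  precipitation; spring and late summer for temperature) plus a 25%
  uniform tail — normalized on the block simplex. M50 lands in the
  mid-teens and M90 in the mid-forties of months, inside observed memory
  ranges. Estimated profiles from real series are smooth multi-month
  humps; a spiky truth is both unrealistic and mis-calibrating, because
  posterior weight draws are necessarily smoother than a spike, which
  dilutes the variance of the antecedent average and inflates the
  compensating coefficient beyond its credible interval.
* **Coefficients**: site presets set the intercept from observed mean ring
  widths (~1.4 mm stressed, ~1.9 / ~1.75 mm at the wetter sites) and use
  effect sizes that put the realized explainable-variance fraction in the
  0.89--0.94 band observed for silver fir, with an autoregressive share of
  a few percent. Core-level SDs give roughly 30% relative heterogeneity in
  climate sensitivity across trees. Growth is simulated recursively with
  the prior-year term centered self-consistently (three fixed-point passes
  reusing the same noise), and widths are floored at zero, exercising the
  missing-ring path.

What the generator does *not* emulate: spatial correlation between cores
beyond shared year effects, measurement error in ring widths, cross-dating
errors, climate trends (series are stationary apart from drought years),
and management records with coarser-than-annual resolution. Passing
recovery tests therefore demonstrate estimator correctness under the
model's own assumptions plus realistic climate coherence — not robustness
to the full messiness of field data.

## Problem sizes and numerical choices

* Standard recovery fixture: 30 cores x 60 years (1957--2016), the scale of
  one species-site dataset. Tests and the acceptance script fit it with 2
  chains x 10,000 iterations (4,000 burn-in, thin 12); the prior-only and
  conjugate-limit validations use smaller designs and 4,000 iterations.
  These reduced protocols are the package's desk-scale defaults for
  validation; the full default protocol (3 x 40,000) is available through
  configuration.
* Simplex arithmetic tolerances: block weights must sum to 1 within 1e-9
  on input; monthly expansion conserves mass to ~1e-12; memory-length
  threshold crossings use a 1e-12 tie tolerance.
* Stick-breaking logits are clipped to +/-35 (weights below ~1e-15 are
  indistinguishable from zero at double precision).
* Degenerate PSRF cases: identical constant chains give 1; zero
  within-chain variance with non-zero between-chain variance gives +inf;
  values are floored at 1.

## Known limitations

* The coefficient/weight-concentration decomposition is weakly identified:
  the product `alpha * sd(Xant)` is recovered substantially more precisely
  than either factor, and coefficient point estimates compensate for any
  smoothing of the weight profile. Interval coverage for the climate
  coefficients is honest only when the true weight profile is as smooth as
  the posterior can represent.
* The volume-based harvesting-intensity variant is the same model with a
  different input column (`--hi-definition volume` simply changes which
  ratio the harvest reader computes); no separate code path exists.
* No tree-level intermediate hierarchy; cores are exchangeable within a
  species-site.
* The sampler is exact but serial; one full recovery fit takes on the
  order of a minute at desk-scale settings on one CPU.
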