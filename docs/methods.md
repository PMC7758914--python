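# Methods

## The problem

Household surveys that report health indicators for small administrative
areas ("blocks", the sub-district unit in Indian states) produce unstable
raw estimates: a block-round cell may rest on as few as 19 respondents.
`bymtrends` smooths these estimates by borrowing strength from bordering
blocks and from the state average, decides whether an indicator's time
trend varies between blocks, and classifies each block's trend with a
calibrated probability rule.

## Model

For block *i* = 1..B and survey round with time value *t* (years since the
first round), the observed cell is a pair (y_it, n_it): successes out of a
denominator for binary indicators, or summed counts out of the summed
maximum possible count for count indicators (counts are aggregated as a
ratio of sums, Σcount/Σmax — the weighted mean of per-respondent ratios
with weights equal to each respondent's maximum, which reduces count data
to the same (y, n) form the Poisson model consumes as an offset).

The linear predictor is

    eta_it = alpha + beta·t + u_i + v_i [+ delta_i·t]

with

- y_it ~ Binomial(n_it, logit⁻¹(eta_it)) (binary) or
  y_it ~ Poisson(n_it·exp(eta_it)) (count);
- u ~ ICAR(tau_u): the Besag intrinsic prior on the block contiguity
  graph, density ∝ exp(−tau_u/2 · Σ_{i~j}(u_i−u_j)²), constrained to sum
  to zero within each connected component;
- v_i ~ iid Normal(0, 1/tau_v): unstructured block heterogeneity;
- delta_i ~ iid Normal(0, 1/tau_delta), sum-to-zero (present only in the
  interaction model): the per-block deviation from the state-average
  trend — an unstructured space-time interaction with linear trends per
  block.

The sum-to-zero constraints keep alpha interpretable as the state-wide
level and beta as the state-average per-year trend; exp(beta + delta_i) is
block *i*'s relative change per year (an odds ratio for binary indicators,
a rate ratio for counts).

Contiguity defaults to rook (a shared border of positive length, after
snapping coordinates at 1e-9 to absorb floating-point slivers); a queen
option (corner touches count) is available but non-default, because "shares
a border" names a border, not a point.

### Priors

The source of the data never pins these down, so they are package choices,
exposed on `ModelSpec`:

| parameter | prior | default rationale |
|---|---|---|
| tau_u, tau_v, tau_delta | Gamma(1, 5e-4) | weakly informative, the family used by standard spatial-smoothing software defaults |
| alpha, beta | Normal(0, precision 1e-3) | effectively flat on the logit/log scale |

Time is coded t = round − first_round (0, 1, 2, 3), treating rounds as
annual; with 12–16 months between survey rounds this makes exp(beta) "per
year" to a good approximation.

## Inference

A bespoke adaptive random-walk Metropolis-within-Gibbs sampler:

- scalar RW-MH for alpha and beta;
- single-site RW-MH for u, vectorised over a greedy graph colouring
  (sites within a colour class share no edge, so their full conditionals
  do not interact and can be updated simultaneously);
- vectorised single-site RW-MH for v and delta (iid priors, block-local
  likelihoods);
- conjugate gamma Gibbs draws for the precisions, with ICAR shape
  (rank/2 = (B − components)/2) for tau_u and (B−1)/2 for the constrained
  delta;
- a joint rescaling move (x, tau) → (c·x, tau/c²) for each of (u, tau_u),
  (v, tau_v), (delta, tau_delta). The Gaussian/ICAR prior exponent is
  invariant under this map and the tau prior powers and Jacobian collapse
  to −2·log c, so the move is cheap; it decouples the field scale from its
  precision and removes the notoriously slow tau mixing when a field is
  near zero (effective sample sizes for tau_delta improve by an order of
  magnitude on flat-interaction data);
- recentring of u and delta each sweep, with the removed mean absorbed
  into alpha and beta respectively so the likelihood is unchanged
  (per-component residual centring on disconnected graphs is the standard
  on-the-fly constraint).

Proposal scales adapt by Robbins-Monro toward ~40% acceptance during
burn-in and are frozen afterwards, preserving detailed balance in the
sampling phase. Default settings: 4 chains × 5,000 iterations, 2,000
burn-in, thin 2; every chain is seeded from a single `SeedSequence`, so
runs are bit-reproducible. Convergence is summarised by split-R̂ and bulk
ESS (via ArviZ); any split-R̂ > 1.05 flags the fit as unconverged — the
flag is carried into run reports, never silenced.

Missing cells (no respondents) contribute nothing to the likelihood but
receive fitted-value draws from the posterior of eta; those draws are the
model's imputation. Smoothed levels are reported as the posterior median
and the 2.5th/97.5th quantiles of the fitted draws.

The sampler is validated against a dense quadrature oracle: on a 2-block,
2-round binary model with fixed precisions, a 25-point-per-axis grid over
(alpha, beta, u1, v1, v2) (u2 = −u1) integrates the exact posterior; MCMC
means and sds of alpha and beta agree within 0.02 on the logit scale.

## Model selection and trends

Both models are always fitted. DIC = Dbar + pD with pD = Dbar − D(posterior
mean of parameters); the saturated deviance constant is omitted since it
cancels in any comparison on the same data. The lower DIC wins; exact ties
go to the no-interaction model (parsimony). A lower DIC for the interaction
model is reported as evidence that trends vary between blocks.

Per-block trends: 10,000 resamples of beta + delta_i from the posterior
draws, exponentiated; the point estimate is the median (quantile-consistent
with the CrI endpoints), the CrI the 2.5th/97.5th quantiles. Two resampling
modes are first-class:

- `joint` (default): beta and delta_i taken from the same posterior draw,
  respecting their posterior correlation;
- `independent`: each marginal resampled separately. This replicates the
  literal procedure of resampling "each of" the two effects and adding
  them; it inflates the CrI when beta and delta_i are negatively
  correlated (in the degenerate case delta_i = −beta + const the joint CrI
  collapses to a point while the independent one does not — a tested
  behavioural contrast).

Classification: CrI entirely above 1.0 → increase (≥97.5% posterior
probability of a rise per year); entirely below → decrease; anything else,
including an endpoint exactly 1.0, → indeterminate.

## Synthetic data

The generator draws data from the model itself: u ~ ICAR(sd_u²) centred,
v iid, delta iid centred (or pinned via `delta_values` for designs with
known per-block ORs), denominators uniform integers in `n_range`
(default 19–123, the block-level sample-size range of a state-wide
household survey), 4 rounds, and optional missingness. Missing units
default to whole blocks (a block with no respondents in any round — the
situation the model must impute purely from neighbours); a per-cell option
exists. The default study map is a 23×24 rook lattice with 18 cells
removed, giving 534 blocks — the analysis depends on geography only
through adjacency, so no real boundary file is bundled.

What the generator does *not* emulate: survey design effects (cluster
sampling, LQAS-style rules), age-group stratification, respondent-level
covariates, non-sampling error, or spatially structured interaction.
Passing recovery tests therefore show the estimator is correct *under the
model's own assumptions*, not that real survey data meet them.

Scenario presets (study conditions, not tuning knobs): `universal_rise`
(beta0 = ln 1.25, sd_delta = 0.05), `universal_decline` (beta0 = ln 0.8),
`opposite_trends` (beta0 = 0, sd_delta = 0.4), `no_interaction`
(sd_delta = 0), `with_missing` (missing_fraction = 0.02). All presets use
sd_u = 0.5, sd_v = 0.1.

## Verification studies and problem sizes

The studies in `bymtrends.studies` (run by `scripts/acceptance.py` and the
acceptance tests) use a 6×6 lattice, 4 rounds, and a 2-chain × 3,000-
iteration sampler (1,000 burn-in, thin 2) for replicate studies — small
enough to run as a desk check, large enough for the posterior to
concentrate. The DIC study uses longer, unthinned chains (9,000 iterations, 2,000 burn-in) because under a null interaction the true DIC gap between
the models is below 1 and Dbar's Monte-Carlo error must be smaller than
that for the comparison to be meaningful. The quadrature oracle uses the
default 8,000-iteration, 4-chain sampler.

## Numerical choices and edge cases

- Binomial likelihoods are evaluated on the logit scale via
  log(1+e^eta) = logaddexp(0, eta); no probabilities are formed during
  sampling, so eta far in the tails is safe.
- ICAR draws use the eigenbasis of Q restricted to eigenvalues > 0 —
  exactly the sum-to-zero-per-component subspace.
- A disconnected graph is allowed everywhere; all centring is
  per-component and the ICAR rank deficiency equals the component count.
- n = 0 is a missing cell, never a zero estimate; datasets store missing
  cells explicitly.
- DIC requires ≥ 100 draws; smoothed levels require ≥ 500.
- `classify_trend` is exhaustive over valid (lo, hi); bounds touching 1.0
  are indeterminate by construction.

## Known limitations

- DIC with pD = Dbar − D(θ̄) can go slightly negative for strongly
  non-normal posteriors and is known to favour over-fit; the selection
  study documents (and tolerates) occasional interaction picks under a
  null.
- The interaction is unstructured (no spatial correlation in delta);
  spatially structured interaction types are out of scope.
- No covariate adjustment, survey weights, or multiple-testing control
  across indicators — trends are descriptive, per indicator.
- The per-year interpretation of exp(beta) assumes equally spaced annual
  rounds; unequal spacing can be expressed through `time_values`.
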