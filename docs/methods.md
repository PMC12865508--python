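# Methods

This note documents the statistical model, the sampler, and the diagnostics
implemented in `rtscr`, in enough detail to audit the code against the math.

## 1. Data

A camera-trap survey yields:

- a detector array of `J` stations at planar coordinates `x_j` (meters) with a
  binary operation matrix `O[j, k]` over `K` occasions (days); per-trap effort
  is `E_j = Σ_k O[j, k]` trap-days;
- identified detection counts `y_id[i, j, k]` for the `n` individuals that were
  photo-identified at least once;
- unidentified detection counts `n_noID[j, k]` — detections (e.g. blurred or
  single-flank photographs) whose individual identity was lost. Their
  individual of origin is unknown; only the trap-level sums are observed.

Raw photo records are deduplicated before counting: records of the same
individual (or consecutive unidentified records) at the same station within a
configurable window (default 30 min) of the last retained record collapse to a
single detection event, following the usual independence convention for
camera-trap record tables.

## 2. Model

Random-thinning spatial capture–recapture (rt-SCR) combines three standard
ingredients:

**Data augmentation.** The unknown population size is embedded in a
superpopulation of fixed size `M` (default `max(50, 4n)`). Each member has a
membership indicator `z_i ~ Bernoulli(ψ)` and an activity center
`s_i ~ Uniform(S)`, where `S` is the state space — by default the trap
bounding box buffered on all sides. Abundance is `N = Σ_i z_i` and density is
`D = 100·N / |S|` per 100 km².

**Poisson encounters with a half-normal rate.** With occasions collapsed
(valid because the rate is occasion-constant and effort enters as a sum),

    y_full[i, j] | z_i  ~  Poisson( λ0 · exp(−d_ij² / 2σ²) · E_j · z_i ),

where `d_ij = ‖s_i − x_j‖`, `λ0` is the baseline encounter rate per trap-day,
and `σ` is the movement scale.

**Random thinning of identity.** Each encounter independently retains its
individual identity with probability `θ`:

    y_id[i, j] | y_full[i, j]  ~  Binomial(y_full[i, j], θ),

and the unidentified remainder is observed only through the trap sums

    n_noID[j] = Σ_i ( y_full[i, j] − y_id[i, j] ).

Standard SCR is the special case `θ = 1` with the unidentified counts
discarded (`fit_scr`).

**Priors.** `λ0 ~ U(0, 5)`, `σ ~ U(0, buffer width)` by default,
`θ ~ Beta(1, 1)`, `ψ ~ Beta(1, 1)` (so `N` is approximately uniform on
`{0, …, M}` a priori).

## 3. Sampler

`fit_rtscr` runs a Metropolis-within-Gibbs sampler, vectorized across chains
(default 3 × 20,000 iterations, 5,000 burn-in, thinning 10). One sweep:

1. **Latent allocation (exact Gibbs).** Conditional on everything else, the
   unidentified counts at trap `j` distribute over individuals as

       y_extra[·, j] ~ Multinomial( n_noID[j],  w_i / Σ w ),   w_i = z_i λ_ij,

   because thinning a Poisson process splits it into independent Poisson
   streams: the `(1−θ)` factor and `λ0` cancel in the weights. This replaces
   single-count Metropolis moves with a draw from the exact full conditional;
   an MH variant is retained (`update_allocation(..., method="mh")`) and is
   tested to produce the same stationary distribution. If every weight at a
   trap vanishes the current allocation is kept (and counted as a fallback).
2. **Membership `z` (Gibbs).** `z_i = 1` is forced when individual `i` holds
   any counts; otherwise `z_i ~ Bernoulli( ψ e^{−Λ_i} / (ψ e^{−Λ_i} + 1 − ψ) )`
   with `Λ_i = Σ_j λ_ij E_j`.
3. **`ψ` (Gibbs).** `ψ ~ Beta(a + N, b + M − N)`.
4. **Activity centers `s`.** Random-walk MH for members with counts; exact
   uniform redraw from `S` for `z_i = 0` members (their likelihood
   contribution given no counts is absorbed by step 2's `e^{−Λ_i}` factor at
   the next sweep — proposals are accepted by the standard MH ratio on the
   complete-data likelihood). A discrete-site mode (used by the enumeration
   oracle test) replaces this with a categorical Gibbs draw over a fixed
   lattice.
5. **`λ0`, `σ` (MH).** Log-scale random walks with the log-normal Jacobian;
   proposal scales adapt toward a 25–45% acceptance rate during burn-in only,
   so the post-burn-in kernel is fixed and valid.
6. **`θ` (Gibbs).** The binomial thinning likelihood gives
   `θ ~ Beta(a + Σ y_id, b + Σ n_noID)` — notably free of the latent
   allocation, which makes it a sharp analytic check on the sampler.

The allocation constraint `Σ_i (y_full − y_id)[·, j] = n_noID[j]` is asserted
at every retained iteration; a violation raises immediately rather than
corrupting output.

Initialization uses a coarse integrated-likelihood grid over `(λ0, σ)` on the
identified data to start chains in a sensible region (overdispersed across
chains).

## 4. Diagnostics and derived quantities

- **Convergence.** Gelman–Rubin `R̂` per parameter with the
  sampling-variability correction: `V̂ = (n−1)/n·W + (m+1)/(mn)·B`,
  `R̂ = √(V̂/W)`; `R̂ < 1.1` is taken as convergence evidence, and the CLI
  exits with status 3 above that threshold.
- **Goodness of fit.** Posterior-predictive checks on three statistics: total
  detections, number of identified individuals, and number of visited traps.
  For each retained draw a replicate dataset is simulated from that draw's
  `(λ0, σ, θ, z, s)` under the observed effort; the Bayesian p-value is
  `Pr(T_rep ≥ T_obs)` with ties counted in favor of the model. The
  identified-individuals statistic is computed on the thinned replicate (the
  observable quantity); the other two use all detections.
- **Home range.** The 95% home-range area implied by a bivariate-normal
  movement model: `π (q σ)²` with `q = √(χ²₂;0.95) ≈ 2.4477`, averaged over
  posterior draws and reported in hectares.
- **MMDM.** Mean, over individuals detected at ≥ 2 distinct traps, of the
  maximum pairwise distance among their detection traps.
- **Closure.** A span test: conditional on an individual being captured on
  `c` of `K` occasions, under closure the capture occasions are a uniform
  `c`-subset, giving exact moments for the span `d = last − first`
  (`P(d=t) ∝ (K−t)·C(t−1, c−2)`). The statistic
  `Z = (Σd − ΣE[d]) / √(ΣVar[d])` is approximately standard normal; open
  populations shorten spans, so small `Φ(Z)` flags a violation. Caveat: the
  null assumes occasions are exchangeable, so strongly staggered trap
  deployment also shortens spans and pushes `Z` negative even for a closed
  population — interpret small p-values alongside the effort pattern.
- **Point estimates.** Posterior means for detection parameters; posterior
  medians for `N` and `D` (right-skewed posteriors); CV = posterior SD /
  posterior mean.

## 5. State-space workflow

The conventional buffer is three times the movement scale. Because `σ` is not
known a priori, the CLI automates a two-stage rule: fit on a wide provisional
buffer (default 15 km), set the final buffer to `3·σ̂` (posterior mean), and
refit. A fixed buffer (`--buffer`) reproduces single-stage analyses. A
habitat polygon may replace the rectangle; the uniform activity-center prior
is then enforced by rejection sampling, and a mask that excludes any trap is
rejected as an error.

## 6. Study-emulation preset

The bundled `study_design()` emulates a 52-station jaguar survey: paired
stations 1308 m apart (the survey's mean nearest-neighbor spacing) whose pair
centers sit on a 5 km lattice, 91 daily occasions with staggered deployment
summing to exactly 3779 trap-days, and a 3σ = 9150 m buffered state space of
exactly 1941 km². Default generative values are `N = 25`, `λ0 = 0.047/day`,
`σ = 3050 m`, `θ = 0.87`, matching the motivating study's reported posterior.

## 7. Validation strategy

The test suite validates the implementation against independent oracles:

- exhaustive enumeration of the joint posterior on a tiny discretized
  instance (2 traps, `M = 3`, 25 candidate sites), with `ψ` marginalized
  analytically — the MCMC posterior of `N` must match within 0.02 total
  variation;
- the analytic `Beta(a + Σy_id, b + Σn_noID)` posterior for `θ`;
- scipy-based recomputation of the complete-data log-likelihood;
- exact binomial marginals for the multinomial allocation step, checked for
  both the Gibbs and MH kernels;
- brute-force subset enumeration for the closure-test span moments;
- a 20-replicate study-scale simulation study (coverage of 95% credible
  intervals) and a 20-replicate posterior-predictive calibration check.
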