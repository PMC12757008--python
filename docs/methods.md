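# Methods

## The model

`burstvar` analyses paired daily series from measurement-burst studies:
life satisfaction `LS` (mean of two 0–100 evening slider items) and physical
activity `PA` (steps per valid hour of device wear). Both are transformed to
the real line before modelling,

    L = logit((LS + 1) / 102),        P = log(PA + 1),

which removes the slider's double bound and the step rate's right skew. The
daily bivariate state of person *i* follows a hierarchical VAR(1):

    y_it = mu_it + m_i + B (y_{i,t-1} - mu_{i,t-1} - m_i) + eps_it

* **Mean structure** `mu_it = delta_0 + X_ik' delta` with an ANCOVA-style
  linear predictor per response: weekday indicators (reference Monday),
  month indicators (reference January), SES (reference "below average"),
  education (reference non-university), gender (reference female), region
  (reference low air pollution), and continuous age and day-in-study.
  Day-in-study is counted from each person's own first study day, since
  enrolment is continuous. Mean periodicity at the weekly and annual scales
  is therefore separated from the day-to-day dynamics.
* **Random effects** `m_i ~ N(0, diag(tau_L^2, tau_P^2))`, uncorrelated
  between responses. They are the only link between a person's bursts and
  produce the usual exchangeable shrinkage.
* **Dynamics** `B` is a 2×2 transition matrix in the row-equation
  convention: `beta_LP = B[0,1]` is the effect of yesterday's P on today's
  L. Each entry has a uniform(−1, 1) prior; draws whose spectral radius
  reaches 1 are rejected and counted.
* **Disturbances** `eps_it ~ N(0, Sigma_i)` with `Var = (sigma_L^2,
  sigma_P^2)` and contemporaneous correlation moderated by exercise
  identity through the inverse Fisher z link,

      rho_i = tanh(alpha0 + alpha1 * exid_std_i),

  so the correlation always stays in (−1, 1). The exercise-identity score
  is standardized within the sample before it enters the link, which makes
  `tanh(alpha0)` the correlation at average exercise identity.

Bursts are dynamically independent given `m_i`: the months-long gaps break
the day-level Markov chain. The first day of every burst contributes its
stationary marginal `N(mu + m, Sigma_stat)` with `Sigma_stat` solving the
discrete Lyapunov equation `Sigma = B Sigma B' + Sigma_eps` (solved exactly
through the 4×4 vec equation). A `first_day="condition"` switch instead
drops burst-first likelihood terms for comparison.

**Priors.** Uniform(−1, 1) per transition entry; improper flat priors for
the regression coefficients (a proper wide-normal fallback is available via
`PriorConfig.delta_sd`); half-normal priors on `sigma_*` and `tau_*` with
scale 1.0 on the transformed-response scale (the observed residual SDs are
near 1.2 and 0.6, so this is weakly informative); flat priors on `alpha0`,
`alpha1`. A single multiplier rescales all half-normal scales for the
sensitivity analysis (0.5 / 1 / 2).

**Missing data** are assumed MAR and handled by full-information posterior
estimation: missing `L`/`P` values are sampled as latent quantities jointly
with the parameters, never dropped or imputed ad hoc. The complete-data
likelihood (`log_likelihood`) is validated against a brute-force dense
Gaussian construction to 1e−8 on short series.

## Posterior computation

Sampling uses a blocked Gibbs scheme with exact conditionals, written for
this model:

1. **Missing responses**: exact bivariate-normal conditionals combining the
   own-day term and the successor-day term, updated in two checkerboard
   batches (odd/even day within burst) so simultaneously updated days are
   never adjacent.
2. **Regression coefficients** (both responses jointly, ~50 dimensions):
   one exact Gaussian draw with the random effects analytically
   marginalized via the Woodbury identity — this removes the
   intercept/random-effect coupling that slows alternating updates. The
   Gaussian's precision is assembled from per-person covariate Gram
   matrices precomputed once per chain (the disturbance weights are
   constant within person because exercise identity is baseline-only).
3. **Random effects**: exact 2-dimensional Gaussian conditionals.
4. **Transition matrix**: independence Metropolis–Hastings whose proposal
   is the exact Gaussian conditional implied by the transition terms alone;
   the acceptance ratio reduces to the burst-first stationary terms and the
   prior support, giving acceptance rates near 0.9.
5. **sigma, alpha, tau**: univariate slice sampling (stepping-out and
   shrinkage) on per-person residual cross-product statistics, so each
   density evaluation is O(n_persons).

There is no step size or mass matrix to tune; warmup iterations are simply
discarded. Determinism is guaranteed per `(seed, package version)`: chain
RNGs are spawned from one `SeedSequence`, and two runs with the same inputs
produce identical draws. Because the kernel has no trajectory integrator,
divergent transitions cannot occur; the diagnostics field `n_divergent`
counts non-finite update events instead (zero in a healthy run) and the
report also carries the MH acceptance rate and the count of
stationarity-rejected transition proposals.

Convergence is summarized with rank-normalized split-Rhat and bulk ESS
(arviz). Coefficients are estimated on standardized continuous covariates
(age, day-in-study) and rescaled per draw to the original units;
the intercept absorbs the mean shifts so every fitted value is invariant to
machine precision. Indicator covariates are left on 0/1, matching the
level-difference reporting convention. Indicator columns for category
levels that never occur in a dataset are dropped (and recorded in the
codebook) so the design stays full rank under the flat coefficient priors.

## The synthetic-data generator

The generator is first-class, tested code and the ground-truth oracle for
every stage. Its defaults emulate the study conditions:

* **Population**: runner share 0.568, women 0.463, high-pollution region
  0.571, university education 0.430, SES shares (0.025, 0.798, 0.177),
  age truncated-normal(38.09, 12.55) on [18, 65]. Exercise identity (9-item
  scale, totals 9–63) is drawn per activity status — runners N(48, 8),
  inactive N(30, 9), truncated to the scale range — reflecting that the
  scale separates exercisers from non-exercisers.
* **Calendar**: four 14-day bursts at months 0/4/8/12 after a
  person-specific entry date, dispersed uniformly over an April 2019 –
  August 2021 enrolment window (continuous enrolment is what makes all
  twelve months identifiable).
* **True parameters** (`default_true_parameters`): the published posterior
  means — transition diag (0.394, 0.316) with near-zero cross-lags,
  sigma (1.2342, 0.5855), tau (1.1847, 0.3870), alpha (0.0872, 0.0105),
  and the full weekday/month/demographic coefficient sets on the original
  covariate scale.
* **Latent series**: burst-first days from the stationary VAR distribution,
  later days by the recursion; generation refuses non-stationary `B`.
* **Missingness**: MAR by construction — the config schema only admits
  observed-data predictors (base rates plus weekday multipliers), and any
  outcome-dependent key is rejected. Defaults: 12% missed evening surveys
  (×1.3 on weekends), 5% non-wear days.
* **Rendering**: inverts the transforms into raw observables. P becomes a
  daily step total spread multinomially over stepping minutes within a
  1440-minute stream with a fixed 23:00–07:00 sleep block (heart rate
  present during sleep, exercising the sleep exclusion), a worn fraction of
  wake minutes (mean 0.875), and sedentary worn minutes that carry only a
  heart-rate reading; L becomes two integer slider items whose mean
  preserves the target within 0.5 units. Preprocessing recovers each day's
  (LS mean, steps/wear-hour) within item rounding and 1% relative step
  error.

What the generator does **not** emulate: intraday EMA prompts (only the
evening survey exists), heart-rate values, sleep stages or GPS, air
pollution concentrations (region is a binary covariate), device non-wear
patterns correlated with activity, and any MNAR mechanism. Passing tests
therefore show the pipeline is correct under the stated model, not that the
model is right for any particular real cohort.

## Reference problem sizes

The packaged checks run at deliberately scaled-down sizes chosen to
exercise every code path while staying desk-sized: the
sensitivity/convergence analogue uses one study of 60 persons with 2 bursts
of 10 days (rendered to ~1.7M minute records and preprocessed back), fitted
with 4 chains of 1000 warmup / 1000–1500 sampling iterations; the recovery
smoke study uses 7 replicates of 150 persons with the full 4×14 design and
2 chains each. At these sizes the prior-sensitivity correlations come out
above 0.9999 and max split-Rhat near 1.003, comfortably inside the
full-scale study's reported envelope. `burstvar recover --reps 20` runs the
20-replicate version when more time is available.

## Numerical choices and edge cases

* Lyapunov solves go through the exact 4×4 vec equation; stacked per-person
  solves reuse one matrix inverse per `B`.
* 2×2 inverses/logdets are closed-form; the coefficient draw uses a
  Cholesky solve and raises a clear error (suggesting the proper-prior
  fallback) if the design is rank-deficient.
* Slice-sampler widths are fixed (0.1 on log sigma and alpha, 0.3 on log
  tau); slice sampling is insensitive to these within wide margins.
* `transform_ls` rejects inputs outside [0, 100]; `transform_pa` rejects
  negative rates; a day with zero valid wear minutes has a missing PA rate
  by definition; two-item LS with one missing item defaults to a missing
  day (config: fall back to the single item).
* Ties in the two-item split: items are `round(ls ± d)` with `d` shrunk
  near the slider bounds so the mean is always representable.
* Degenerate inputs: n=1 populations standardize exercise identity with a
  unit guard; persons need at least one burst of two days to be fittable.

## Known limitations

* **Slider-bound censoring.** The latent Gaussian model puts ~2% of days
  outside the representable LS range (|L| > 4.615 maps outside [0, 100]) at
  the study-like regime, so observable data are slightly tail-compressed.
  In recovery studies this attenuates `sigma_L` (≈ −0.035) and `tau_L`
  (≈ −0.05) while `beta`, `alpha`, and the P-scale parameters recover
  cleanly. This is a property of the bounded measurement design itself, not
  of the sampler (the likelihood is oracle-verified), and it would affect
  any Gaussian analysis of transformed slider data.
* Exercise identity moderates only the contemporaneous correlation;
  weekday/season moderation of the LS–PA link is intentionally out of
  scope, as are higher-order lags and time-varying transition matrices.
* Reported `alpha1` stays on the standardized exercise-identity scale
  (per-SD), unlike the mean-model coefficients which are rescaled to
  original units; `tanh(alpha0)` is the correlation at the sample-average
  score either way.
* Reproducibility is per package version: a change in update order or
  numerics would change draws for a given seed (posteriors agree within
  Monte Carlo error).
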