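# Methods

`telemove` implements a covariate-driven hidden Markov model (HMM) for animal
movement telemetry, together with the synthetic-data machinery needed to test
it end to end, and a correlated-random-walk simulator that links movement
states to landscape connectivity. This note documents the model, the choices
that were genuinely open, the defaults and their units, and what the synthetic
experiments do and do not demonstrate.

## The movement model

Observations are *steps*: at a fixed sampling interval (default 80 minutes),
each step has a length `l_t` (km) and a turning angle `theta_t` (radians in
(-pi, pi], counterclockwise positive). Conditional on a latent behavioural
state `S_t` in {1..N}:

- `l_t | S_t = k ~ Gamma(mean mu_k, sd sigma_k)` with shape `(mu_k/sigma_k)^2`
  and rate `mu_k/sigma_k^2`;
- `theta_t | S_t = k ~ von Mises(m_k, kappa_k)`.

State switching is Markov with a transition probability matrix that depends on
covariates measured at the step's start position. With covariate row `z`, the
off-diagonal linear predictors are `eta_ij = beta_0ij + beta'_ij z`, the
diagonal predictors are fixed at 0 (the multinomial-logit reference), and row
`i` of `Gamma(z)` is the softmax of its predictors. Covariates enter
additively; interactions are not modeled. The default covariates are the
z-scored human-footprint index at the step start (`hfi_std`), a protected-area
indicator (`in_park`), and a denning-season indicator (`denning`, Julian days
160-220 inclusive).

The initial state distribution of each track is the stationary distribution of
`Gamma` at the track's first observed covariate row. This adds no free
parameters and is well defined under covariates; it is a convention of this
package (alternatives include free initial probabilities or a uniform start).
The parameter count is therefore `p = 4N + (1 + c) N(N-1)` for `c` covariates.

Missing observations (gaps in the fix series, filtered resting steps)
contribute an emission factor of one for the missing component while
transitions still advance across the slot. Zero-length steps cannot occur
after the minimum-step filter, so the gamma density needs no zero-inflation
term. Covariate values at slots with missing positions are forward-filled
within a track (then back-filled at the start) so transitions remain defined.

## Estimation

The likelihood is maximized over a working-scale vector
`[log mu, log sigma, m, log kappa, vec(beta)]` (angle means are unconstrained
and wrapped to (-pi, pi] on output) by L-BFGS-B with finite-difference
gradients, from `n_starts` initializations (default 10). The first start
splits the sorted observed step lengths into N quantile groups for
`(mu, sigma)`, uses the pooled circular concentration for every `kappa`, and
intercepts giving a 0.8 diagonal; later starts jitter these (log-normal ~20%
on positive parameters, normal on angle means and coefficients). The scaled
forward recursion (numba-compiled) underlies every likelihood evaluation.
Convergence tolerance `tol` maps to the optimizer's relative `ftol`
(default 1e-9; loosening it past ~1e-8 makes independent multi-start runs
disagree in log-likelihood by more than 1e-4). Wide box bounds (e.g. |log mu| <= 10) only guard against
floating-point overflow.

Fitted states are relabeled by increasing step mean, permuting the transition
coefficients consistently, so "state 1" is always the slowest. Ties in
Viterbi backtracking resolve toward the lower state index.

The observed information is a central finite-difference Hessian of the
negative log-likelihood at the (relabeled) optimum (relative step 1e-4); its
inverse is the working-scale covariance. When the Hessian fails a Cholesky
test the pseudo-inverse is used instead, and an error is raised only if no
finite inverse exists — a deliberate softening that keeps large replicate
experiments robust while still surfacing truly degenerate fits.

## Stationary probabilities and confidence intervals

At covariates `z`, `delta(z)` solves `delta Gamma(z) = delta`,
`sum(delta) = 1` (by linear solve, not iteration). Confidence intervals use
the delta method: a central-difference gradient of `delta_k` with respect to
the working parameters (only the transition block is differentiated; the
emission block cannot move `delta`), the inverse-Hessian covariance, and a
normal interval clamped to [0, 1]. Point estimates always sum to one per grid
row; the clamping can make bounds asymmetric near 0 or 1.

## Goodness of fit

Pseudo-residuals are one-step-ahead probability integral transforms: the
forecast CDF of each observed component (the forward-weighted mixture of
state CDFs given the track's history) mapped through the standard-normal
quantile. Angle CDFs are taken on (-pi, pi] anchored at -pi. Under a
correctly specified model the residuals are standard normal; the test suite
checks both this and that a deliberately under-specified 1-state fit fails
the same Kolmogorov-Smirnov check.

## Synthetic data: what it emulates, and what it does not

`make_landscape` produces a smooth, spatially autocorrelated footprint field
(a west-east gradient plus seeded Gaussian bumps, affinely rescaled to the
configured range, default 2-16 to match the footprint contrast of a
park/buffer-zone mosaic at 1-km resolution) and marks the lowest-footprint
fraction of cells (default 50%) as the protected area. The bump width
(`bump_sd_cells`, default 12) is a free roughness knob: no empirical spatial
covariance is targeted, only "smooth at the scale of a home range".

`simulate_tracks` draws tracks from exactly the fitted model's generative
process: covariates read at the current position, next state from the
covariate-dependent transition row, then a gamma step and a von Mises turn;
heading accumulates turns (initial heading uniform), and steps leaving the
grid reflect at the boundary (after a reflection the heading is realigned
with the realized displacement). Reflection keeps tracks in bounds without
touching the state dynamics; recovery experiments use landscapes large enough
that reflections are essentially absent.

The reference emission parameters are the published three-state summaries for
African wild dogs (mean speeds 0.17/1.10/1.82 km/h, speed SDs
0.05/0.79/1.79 km/h, angle means -0.036/0.057/0.024 rad, angle circular SDs
2.16/1.59/1.65 rad), converted from speeds to 80-min step lengths by
multiplying by 4/3 h and from circular SDs to von Mises concentrations by
inverting `circ SD = sqrt(-2 ln(I1(kappa)/I0(kappa)))` (bracketed
root-finding to 1e-12). Default transition intercepts give a 0.8 diagonal at
covariate zero; the default covariate coefficients encode the qualitative
field pattern (a stronger footprint suppresses switches into the fast state;
being outside the park and denning promote them) at moderate magnitudes
(|coefficient| 0.3-0.6 per SD of covariate) — the real coefficients are not
published, so these are study conditions, not estimates.

`inject_resting` converts a random subset of steps into sub-0.2-km
displacements to exercise the resting filter. Because a rest replaces the
step's end position, the following step is perturbed too — as in real data,
where the filter is precisely what handles this.

What passing these tests shows: the estimator recovers the generating model
under its own assumptions at realistic sizes, the uncertainty quantification
is calibrated, and the pipeline is deterministic under seeds. What it does
not show: robustness to real-data violations — irregular fix success,
state-dependent missingness (the resting filter removes slow-state steps
preferentially), measurement error, or behavioural dynamics beyond a
first-order Markov chain.

## Connectivity simulation

`simulate_pattern` is a plain correlated random walk: per step an independent
gamma speed (km per step) and a von Mises(-mixture) turning angle; all
individuals start at the origin with uniform headings. A pattern "connects"
when its distance from the origin first reaches the ring radius — a pure
distance threshold, first crossing counts. The two default patterns are
qualitative emulations (fast/directed: speed mean 2 km per step, kappa 10;
slow/tortuous: speed mean 0.6, a 60/40 von Mises mixture centered at 0 and
pi): only the ordering and monotonicity claims are asserted, never specific
proportions.

## Problem sizes in the test and acceptance runs

Simulation sizes are the package's own choices, set once to leave comfortable
Monte-Carlo margins: parameter recovery uses 10 replicates of 20 tracks x 500
steps (10,000 steps; at this size the Monte-Carlo error of each mean-speed
estimate is well inside the 5% acceptance band); model selection uses 20
replicates of 6 x 200; CI-coverage checks use the 10 x 300 scenario with 30
replicates in the test suite (binomial band widened accordingly) and the full
100 replicates in `scripts/acceptance.py`; residual calibration uses 5,000
steps. The coverage experiment standardizes the footprint covariate by the
landscape's population moments (the generator's own scale) rather than
re-standardizing per replicate, so the grid point "covariate = 0" is the same
quantity in truth and fit. Coverage refits use 2 starts; recovery refits use
the full 10.

## Known limitations

- Confidence intervals are Wald-type on the natural scale; close to 0 or 1
  they are clamped rather than transformed.
- The min-step filter induces state-dependent missingness in realistic
  pipelines; emission estimates for the slowest state are then biased toward
  larger steps (by construction, not by defect), so recovery experiments skip
  the filter.
- No continuous-time or irregular-interval extension; fixes must be
  regularizable to a constant interval.
- The gamma MLE's standard deviation is not the sample SD (unlike the mean,
  which coincides with the sample mean in the 1-state case); closed-form
  checks in the tests account for this.
- `model_select` compares AIC only; it does not attempt the interpretability
  judgement needed when extra states overlap.
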