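# telemove

Covariate-driven hidden Markov models for animal movement telemetry.

Wide-ranging carnivores such as African wild dogs cross landscapes whose
permeability is shaped by people. A standard way to quantify this from GPS
collar data is a multi-state movement HMM: each latent behavioural state has
its own distribution of step lengths (gamma) and turning angles (von Mises),
and the probability of switching between states responds to covariates
measured at the start of each step — here a human-footprint index, membership
in a protected area, and a denning-season indicator. Because fast, directed
states are what carry animals to distant places, covariate effects on state
occupancy translate directly into effects on landscape connectivity.

`telemove` provides, as a Python library:

- **Track preparation** — snap raw fixes to a fixed time grid (no
  interpolation), compute step lengths and signed turning angles, set
  sub-threshold resting steps missing (default < 0.2 km), extract and
  standardize raster covariates (`telemove.prep`).
- **The HMM core** — forward likelihood with missing-data handling,
  multi-start maximum likelihood, AIC model selection over the number of
  states, Viterbi decoding, forward-backward state probabilities,
  delta-method confidence intervals for stationary state probabilities over
  covariate grids, and one-step-ahead pseudo-residuals
  (`telemove.fitting`, `telemove.decode`, `telemove.stationary`).
- **Synthetic data** — seeded footprint landscapes and ground-truth
  multi-state tracks with the exact generative structure the model assumes,
  so every stage is testable without any telemetry download
  (`telemove.landscape`, `telemove.simulate`).
- **Connectivity simulation** — a correlated-random-walk comparison showing
  how speed and turning-angle distributions drive the probability of
  reaching distant locations (`telemove.connectivity`).

## The model

For step `t` of a track, observation `(l_t, theta_t)` given state
`S_t = k in {1..N}`:

    l_t     ~ Gamma(mean mu_k, sd sigma_k)
    theta_t ~ von Mises(m_k, kappa_k)
    P(S_t = j | S_{t-1} = i) = Gamma_ij(z_t),   Gamma(z) = row-softmax(eta),
    eta_ij = beta0_ij + beta_ij' z  (i != j),   eta_ii = 0

with `z_t` the covariates at the step's start. Tracks start from the
stationary distribution of `Gamma` at their first covariate row. States are
relabeled by increasing `mu_k` so state 1 is always the slowest. Stationary
probabilities `delta(z)` solve `delta Gamma(z) = delta`; their confidence
intervals combine a numerical gradient with the inverse observed information.
See `docs/methods.md` for the full account.

## Worked example

```python
import telemove as tm

land = tm.make_landscape(seed=1, n_cells_x=300, n_cells_y=300)
spec = tm.HMMSpec(tm.wild_dog_emissions(), tm.TransitionModel.intercept_only(3, 0.8))
records = tm.synthetic_step_table(spec, land, n_tracks=10, n_steps=300, seed=6)

sel = tm.model_select(records, state_counts=(2, 3), n_starts=5, seed=0)
print(sel.table)
```

prints

```
 n_states  loglik  n_params     aic  delta_aic
        2 -8139.4        10 16298.9       38.1
        3 -8112.4        18 16260.7        0.0
```

AIC selects the three-state model the data were generated from. Its
estimated states (step mean converted back to speed over the 80-min
interval, angle dispersion as circular SD) recover the generating values
(0.17/1.10/1.82 km/h and 2.16/1.59/1.65 rad):

```
state 1: step mean 0.22 km (0.17 km/h), angle circular SD 2.06 rad
state 2: step mean 1.41 km (1.06 km/h), angle circular SD 1.60 rad
state 3: step mean 2.37 km (1.78 km/h), angle circular SD 1.61 rad
```

With a footprint covariate in the transitions
(`tm.wild_dog_spec(covariates=("hfi_std",))`), fitting and calling
`tm.stationary_with_ci` over a covariate grid traces how state occupancy
responds to the footprint:

```
 hfi_std  delta1   lo1   hi1  delta2   lo2   hi2  delta3   lo3   hi3
    -2.0   0.179 0.081 0.277   0.432 0.210 0.653   0.389 0.193 0.585
     0.0   0.344 0.284 0.404   0.475 0.363 0.588   0.181 0.074 0.288
     2.0   0.511 0.352 0.670   0.432 0.275 0.589   0.057 0.000 0.121
```

The long-run probability of the fast, directed state (`delta3`) falls from
0.39 to 0.06 across four SDs of footprint while the slow state rises — the
generator encodes exactly this suppression of fast movement by the human
footprint, and the fitted curves recover it with pointwise 95% bounds.

The scripts in `examples/` walk through each capability (landscape and track
simulation, step preparation, fitting and decoding, stationary curves,
connectivity) and print annotated output; `telemove pipeline -c config.toml`
runs the whole chain from a TOML configuration and writes CSV/JSON/PNG
artifacts.

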