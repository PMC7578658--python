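"""Shared fixtures and brute-force oracles for the test suite.

The enumeration oracles compute HMM quantities by summing/maximizing over all
N^T state sequences; they share nothing with the package's recursions beyond
the emission densities' mathematical definition, which is re-derived here via
scipy.stats.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises

import telemove as tm
from telemove.model import stationary_distribution, transition_matrix


@pytest.fixture(scope="session")
def landscape():
    return tm.make_landscape(seed=7, n_cells_x=80, n_cells_y=80)


@pytest.fixture(scope="session")
def big_landscape():
    # large extent so simulated tracks essentially never hit the boundary
    return tm.make_landscape(seed=11, n_cells_x=400, n_cells_y=400)


@pytest.fixture(scope="session")
def ref_emissions():
    return tm.wild_dog_emissions()


@pytest.fixture(scope="session")
def ref_spec_nocov(ref_emissions):
    return tm.HMMSpec(ref_emissions, tm.TransitionModel.intercept_only(3, 0.8))


def toy_records(steps, angles, covs=None, ids=None):
    """Build a step table from raw arrays (NaN = missing)."""
    steps = np.asarray(steps, dtype=float)
    df = pd.DataFrame(
        {
            "id": ids if ids is not None else "a",
            "t": pd.date_range("2018-01-01", periods=steps.size, freq="80min"),
            "x_km": 0.0,
            "y_km": 0.0,
            "step_km": steps,
            "angle_rad": np.asarray(angles, dtype=float),
        }
    )
    if covs is not None:
        for name, vals in covs.items():
            df[name] = np.asarray(vals, dtype=float)
    return df


def emission_density_oracle(spec, step, angle, state):
    """Per-observation emission density via scipy, missing components -> 1."""
    em = spec.emissions
    dens = 1.0
    if np.isfinite(step):
        dens *= gamma_dist.pdf(step, a=em.gamma_shape[state],
                               scale=em.step_sd[state] ** 2 / em.step_mean[state])
    if np.isfinite(angle):
        dens *= vonmises.pdf(angle, em.angle_conc[state], loc=em.angle_mean[state])
    return dens


def _sequence_prob(spec, steps, angles, zrows, seq):
    tpms = [transition_matrix(spec.transitions, z) for z in zrows]
    prob = stationary_distribution(tpms[0])[seq[0]]
    prob *= emission_density_oracle(spec, steps[0], angles[0], seq[0])
    for t in range(1, len(seq)):
        prob *= tpms[t][seq[t - 1], seq[t]]
        prob *= emission_density_oracle(spec, steps[t], angles[t], seq[t])
    return prob


def enumerate_loglik(spec, steps, angles, zrows):
    """log sum over all N^T sequences of the joint density."""
    n, t = spec.n_states, len(steps)
    total = 0.0
    for seq in itertools.product(range(n), repeat=t):
        total += _sequence_prob(spec, steps, angles, zrows, seq)
    return np.log(total)

def enumerate_viterbi(spec, steps, angles, zrows):
    """argmax over all sequences; ties resolved toward the lexicographically lowest."""
    n, t = spec.n_states, len(steps)
    best, best_p = None, -1.0
    for seq in itertools.product(range(n), repeat=t):
        p = _sequence_prob(spec, steps, angles, zrows, seq)
        if p > best_p:
            best, best_p = seq, p
    return np.asarray(best) + 1


def enumerate_posteriors(spec, steps, angles, zrows):
    """Smoothed marginals by summing sequence probabilities."""
    n, t = spec.n_states, len(steps)
    post = np.zeros((t, n))
    for seq in itertools.product(range(n), repeat=t):
        p = _sequence_prob(spec, steps, angles, zrows, seq)
        for i, s in enumerate(seq):
            post[i, s] += p
    return post / post.sum(axis=1, keepdims=True)


def random_toy(n_states, t, seed, with_missing=False, n_cov=0):
    """A random small spec + observation set for oracle comparisons."""
    rng = np.random.default_rng(seed)
    em = tm.EmissionParams(
        step_mean=rng.uniform(0.3, 3.0, n_states),
        step_sd=rng.uniform(0.2, 1.5, n_states),
        angle_mean=rng.uniform(-3, 3, n_states),
        angle_conc=rng.uniform(0.2, 5.0, n_states),
    )
    covs = tuple(f"z{i}" for i in range(n_cov))
    beta = rng.normal(0, 0.7, (1 + n_cov, n_states * (n_states - 1)))
    spec = tm.HMMSpec(em, tm.TransitionModel(n_states, beta, covs))
    steps = rng.gamma(2.0, 0.8, t)
    angles = rng.uniform(-np.pi, np.pi, t)
    if with_missing:
        steps[rng.random(t) < 0.3] = np.nan
        angles[rng.random(t) < 0.3] = np.nan
    angles[0] = np.nan  # first angle undefined by construction
    zrows = rng.normal(0, 1, (t, n_cov))
    return spec, steps, angles, zrows


def records_from_toy(steps, angles, zrows, covs):
    covmap = {name: zrows[:, i] for i, name in enumerate(covs)}
    return toy_records(steps, angles, covs=covmap)
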