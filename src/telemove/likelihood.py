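"""Scaled forward likelihood for the covariate-driven movement HMM.

The observation at step t is the pair (step length, turning angle); either
component may be missing, in which case its emission factor is one while
transitions still advance across the slot. Per track, the initial state
distribution is the stationary distribution of the transition matrix at the
first step's covariate row.

The full per-step recursion — emission log-densities, row-softmax transition
matrices and the scaled forward pass — is compiled with numba; observation
transforms that do not change between evaluations (log step lengths, angle
cosines/sines) are cached on :class:`StepData`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln, i0e

from .model import EmissionParams, HMMSpec, offdiag_pairs, stationary_distribution, transition_matrix

LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class StepData:
    """Step table unpacked into flat arrays for the likelihood kernels.

    ``design`` is the (T, 1+c) matrix (1, z_t); tracks are contiguous
    segments delimited by ``seg_start``/``seg_len``. The log/trig caches hold
    zeros where the component is missing, with companion 0/1 masks.
    """

    steps: np.ndarray
    angles: np.ndarray
    design: np.ndarray
    seg_start: np.ndarray
    seg_len: np.ndarray
    ids: list
    steps0: np.ndarray
    log_steps: np.ndarray
    step_obs: np.ndarray
    cos_a: np.ndarray
    sin_a: np.ndarray
    angle_obs: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.steps.size

    @property
    def n_observed(self) -> int:
        return int(self.step_obs.sum())


def prepare_step_data(records: pd.DataFrame, covariates: tuple[str, ...]) -> StepData:
    """Build a StepData from a step table, forward-filling covariate gaps.

    Covariates can be missing only where the start position was missing; the
    last observed row is carried forward (and the first observed row backward)
    so transitions remain defined across missing slots.
    """
    steps_l, angles_l, zs, seg_start, seg_len, ids = [], [], [], [], [], []
    pos = 0
    for ind, df in records.groupby("id", sort=False):
        t = len(df)
        steps_l.append(df["step_km"].to_numpy(dtype=float))
        angles_l.append(df["angle_rad"].to_numpy(dtype=float))
        if covariates:
            z = df[list(covariates)].astype(float).ffill().bfill().to_numpy()
            if not np.all(np.isfinite(z)):
                raise ValueError(f"individual {ind!r} has no observed covariate values")
        else:
            z = np.zeros((t, 0))
        zs.append(z)
        seg_start.append(pos)
        seg_len.append(t)
        ids.append(ind)
        pos += t
    steps = np.concatenate(steps_l)
    angles = np.concatenate(angles_l)
    design = np.hstack([np.ones((steps.size, 1)), np.vstack(zs)])
    step_obs = np.isfinite(steps) & (steps > 0)
    angle_obs = np.isfinite(angles)
    steps0 = np.where(step_obs, steps, 1.0)
    return StepData(
        steps=steps,
        angles=angles,
        design=design,
        seg_start=np.asarray(seg_start, dtype=np.int64),
        seg_len=np.asarray(seg_len, dtype=np.int64),
        ids=ids,
        steps0=steps0,
        log_steps=np.log(steps0),
        step_obs=step_obs.astype(np.float64),
        cos_a=np.where(angle_obs, np.cos(np.where(angle_obs, angles, 0.0)), 0.0),
        sin_a=np.where(angle_obs, np.sin(np.where(angle_obs, angles, 0.0)), 0.0),
        angle_obs=angle_obs.astype(np.float64),
    )


def gamma_log_norm(em: EmissionParams) -> np.ndarray:
    shape = em.gamma_shape
    return shape * np.log(em.gamma_rate) - gammaln(shape)


def vonmises_log_norm(em: EmissionParams) -> np.ndarray:
    kappa = em.angle_conc
    return -(LOG_2PI + np.log(i0e(kappa)) + kappa)


def emission_logprobs(em: EmissionParams, steps: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(T, N) log emission densities; missing components contribute 0."""
    n = em.n_states
    logp = np.zeros((steps.size, n))
    shape, rate = em.gamma_shape, em.gamma_rate
    obs_s = np.isfinite(steps) & (steps > 0)
    s = steps[obs_s, None]
    logp[obs_s] += (shape - 1.0) * np.log(s) - rate * s + gamma_log_norm(em)
    obs_a = np.isfinite(angles)
    a = angles[obs_a, None]
    logp[obs_a] += em.angle_conc * np.cos(a - em.angle_mean) + vonmises_log_norm(em)
    return logp


@njit(cache=False)
def _forward_nll_kernel(steps0, log_steps, step_obs, cos_a, sin_a, angle_obs,
                        shape, rate, lng, kappa, cos_m, sin_m, lnv,
                        eta, pair_i, pair_j, seg_start, seg_len, init):
    """Negative log-likelihood by the scaled forward recursion.

    ``eta[t]`` are off-diagonal linear predictors ordered by (pair_i, pair_j);
    the matrix used to advance from step t-1 to step t is built from eta[t]
    (covariates at the start of step t). Emission log-densities are computed
    inline from the cached observation transforms.
    """
    n = shape.size
    n_off = pair_i.size
    total = 0.0
    alpha = np.empty(n)
    alpha_new = np.empty(n)
    gamma = np.empty((n, n))
    lp = np.empty(n)
    for s in range(seg_start.size):
        a0 = seg_start[s]
        length = seg_len[s]
        for t in range(a0, a0 + length):
            for k in range(n):
                v = 0.0
                if step_obs[t] > 0.0:
                    v += (shape[k] - 1.0) * log_steps[t] - rate[k] * steps0[t] + lng[k]
                if angle_obs[t] > 0.0:
                    v += kappa[k] * (cos_a[t] * cos_m[k] + sin_a[t] * sin_m[k]) + lnv[k]
                lp[k] = v
            c = lp[0]
            for k in range(1, n):
                if lp[k] > c:
                    c = lp[k]
            if t == a0:
                w = 0.0
                for k in range(n):
                    alpha[k] = init[s, k] * np.exp(lp[k] - c)
                    w += alpha[k]
            else:
                for i in range(n):
                    for j in range(n):
                        gamma[i, j] = 0.0
                for k in range(n_off):
                    gamma[pair_i[k], pair_j[k]] = eta[t, k]
                for i in range(n):
                    m = 0.0
                    for j in range(n):
                        if gamma[i, j] > m:
                            m = gamma[i, j]
                    denom = 0.0
                    for j in range(n):
                        gamma[i, j] = np.exp(gamma[i, j] - m)
                        denom += gamma[i, j]
                    for j in range(n):
                        gamma[i, j] /= denom
                w = 0.0
                for j in range(n):
                    acc = 0.0
                    for i in range(n):
                        acc += alpha[i] * gamma[i, j]
                    alpha_new[j] = acc * np.exp(lp[j] - c)
                    w += alpha_new[j]
                for j in range(n):
                    alpha[j] = alpha_new[j]
            if not (w > 0.0) or not np.isfinite(w):
                return np.inf
            total += np.log(w) + c
            for k in range(n):
                alpha[k] /= w
    return -total


def _kernel_nll(em_arrays, eta, pi, pj, data: StepData, init) -> float:
    shape, rate, lng, kappa, cos_m, sin_m, lnv = em_arrays
    return _forward_nll_kernel(
        data.steps0, data.log_steps, data.step_obs, data.cos_a, data.sin_a, data.angle_obs,
        shape, rate, lng, kappa, cos_m, sin_m, lnv, eta, pi, pj,
        data.seg_start, data.seg_len, init,
    )


def emission_arrays(em: EmissionParams):
    return (em.gamma_shape, em.gamma_rate, gamma_log_norm(em), em.angle_conc,
            np.cos(em.angle_mean), np.sin(em.angle_mean), vonmises_log_norm(em))


def _initial_distributions(spec: HMMSpec, data: StepData) -> np.ndarray:
    init = np.empty((data.seg_start.size, spec.n_states))
    for s, a0 in enumerate(data.seg_start):
        z = data.design[a0, 1:]
        init[s] = stationary_distribution(transition_matrix(spec.transitions, z))
    return init


def forward_loglik(spec: HMMSpec, records_or_data) -> float:
    """Total log-likelihood of a step table (or prepared StepData) under ``spec``."""
    data = (records_or_data if isinstance(records_or_data, StepData)
            else prepare_step_data(records_or_data, spec.covariates))
    eta = data.design @ spec.transitions.beta
    pairs = offdiag_pairs(spec.n_states)
    pi = np.array([p[0] for p in pairs], dtype=np.int64)
    pj = np.array([p[1] for p in pairs], dtype=np.int64)
    init = _initial_distributions(spec, data)
    nll = _kernel_nll(emission_arrays(spec.emissions), eta, pi, pj, data, init)
    return -float(nll)


def per_step_tpms(spec: HMMSpec, data: StepData) -> np.ndarray:
    """(T, N, N) transition matrices from each step's covariate row (vectorized)."""
    from .model import transition_matrices

    return transition_matrices(spec.transitions, data.design)
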