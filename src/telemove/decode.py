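"""State decoding, smoothing and goodness-of-fit for fitted movement HMMs.

Viterbi gives the jointly most probable state sequence per track;
forward-backward gives per-step posterior state probabilities; one-step-ahead
pseudo-residuals map each observed component through its forecast CDF and the
standard-normal quantile, so a correctly specified model yields standard
normal residuals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, vonmises

from .fitting import HMMFit
from .likelihood import StepData, emission_logprobs, per_step_tpms, prepare_step_data
from .model import HMMSpec, stationary_distribution, transition_matrix, wrap_angle


def _as_spec(fit_or_spec) -> HMMSpec:
    return fit_or_spec.spec if isinstance(fit_or_spec, HMMFit) else fit_or_spec


def _prepared(spec: HMMSpec, records) -> StepData:
    return records if isinstance(records, StepData) else prepare_step_data(records, spec.covariates)


def _segment_arrays(spec: HMMSpec, data: StepData):
    logp = emission_logprobs(spec.emissions, data.steps, data.angles)
    tpms = per_step_tpms(spec, data)
    inits = [
        stationary_distribution(transition_matrix(spec.transitions, data.design[a0, 1:]))
        for a0 in data.seg_start
    ]
    return logp, tpms, inits


def viterbi(fit_or_spec, records) -> np.ndarray:
    """Most probable joint state sequence (1-based), ties toward the lower index."""
    spec = _as_spec(fit_or_spec)
    data = _prepared(spec, records)
    logp, tpms, inits = _segment_arrays(spec, data)
    n = spec.n_states
    states = np.empty(data.n_steps, dtype=int)
    with np.errstate(divide="ignore"):
        log_tpms = np.log(tpms)
    for s, (a0, ln) in enumerate(zip(data.seg_start, data.seg_len)):
        delta = np.log(inits[s]) + logp[a0]
        psi = np.zeros((ln, n), dtype=int)
        for t in range(1, ln):
            cand = delta[:, None] + log_tpms[a0 + t]  # (from, to)
            psi[t] = np.argmax(cand, axis=0)
            delta = cand[psi[t], np.arange(n)] + logp[a0 + t]
        path = np.empty(ln, dtype=int)
        path[-1] = int(np.argmax(delta))
        for t in range(ln - 1, 0, -1):
            path[t - 1] = psi[t, path[t]]
        states[a0:a0 + ln] = path + 1
    return states


def _forward_backward(spec: HMMSpec, data: StepData) -> np.ndarray:
    logp, tpms, inits = _segment_arrays(spec, data)
    n = spec.n_states
    post = np.empty((data.n_steps, n))
    for s, (a0, ln) in enumerate(zip(data.seg_start, data.seg_len)):
        p = np.exp(logp[a0:a0 + ln] - logp[a0:a0 + ln].max(axis=1, keepdims=True))
        alpha = np.empty((ln, n))
        a = inits[s] * p[0]
        alpha[0] = a / a.sum()
        for t in range(1, ln):
            a = (alpha[t - 1] @ tpms[a0 + t]) * p[t]
            alpha[t] = a / a.sum()
        beta = np.empty((ln, n))
        beta[-1] = 1.0
        for t in range(ln - 2, -1, -1):
            b = tpms[a0 + t + 1] @ (p[t + 1] * beta[t + 1])
            beta[t] = b / b.sum()
        g = alpha * beta
        post[a0:a0 + ln] = g / g.sum(axis=1, keepdims=True)
    return post


@dataclass(frozen=True)
class DecodedTrack:
    """Viterbi states plus smoothed posteriors for every step record."""

    table: pd.DataFrame  # id, t, viterbi_state, p_state*, p_assigned
    mean_assigned_prob: float
    sd_assigned_prob: float

    @property
    def states(self) -> np.ndarray:
        return self.table["viterbi_state"].to_numpy()

    @property
    def posterior(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("p_state")]
        return self.table[cols].to_numpy()


def state_probs(fit_or_spec, records) -> DecodedTrack:
    """Forward-backward smoothed state probabilities plus the Viterbi path.

    Also reports the mean and SD of the posterior probability of the assigned
    (Viterbi) state — the usual summary of decoding confidence.
    """
    spec = _as_spec(fit_or_spec)
    data = _prepared(spec, records)
    post = _forward_backward(spec, data)
    states = viterbi(spec, data)
    p_assigned = post[np.arange(post.shape[0]), states - 1]
    ids = np.concatenate([
        np.repeat(ind, ln) for ind, ln in zip(data.ids, data.seg_len)
    ])
    table = pd.DataFrame({"id": ids, "viterbi_state": states})
    for k in range(spec.n_states):
        table[f"p_state{k + 1}"] = post[:, k]
    table["p_assigned"] = p_assigned
    return DecodedTrack(table, float(p_assigned.mean()), float(p_assigned.std()))


def _vonmises_cdf_anchored(theta, mean, kappa):
    """P(angle in (-pi, theta]) for a von Mises wrapped to (-pi, pi]."""
    a = wrap_angle(np.asarray(theta, dtype=float) - mean)
    b = wrap_angle(-np.pi - mean)
    val = vonmises.cdf(a, kappa) - vonmises.cdf(b, kappa)
    return val + (a <= b)


def pseudo_residuals(fit_or_spec, records) -> pd.DataFrame:
    """One-step-ahead forecast pseudo-residuals on the standard-normal scale.

    For each observed component, the forecast CDF is the forward-weighted
    mixture of state CDFs given all previous observations in the track;
    mapping through the normal quantile yields residuals that are standard
    normal iff the model is correctly specified. Missing observations give
    missing residuals.
    """
    spec = _as_spec(fit_or_spec)
    data = _prepared(spec, records)
    logp, tpms, inits = _segment_arrays(spec, data)
    n = spec.n_states
    em = spec.emissions
    weights = np.empty((data.n_steps, n))
    for s, (a0, ln) in enumerate(zip(data.seg_start, data.seg_len)):
        p = np.exp(logp[a0:a0 + ln] - logp[a0:a0 + ln].max(axis=1, keepdims=True))
        w = inits[s]
        weights[a0] = w
        filt = w * p[0]
        filt /= filt.sum()
        for t in range(1, ln):
            w = filt @ tpms[a0 + t]
            weights[a0 + t] = w
            filt = w * p[t]
            filt /= filt.sum()

    step_res = np.full(data.n_steps, np.nan)
    obs = np.isfinite(data.steps)
    if obs.any():
        cdf = gamma_dist.cdf(data.steps[obs, None], a=em.gamma_shape,
                             scale=em.step_sd**2 / em.step_mean)
        u = np.clip((weights[obs] * cdf).sum(axis=1), 1e-12, 1 - 1e-12)
        step_res[obs] = norm.ppf(u)

    angle_res = np.full(data.n_steps, np.nan)
    obs = np.isfinite(data.angles)
    if obs.any():
        cdf = np.column_stack([
            _vonmises_cdf_anchored(data.angles[obs], em.angle_mean[k], em.angle_conc[k])
            for k in range(n)
        ])
        u = np.clip((weights[obs] * cdf).sum(axis=1), 1e-12, 1 - 1e-12)
        angle_res[obs] = norm.ppf(u)

    ids = np.concatenate([np.repeat(ind, ln) for ind, ln in zip(data.ids, data.seg_len)])
    return pd.DataFrame({"id": ids, "step_resid": step_res, "angle_resid": angle_res})
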