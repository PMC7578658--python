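"""Stationary state probabilities over covariate grids, with delta-method CIs.

At fixed covariates z, the stationary distribution delta(z) solves
delta Gamma(z) = delta with probabilities summing to one — the long-run
occupancy of each behavioural state. Uncertainty comes from the delta
method: a numerical gradient of delta_k with respect to the working-scale
parameters, combined with the inverse observed-information covariance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .fitting import HMMFit, unpack_params
from .model import stationary_distribution, transition_matrix


@dataclass(frozen=True)
class StationaryCurve:
    """Stationary probabilities and CI bounds per covariate-grid row and state."""

    table: pd.DataFrame  # grid columns + delta{k}, lo{k}, hi{k}
    level: float

    def delta(self) -> np.ndarray:
        cols = [c for c in self.table.columns if c.startswith("delta")]
        return self.table[cols].to_numpy()


def covariate_grid(covariates, vary: str, values, fixed=None) -> pd.DataFrame:
    """Grid varying one covariate with the others held fixed (default 0)."""
    fixed = dict(fixed or {})
    values = np.asarray(values, dtype=float)
    grid = pd.DataFrame({vary: values})
    for name in covariates:
        if name != vary:
            grid[name] = fixed.get(name, 0.0)
    return grid[list(covariates)]


def _delta_at(theta, n_states, covariates, z) -> np.ndarray:
    spec = unpack_params(theta, n_states, covariates)
    return stationary_distribution(transition_matrix(spec.transitions, z))


def stationary_with_ci(fit: HMMFit, grid, level: float = 0.95) -> StationaryCurve:
    """Stationary probabilities with normal delta-method confidence bounds.

    ``grid`` is a DataFrame with one column per transition covariate (see
    :func:`covariate_grid`). Bounds are clamped to [0, 1]; per row the point
    estimates sum to one exactly.
    """
    spec = fit.spec
    n = spec.n_states
    covariates = spec.covariates
    if isinstance(grid, pd.DataFrame):
        zgrid = grid[list(covariates)].to_numpy(dtype=float)
    else:
        zgrid = np.atleast_2d(np.asarray(grid, dtype=float))
    cov = fit.covariance()
    theta = fit.working
    # only the transition block moves delta; restrict differentiation to it
    beta_idx = np.arange(4 * n, theta.size)
    zcrit = norm.ppf(0.5 + level / 2.0)

    rows = []
    for z in zgrid:
        delta = _delta_at(theta, n, covariates, z)
        grad = np.zeros((n, theta.size))
        for i in beta_idx:
            h = 1e-6 * (1.0 + abs(theta[i]))
            tp = theta.copy()
            tm = theta.copy()
            tp[i] += h
            tm[i] -= h
            grad[:, i] = (_delta_at(tp, n, covariates, z) - _delta_at(tm, n, covariates, z)) / (2 * h)
        var = np.einsum("kp,pq,kq->k", grad, cov, grad)
        se = np.sqrt(np.maximum(var, 0.0))
        lo = np.clip(delta - zcrit * se, 0.0, 1.0)
        hi = np.clip(delta + zcrit * se, 0.0, 1.0)
        rows.append((delta, lo, hi))

    table = pd.DataFrame(zgrid, columns=list(covariates))
    for k in range(n):
        table[f"delta{k + 1}"] = [r[0][k] for r in rows]
        table[f"lo{k + 1}"] = [r[1][k] for r in rows]
        table[f"hi{k + 1}"] = [r[2][k] for r in rows]
    return StationaryCurve(table, level)
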