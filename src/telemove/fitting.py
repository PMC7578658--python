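"""Maximum-likelihood fitting of movement HMMs by multi-start quasi-Newton.

The working-scale parameter vector is
``[log mu (N), log sigma (N), angle mean (N), log kappa (N), beta.ravel()]``
so the optimization is smooth and unconstrained (L-BFGS-B with wide box
bounds guards against overflow only). Fitted states are relabeled by
increasing step mean; the observed-information Hessian is evaluated at the
relabeled optimum by central finite differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .likelihood import StepData, _kernel_nll, prepare_step_data
from .model import (EmissionParams, HMMSpec, TransitionModel, circular_sd_kappa,
                    offdiag_pairs, transition_matrices, wrap_angle)


class FittingError(RuntimeError):
    pass


def n_working_params(n_states: int, n_covariates: int) -> int:
    return 4 * n_states + (1 + n_covariates) * n_states * (n_states - 1)


def pack_params(spec: HMMSpec) -> np.ndarray:
    em = spec.emissions
    return np.concatenate(
        [np.log(em.step_mean), np.log(em.step_sd), em.angle_mean, np.log(em.angle_conc),
         spec.transitions.beta.ravel()]
    )


def unpack_params(theta: np.ndarray, n_states: int, covariates: tuple[str, ...]) -> HMMSpec:
    n, c = n_states, len(covariates)
    em = EmissionParams(
        step_mean=np.exp(theta[:n]),
        step_sd=np.exp(theta[n:2 * n]),
        angle_mean=wrap_angle(theta[2 * n:3 * n]),
        angle_conc=np.exp(theta[3 * n:4 * n]),
    )
    beta = theta[4 * n:].reshape(1 + c, n * (n - 1))
    return HMMSpec(em, TransitionModel(n, beta, covariates))


def _batched_stationary(gammas: np.ndarray) -> np.ndarray:
    n = gammas.shape[-1]
    a = np.eye(n) - gammas + 1.0
    b = np.ones((gammas.shape[0], n, 1))
    delta = np.linalg.solve(np.swapaxes(a, -1, -2), b)[..., 0]
    return delta / delta.sum(axis=1, keepdims=True)


def _nll_theta(theta, data: StepData, n_states: int, covariates, pi, pj) -> float:
    from scipy.special import gammaln, i0e

    n, c = n_states, len(covariates)
    mu = np.exp(theta[:n])
    sd = np.exp(theta[n:2 * n])
    m = np.atleast_1d(wrap_angle(theta[2 * n:3 * n]))
    kappa = np.exp(theta[3 * n:4 * n])
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sd)) and np.all(np.isfinite(kappa))):
        return 1e12
    shape = (mu / sd) ** 2
    rate = mu / sd**2
    lng = shape * np.log(rate) - gammaln(shape)
    lnv = -(np.log(2.0 * np.pi) + np.log(i0e(kappa)) + kappa)
    beta = theta[4 * n:].reshape(1 + c, n * (n - 1))
    eta = data.design @ beta
    tm = TransitionModel.__new__(TransitionModel)
    object.__setattr__(tm, "n_states", n)
    object.__setattr__(tm, "beta", beta)
    object.__setattr__(tm, "covariates", tuple(covariates))
    init = _batched_stationary(transition_matrices(tm, data.design[data.seg_start]))
    em_arrays = (shape, rate, lng, kappa, np.cos(m), np.sin(m), lnv)
    nll = _kernel_nll(em_arrays, eta, pi, pj, data, init)
    return float(nll) if np.isfinite(nll) else 1e12


@dataclass
class HMMFit:
    """A fitted movement HMM with estimates relabeled by increasing step mean."""

    spec: HMMSpec
    loglik: float
    n_params: int
    working: np.ndarray
    hessian: np.ndarray | None
    converged: bool
    n_starts: int
    n_obs: int
    start_logliks: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def covariance(self) -> np.ndarray:
        """Working-scale covariance: inverse observed information.

        Falls back to the Moore-Penrose pseudo-inverse when the Hessian is not
        positive definite; raises if no finite inverse exists.
        """
        if self.hessian is None:
            raise FittingError("fit has no Hessian; refit with compute_hessian=True")
        try:
            np.linalg.cholesky(self.hessian)
            cov = np.linalg.inv(self.hessian)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(self.hessian)
        if not np.all(np.isfinite(cov)):
            raise FittingError(
                "singular Hessian: the model is not identified at this optimum; "
                "try more data or more starts"
            )
        return cov


def _quantile_start(data: StepData, n_states: int, covariates, diag_prob=0.8) -> np.ndarray:
    steps = np.sort(data.steps[np.isfinite(data.steps)])
    if steps.size < 2 * n_states:
        raise FittingError("too few observed steps to initialize the fit")
    groups = np.array_split(steps, n_states)
    mu0 = np.array([g.mean() for g in groups])
    sd0 = np.array([max(g.std(), 0.1 * g.mean()) for g in groups])
    angles = data.angles[np.isfinite(data.angles)]
    if angles.size:
        rho = float(np.hypot(np.cos(angles).sum(), np.sin(angles).sum()) / angles.size)
        rho = min(max(rho, 1e-3), 0.999)
        kappa0 = circular_sd_kappa(float(np.sqrt(-2.0 * np.log(rho))), "to_kappa")
        kappa0 = max(kappa0, 0.1)
    else:
        kappa0 = 0.5
    n_off = n_states * (n_states - 1)
    beta0 = np.zeros((1 + len(covariates), n_off))
    if n_states > 1:
        beta0[0] = np.log((1.0 - diag_prob) / (n_states - 1) / diag_prob)
    return np.concatenate(
        [np.log(mu0), np.log(sd0), np.zeros(n_states), np.full(n_states, np.log(kappa0)),
         beta0.ravel()]
    )


def _jitter(theta0, n_states, covariates, rng) -> np.ndarray:
    n = n_states
    theta = theta0.copy()
    theta[:n] += rng.normal(0, 0.2, n)          # log mu
    theta[n:2 * n] += rng.normal(0, 0.2, n)     # log sigma
    theta[2 * n:3 * n] += rng.normal(0, 0.3, n)  # angle mean
    theta[3 * n:4 * n] += rng.normal(0, 0.2, n)  # log kappa
    n_off = n * (n - 1)
    if n_off:
        beta = theta[4 * n:].reshape(-1, n_off)
        beta[0] += rng.normal(0, 0.5, n_off)
        if beta.shape[0] > 1:
            beta[1:] += rng.normal(0, 0.3, (beta.shape[0] - 1, n_off))
    return theta


def _relabel_by_step_mean(theta: np.ndarray, n_states: int, covariates) -> np.ndarray:
    n = n_states
    order = np.argsort(theta[:n], kind="stable")
    if np.array_equal(order, np.arange(n)):
        return theta
    out = theta.copy()
    for b in range(4):
        out[b * n:(b + 1) * n] = theta[b * n:(b + 1) * n][order]
    pairs = offdiag_pairs(n)
    idx = {p: k for k, p in enumerate(pairs)}
    col_perm = [idx[(order[a], order[b])] for a, b in pairs]
    n_off = n * (n - 1)
    beta = theta[4 * n:].reshape(-1, n_off)
    out[4 * n:] = beta[:, col_perm].ravel()
    return out


def finite_diff_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    h = rel_step * (1.0 + np.abs(x))
    f0 = fun(x)
    hess = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = h[i]
        fp[i] = fun(x + e)
        fm[i] = fun(x - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return 0.5 * (hess + hess.T)


def _bounds(n_states, covariates):
    n = n_states
    b = []
    b += [(-10.0, 10.0)] * n     # log mu
    b += [(-10.0, 10.0)] * n     # log sigma
    b += [(-25.0, 25.0)] * n     # angle mean
    b += [(-8.0, 12.0)] * n      # log kappa
    b += [(-30.0, 30.0)] * (1 + len(covariates)) * n * (n - 1)
    return b


def fit(
    records,
    n_states: int,
    covariates: tuple[str, ...] = (),
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 1000,
    compute_hessian: bool = True,
) -> HMMFit:
    """Fit an ``n_states`` movement HMM to a prepared step table.

    ``records`` is a step DataFrame (or prepared StepData); ``covariates``
    names the transition covariate columns. The best of ``n_starts``
    jittered initializations is returned (the first start is unjittered,
    seeded from a quantile split of the observed step lengths).
    """
    covariates = tuple(covariates)
    data = records if isinstance(records, StepData) else prepare_step_data(records, covariates)
    pairs = offdiag_pairs(n_states)
    pi = np.array([p[0] for p in pairs], dtype=np.int64)
    pj = np.array([p[1] for p in pairs], dtype=np.int64)
    obj = lambda th: _nll_theta(th, data, n_states, covariates, pi, pj)

    theta0 = _quantile_start(data, n_states, covariates)
    rng = np.random.default_rng(seed)
    bounds = _bounds(n_states, covariates)
    results, diagnostics = [], []
    for s in range(n_starts):
        x0 = theta0 if s == 0 else _jitter(theta0, n_states, covariates, rng)
        try:
            res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": max_iter, "maxfun": 200000, "ftol": tol})
            results.append(res)
            diagnostics.append({"start": s, "loglik": -float(res.fun),
                                "converged": bool(res.success), "message": str(res.message)})
        except Exception as err:  # pragma: no cover - defensive
            diagnostics.append({"start": s, "loglik": -np.inf, "converged": False,
                                "message": repr(err)})
    finite = [r for r in results if np.isfinite(r.fun) and r.fun < 1e11]
    if not finite:
        raise FittingError(f"no start converged to a finite optimum; diagnostics: {diagnostics}")
    best = min(finite, key=lambda r: r.fun)
    theta = _relabel_by_step_mean(best.x, n_states, covariates)
    loglik = -obj(theta)
    spec = unpack_params(theta, n_states, covariates)
    hessian = finite_diff_hessian(obj, theta) if compute_hessian else None
    return HMMFit(
        spec=spec,
        loglik=float(loglik),
        n_params=spec.n_params,
        working=theta,
        hessian=hessian,
        converged=bool(best.success),
        n_starts=n_starts,
        n_obs=data.n_observed,
        start_logliks=diagnostics,
    )


@dataclass
class ModelSelection:
    table: pd.DataFrame
    best_n: int
    fits: dict


def model_select(
    records,
    state_counts=(2, 3, 4),
    covariates: tuple[str, ...] = (),
    n_starts: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> ModelSelection:
    """Fit each candidate number of states and rank by AIC (-2 loglik + 2p)."""
    if not len(state_counts):
        raise ValueError("state_counts must be non-empty")
    covariates = tuple(covariates)
    data = records if isinstance(records, StepData) else prepare_step_data(records, covariates)
    fits, rows = {}, []
    for k, n in enumerate(state_counts):
        try:
            f = fit(data, n, covariates, n_starts=n_starts, seed=seed + 1000 * k, **fit_kwargs)
        except FittingError as err:
            raise FittingError(f"fitting failed for N={n}: {err}") from err
        fits[n] = f
        rows.append({"n_states": n, "loglik": f.loglik, "n_params": f.n_params, "aic": f.aic})
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best_n = int(table.loc[table["aic"].idxmin(), "n_states"])
    return ModelSelection(table=table, best_n=best_n, fits=fits)
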