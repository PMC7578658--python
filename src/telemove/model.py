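"""Model specification for covariate-driven movement HMMs.

A movement HMM has N latent behavioural states. Conditional on the state,
a step length (km per fixed time interval) follows a gamma distribution and
a turning angle (radians) a von Mises distribution. State switches follow a
Markov chain whose transition probability matrix is a multinomial-logit
function of step-start covariates (here: standardized human-footprint index,
a protected-area indicator, and a denning-season indicator).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = theta - TWO_PI * np.ceil((theta - np.pi) / TWO_PI)
    # ceil maps pi exactly to pi; guard values landing on -pi
    wrapped = np.where(wrapped <= -np.pi, wrapped + TWO_PI, wrapped)
    if np.ndim(theta) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class EmissionParams:
    """Per-state natural-scale emission parameters.

    Gamma step-length distributions are parameterized by mean and SD
    (shape = (mean/sd)^2, rate = mean/sd^2); angles by von Mises mean
    direction (radians in (-pi, pi]) and concentration kappa.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    angle_mean: np.ndarray
    angle_conc: np.ndarray

    def __post_init__(self):
        for name in ("step_mean", "step_sd", "angle_mean", "angle_conc"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = self.step_mean.size
        if not all(getattr(self, f).size == n for f in ("step_sd", "angle_mean", "angle_conc")):
            raise ValueError("emission parameter arrays must have one entry per state")
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("gamma step mean and SD must be positive")
        if np.any(self.angle_conc <= 0):
            raise ValueError("von Mises concentration must be positive")
        if np.any(self.angle_mean <= -np.pi) or np.any(self.angle_mean > np.pi):
            raise ValueError("angle means must lie in (-pi, pi]")

    @property
    def n_states(self) -> int:
        return self.step_mean.size

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_rate(self) -> np.ndarray:
        return self.step_mean / self.step_sd**2


def offdiag_pairs(n_states: int) -> list[tuple[int, int]]:
    """Row-major (from, to) ordering of the off-diagonal transition entries."""
    return [(i, j) for i in range(n_states) for j in range(n_states) if j != i]


@dataclass(frozen=True)
class TransitionModel:
    """Multinomial-logit transition model with diagonal reference.

    ``beta`` has shape (1 + c, N(N-1)): an intercept row followed by one row
    per covariate; columns follow :func:`offdiag_pairs` order. For covariate
    row z the off-diagonal linear predictors are eta = (1, z) @ beta, the
    diagonal predictors are 0, and each row of the matrix is the softmax of
    its predictors — so entries lie in (0, 1) and rows sum to one.
    """

    n_states: int
    beta: np.ndarray
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "covariates", tuple(self.covariates))
        n_off = self.n_states * (self.n_states - 1)
        if beta.shape != (1 + len(self.covariates), n_off):
            raise ValueError(
                f"beta must have shape {(1 + len(self.covariates), n_off)}, got {beta.shape}"
            )

    @classmethod
    def intercept_only(cls, n_states: int, diag_prob: float = 0.8) -> "TransitionModel":
        """Covariate-free model whose matrix has the given diagonal probability."""
        if n_states == 1:
            return cls(1, np.zeros((1, 0)))
        off = (1.0 - diag_prob) / (n_states - 1)
        eta = np.log(off / diag_prob)
        return cls(n_states, np.full((1, n_states * (n_states - 1)), eta))


def transition_matrix(transitions: TransitionModel, z=None) -> np.ndarray:
    """Transition probability matrix at a single covariate row ``z``."""
    n = transitions.n_states
    z = np.zeros(0) if z is None else np.asarray(z, dtype=float).ravel()
    if z.size != len(transitions.covariates):
        raise ValueError(f"expected {len(transitions.covariates)} covariate values, got {z.size}")
    if not np.all(np.isfinite(z)):
        raise ValueError("covariates must be finite")
    eta_off = np.concatenate([[1.0], z]) @ transitions.beta
    eta = np.zeros((n, n))
    for k, (i, j) in enumerate(offdiag_pairs(n)):
        eta[i, j] = eta_off[k]
    eta -= eta.max(axis=1, keepdims=True)
    gamma = np.exp(eta)
    return gamma / gamma.sum(axis=1, keepdims=True)


def transition_matrices(transitions: TransitionModel, design: np.ndarray) -> np.ndarray:
    """Vectorized transition matrices for a (T, 1+c) design matrix."""
    n = transitions.n_states
    eta_off = design @ transitions.beta  # (T, N(N-1))
    t = design.shape[0]
    eta = np.zeros((t, n, n))
    for k, (i, j) in enumerate(offdiag_pairs(n)):
        eta[:, i, j] = eta_off[:, k]
    eta -= eta.max(axis=2, keepdims=True)
    gamma = np.exp(eta)
    return gamma / gamma.sum(axis=2, keepdims=True)


def stationary_distribution(gamma: np.ndarray) -> np.ndarray:
    """Solve delta @ gamma = delta, sum(delta) = 1 by a linear system."""
    n = gamma.shape[0]
    a = np.eye(n) - gamma + 1.0
    delta = np.linalg.solve(a.T, np.ones(n))
    return delta / delta.sum()


@dataclass(frozen=True)
class HMMSpec:
    """Complete model: emissions plus covariate-driven transitions.

    The initial state distribution of each track is the stationary
    distribution of the transition matrix at that track's first observed
    covariate row; it contributes no free parameters.
    """

    emissions: EmissionParams
    transitions: TransitionModel

    def __post_init__(self):
        if self.emissions.n_states != self.transitions.n_states:
            raise ValueError("emissions and transitions disagree on the number of states")

    @property
    def n_states(self) -> int:
        return self.emissions.n_states

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.transitions.covariates

    @property
    def n_params(self) -> int:
        n, c = self.n_states, len(self.covariates)
        return 4 * n + (1 + c) * n * (n - 1)


def mean_resultant_length(kappa) -> float:
    """rho = I1(kappa) / I0(kappa), computed with exponentially scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def circular_sd_kappa(value: float, direction: str) -> float:
    """Convert between von Mises concentration and circular standard deviation.

    Circular SD is sqrt(-2 ln rho) with rho the mean resultant length
    I1(kappa)/I0(kappa). ``direction`` is ``"to_sd"`` (kappa -> circular SD)
    or ``"to_kappa"`` (circular SD -> kappa, by bracketed root finding).
    """
    if not np.isfinite(value) or value <= 0:
        raise ValueError("input must be a positive finite number")
    if direction == "to_sd":
        return float(np.sqrt(-2.0 * np.log(mean_resultant_length(value))))
    if direction == "to_kappa":
        target_rho = float(np.exp(-0.5 * value**2))
        f = lambda log_k: mean_resultant_length(np.exp(log_k)) - target_rho
        lo, hi = -25.0, 25.0
        if f(lo) > 0 or f(hi) < 0:
            raise ValueError(f"circular SD {value} outside invertible range")
        return float(np.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)))
    raise ValueError("direction must be 'to_kappa' or 'to_sd'")


# Published three-state movement parameters for African wild dogs in the
# Luangwa Valley (decoded-state summaries): per-state mean speed and speed SD
# in km/h, angle mean in radians, and angle dispersion as circular SD.
WILD_DOG_SPEED_MEAN_KMH = (0.17, 1.10, 1.82)
WILD_DOG_SPEED_SD_KMH = (0.05, 0.79, 1.79)
WILD_DOG_ANGLE_MEAN_RAD = (-0.036, 0.057, 0.024)
WILD_DOG_ANGLE_CIRC_SD = (2.16, 1.59, 1.65)
STEP_MINUTES_DEFAULT = 80.0


def wild_dog_emissions(step_minutes: float = STEP_MINUTES_DEFAULT) -> EmissionParams:
    """Reference three-state emissions from published wild-dog speed summaries.

    Speeds (km/h) are converted to step lengths by multiplying by the step
    duration in hours (80 min -> 4/3 h); angle concentrations come from
    inverting the published circular SDs.
    """
    hours = step_minutes / 60.0
    kappa = [circular_sd_kappa(s, "to_kappa") for s in WILD_DOG_ANGLE_CIRC_SD]
    return EmissionParams(
        step_mean=np.array(WILD_DOG_SPEED_MEAN_KMH) * hours,
        step_sd=np.array(WILD_DOG_SPEED_SD_KMH) * hours,
        angle_mean=np.array(WILD_DOG_ANGLE_MEAN_RAD),
        angle_conc=np.array(kappa),
    )


def default_covariate_beta(n_states: int = 3, diag_prob: float = 0.8) -> np.ndarray:
    """Default generator coefficients for ('hfi_std', 'in_park', 'denning').

    Intercepts give a diagonal probability of ``diag_prob`` at covariate zero.
    Signs emulate the field pattern: a stronger human footprint suppresses
    switches into the fast state, being outside the park and denning promote
    them.
    """
    base = TransitionModel.intercept_only(n_states, diag_prob).beta[0]
    pairs = offdiag_pairs(n_states)
    fast = n_states - 1
    hfi = np.array([-0.6 if j == fast else (0.3 if j == 0 else 0.0) for _, j in pairs])
    park = np.array([0.4 if j == fast else 0.0 for _, j in pairs])  # sign applies to *out-of-park*
    denning = np.array([0.5 if j == fast else (-0.3 if j == 1 else 0.0) for _, j in pairs])
    return np.vstack([base, hfi, -park, denning])


def wild_dog_spec(
    covariates: tuple[str, ...] = ("hfi_std", "in_park", "denning"),
    step_minutes: float = STEP_MINUTES_DEFAULT,
) -> HMMSpec:
    """Reference 3-state generating model used throughout the synthetic suite."""
    emissions = wild_dog_emissions(step_minutes)
    beta_full = default_covariate_beta(3)
    rows = {"hfi_std": 1, "in_park": 2, "denning": 3}
    idx = [0] + [rows[c] for c in covariates]
    return HMMSpec(emissions, TransitionModel(3, beta_full[idx], covariates))
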