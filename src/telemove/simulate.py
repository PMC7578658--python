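"""Simulate multi-state movement tracks over a synthetic landscape.

Tracks follow the same generative model the HMM assumes: at each step the
covariates are read at the current position (the start of the step), the next
state is drawn from the covariate-dependent transition row, then a step
length from that state's gamma and a turning angle from its von Mises.
Heading accumulates turning angles and steps leaving the grid are reflected
at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid
from .model import HMMSpec, stationary_distribution, transition_matrix, wrap_angle

DENNING_WINDOW_DEFAULT = (160, 220)  # Julian days, inclusive


@dataclass(frozen=True)
class TrueTrack:
    """Ground-truth simulated track.

    Arrays all have length n_steps + 1: ``positions[0]`` is the start point
    and ``true_states[0]`` duplicates the state of the first step so lengths
    match. ``bearings[t]`` is the heading after step t (``bearings[0]`` the
    initial heading).
    """

    individual_id: str
    times: pd.DatetimeIndex
    positions: np.ndarray  # (n+1, 2) km
    true_states: np.ndarray  # 1-based state labels
    bearings: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        if not (self.positions.shape[0] == self.true_states.size == self.bearings.size == n):
            raise ValueError("times, positions, true_states and bearings must have equal length")

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1


def denning_indicator(times, window=DENNING_WINDOW_DEFAULT):
    """1 where the timestamp's Julian day lies in [window[0], window[1]]."""
    doy = np.asarray(pd.DatetimeIndex(times).dayofyear)
    return ((doy >= window[0]) & (doy <= window[1])).astype(int)


def _reflect(value: float, lo: float, hi: float) -> float:
    period = 2.0 * (hi - lo)
    v = (value - lo) % period
    return lo + (v if v <= hi - lo else period - v)


def _covariate_row(names, landscape, hfi_mu, hfi_sd, x, y, denning):
    row = np.empty(len(names))
    for k, name in enumerate(names):
        if name == "hfi_std":
            row[k] = (landscape.footprint_at(x, y) - hfi_mu) / hfi_sd
        elif name == "in_park":
            row[k] = float(landscape.park_at(x, y))
        elif name == "denning":
            row[k] = float(denning)
        else:
            raise ValueError(
                f"unknown covariate {name!r}: the landscape provides 'hfi_std', 'in_park', 'denning'"
            )
    return row


def simulate_tracks(
    spec: HMMSpec,
    landscape: LandscapeGrid,
    n_tracks: int,
    n_steps: int,
    step_minutes: float = 80.0,
    denning_window: tuple[int, int] = DENNING_WINDOW_DEFAULT,
    seed: int = 0,
    start_time: str = "2017-01-01T06:00:00",
    stagger_start_days: bool = True,
) -> list[TrueTrack]:
    """Simulate ``n_tracks`` independent tracks from the generating model.

    Start positions are uniform over the inner 80% of the landscape; start
    dates are staggered uniformly over a year (so the denning indicator
    varies between tracks) unless ``stagger_start_days`` is False. The
    footprint covariate is standardized with the landscape's population mean
    and SD, which defines the scale of the model's 'hfi_std' coefficients.
    """
    rng = np.random.default_rng(seed)
    em = spec.emissions
    shape, rate = em.gamma_shape, em.gamma_rate
    hfi_mu, hfi_sd = landscape.standardization()
    xmin, xmax, ymin, ymax = landscape.extent
    inset_x, inset_y = 0.1 * (xmax - xmin), 0.1 * (ymax - ymin)
    base = pd.Timestamp(start_time)
    names = spec.covariates

    tracks = []
    for i in range(n_tracks):
        offset_days = int(rng.integers(0, 365)) if stagger_start_days else 0
        times = base + pd.Timedelta(days=offset_days) + pd.to_timedelta(
            np.arange(n_steps + 1) * step_minutes, unit="m"
        )
        denning = denning_indicator(times, denning_window)

        pos = np.empty((n_steps + 1, 2))
        states = np.empty(n_steps + 1, dtype=int)
        bearings = np.empty(n_steps + 1)
        pos[0, 0] = rng.uniform(xmin + inset_x, xmax - inset_x)
        pos[0, 1] = rng.uniform(ymin + inset_y, ymax - inset_y)
        heading = rng.uniform(-np.pi, np.pi)
        bearings[0] = heading

        state = -1
        for t in range(1, n_steps + 1):
            z = _covariate_row(names, landscape, hfi_mu, hfi_sd, pos[t - 1, 0], pos[t - 1, 1],
                               denning[t - 1])
            gamma_row = transition_matrix(spec.transitions, z)
            if state < 0:
                probs = stationary_distribution(gamma_row)
            else:
                probs = gamma_row[state]
            state = int(rng.choice(spec.n_states, p=probs))
            length = rng.gamma(shape[state], 1.0 / rate[state])
            turn = rng.vonmises(em.angle_mean[state], em.angle_conc[state])
            heading = wrap_angle(heading + turn)
            x = pos[t - 1, 0] + length * np.cos(heading)
            y = pos[t - 1, 1] + length * np.sin(heading)
            xr, yr = _reflect(x, xmin, xmax), _reflect(y, ymin, ymax)
            pos[t] = (xr, yr)
            if (xr, yr) != (x, y):  # realign heading with the realized displacement
                dx, dy = pos[t] - pos[t - 1]
                if dx != 0.0 or dy != 0.0:
                    heading = np.arctan2(dy, dx)
            states[t] = state + 1
            bearings[t] = heading
        states[0] = states[1]
        tracks.append(TrueTrack(f"ind{i + 1:02d}", pd.DatetimeIndex(times), pos, states, bearings))
    return tracks


def tracks_to_fixes(tracks: list[TrueTrack], include_true_state: bool = True) -> pd.DataFrame:
    """Flatten tracks into a raw fix table (id, timestamp, x_km, y_km[, true_state])."""
    frames = []
    for tr in tracks:
        df = pd.DataFrame(
            {
                "id": tr.individual_id,
                "timestamp": tr.times,
                "x_km": tr.positions[:, 0],
                "y_km": tr.positions[:, 1],
            }
        )
        if include_true_state:
            df["true_state"] = tr.true_states
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def synthetic_step_table(
    spec: HMMSpec,
    landscape: LandscapeGrid,
    n_tracks: int,
    n_steps: int,
    seed: int = 0,
    step_minutes: float = 80.0,
    denning_window: tuple[int, int] = DENNING_WINDOW_DEFAULT,
    min_step_km: float | None = None,
) -> pd.DataFrame:
    """Simulate tracks and return a fit-ready step table.

    Covariates are attached exactly on the generator's scale (the footprint
    standardized by the landscape's population mean/SD), so recovery and
    coverage experiments compare estimates against the generating
    coefficients without a sample-dependent rescaling. ``min_step_km``
    applies the resting filter when given; recovery experiments leave it off.
    """
    from .prep import extract_covariates, filter_min_step, steps_and_angles

    tracks = simulate_tracks(spec, landscape, n_tracks, n_steps, step_minutes,
                             denning_window, seed)
    records = steps_and_angles(tracks_to_fixes(tracks, include_true_state=False))
    if min_step_km is not None:
        records = filter_min_step(records, min_step_km)
    records = extract_covariates(records, landscape, denning_window)
    mu, sd = landscape.standardization()
    records["hfi_std"] = (records["hfi_raw"] - mu) / sd
    return records


def inject_resting(
    tracks: list[TrueTrack],
    rest_prob: float,
    seed: int = 0,
    max_rest_km: float = 0.15,
) -> pd.DataFrame:
    """Convert tracks to a fix table with a random subset of steps made 'resting'.

    Each selected step's end position is replaced by a displacement shorter
    than the 0.2-km analysis threshold from the step's start, emulating fixes
    taken at a resting site; the minimum-step filter downstream turns these
    into missing values.
    """
    if not 0.0 <= rest_prob < 1.0:
        raise ValueError("rest_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    fixes = tracks_to_fixes(tracks)
    out = []
    for _, df in fixes.groupby("id", sort=False):
        df = df.copy()
        x = df["x_km"].to_numpy().copy()
        y = df["y_km"].to_numpy().copy()
        if rest_prob > 0:
            resting = rng.random(len(df) - 1) < rest_prob
            for t in np.flatnonzero(resting) + 1:
                r = rng.uniform(0.0, max_rest_km)
                phi = rng.uniform(-np.pi, np.pi)
                x[t] = x[t - 1] + r * np.cos(phi)
                y[t] = y[t - 1] + r * np.sin(phi)
        df["x_km"], df["y_km"] = x, y
        out.append(df)
    return pd.concat(out, ignore_index=True)
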