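"""Turn raw GPS fix tables into the regularized step series the HMM consumes.

The pipeline is: snap fixes to a fixed time grid (no interpolation), compute
step lengths and signed turning angles, set sub-threshold steps missing,
attach landscape covariates read at each step's start position, and
standardize the footprint covariate.

Step tables are plain pandas DataFrames with one row per step and columns
``id, t, x_km, y_km, step_km, angle_rad`` plus, after covariate extraction,
``hfi_raw, hfi_std, in_park, denning``. ``x_km, y_km`` are the step-start
position; missing values are NaN throughout.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid
from .model import wrap_angle
from .simulate import DENNING_WINDOW_DEFAULT, denning_indicator

MIN_STEP_KM_DEFAULT = 0.2

STEP_COLUMNS = ["id", "t", "x_km", "y_km", "step_km", "angle_rad"]


@dataclass(frozen=True)
class StandardizationStats:
    """Mean and (population) SD of the raw footprint covariate over analyzed steps."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("standardization SD must be positive")

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean, "sd": self.sd}, fh)

    @classmethod
    def from_json(cls, path) -> "StandardizationStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["mean"], d["sd"])


def regularize(fixes: pd.DataFrame, step_minutes: float, tolerance_minutes: float = 5.0) -> pd.DataFrame:
    """Snap each individual's fixes to a fixed time grid anchored at its first fix.

    Grid slots with no fix within ``tolerance_minutes`` become missing
    positions (NaN); when several fixes fall near one slot the nearest wins.
    No interpolation is performed.
    """
    if step_minutes <= 0:
        raise ValueError("step_minutes must be positive")
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    out = []
    for ind, df in fixes.groupby("id", sort=False):
        if df["timestamp"].duplicated().any():
            raise ValueError(f"duplicate timestamps for individual {ind!r}")
        df = df.sort_values("timestamp")
        t0 = df["timestamp"].iloc[0]
        rel = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 60.0
        slot = np.rint(rel / step_minutes).astype(int)
        resid = np.abs(rel - slot * step_minutes)
        ok = resid <= tolerance_minutes
        n_slots = int(slot[ok].max()) + 1 if ok.any() else 1
        x = np.full(n_slots, np.nan)
        y = np.full(n_slots, np.nan)
        best = np.full(n_slots, np.inf)
        cols = {c: np.full(n_slots, np.nan) for c in df.columns
                if c not in ("id", "timestamp", "x_km", "y_km")}
        for k in np.flatnonzero(ok):
            s = slot[k]
            if resid[k] < best[s]:
                best[s] = resid[k]
                x[s] = df["x_km"].iloc[k]
                y[s] = df["y_km"].iloc[k]
                for c in cols:
                    cols[c][s] = df[c].iloc[k]
        grid_times = t0 + pd.to_timedelta(np.arange(n_slots) * step_minutes, unit="m")
        out.append(pd.DataFrame({"id": ind, "timestamp": grid_times, "x_km": x, "y_km": y, **cols}))
    return pd.concat(out, ignore_index=True)


def steps_and_angles(fixes: pd.DataFrame) -> pd.DataFrame:
    """Compute step lengths and signed turning angles from regularized fixes.

    One row per consecutive pair of grid slots: ``step_km`` is the Euclidean
    distance, ``angle_rad`` the change in heading between the two adjacent
    displacement vectors (counterclockwise positive, wrapped to (-pi, pi]).
    The first step of each individual — and any step adjacent to a missing or
    zero-length displacement — has a missing angle.
    """
    out = []
    for ind, df in fixes.groupby("id", sort=False):
        x = df["x_km"].to_numpy(dtype=float)
        y = df["y_km"].to_numpy(dtype=float)
        dx, dy = np.diff(x), np.diff(y)
        step = np.hypot(dx, dy)
        heading = np.arctan2(dy, dx)
        heading[step == 0] = np.nan  # heading undefined for zero displacement
        angle = np.full(step.size, np.nan)
        if step.size > 1:
            angle[1:] = wrap_angle(heading[1:] - heading[:-1])
            angle[1:][~np.isfinite(heading[1:]) | ~np.isfinite(heading[:-1])] = np.nan
        out.append(
            pd.DataFrame(
                {
                    "id": ind,
                    "t": df["timestamp"].to_numpy()[:-1],
                    "x_km": x[:-1],
                    "y_km": y[:-1],
                    "step_km": step,
                    "angle_rad": angle,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def filter_min_step(records: pd.DataFrame, min_km: float = MIN_STEP_KM_DEFAULT) -> pd.DataFrame:
    """Set steps shorter than ``min_km`` (and adjacent angles) missing.

    Sub-threshold steps correspond to fixes taken while the animal rested;
    they are treated as missing values, not deleted, so the time series keeps
    its regular spacing. The angle of the following step is also set missing
    because the heading through a removed displacement is undefined.
    """
    if min_km < 0:
        raise ValueError("min_km must be non-negative")
    out = []
    for _, df in records.groupby("id", sort=False):
        df = df.copy()
        step = df["step_km"].to_numpy(dtype=float)
        angle = df["angle_rad"].to_numpy(dtype=float)
        short = np.isfinite(step) & (step < min_km)
        step[short] = np.nan
        angle[short] = np.nan
        angle[1:][short[:-1]] = np.nan
        df["step_km"], df["angle_rad"] = step, angle
        out.append(df)
    return pd.concat(out, ignore_index=True)


def extract_covariates(
    records: pd.DataFrame,
    landscape: LandscapeGrid,
    denning_window: tuple[int, int] = DENNING_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """Attach hfi_raw, in_park and denning covariates at each step's start.

    The footprint value comes from the raster cell containing the step-start
    position; rows with a missing start position get missing hfi_raw/in_park
    (they are forward-filled per individual before model fitting).
    """
    records = records.copy()
    x = records["x_km"].to_numpy(dtype=float)
    y = records["y_km"].to_numpy(dtype=float)
    hfi = np.full(x.size, np.nan)
    park = np.full(x.size, np.nan)
    have = np.isfinite(x) & np.isfinite(y)
    if have.any():
        try:
            row, col = landscape.cell_index(x[have], y[have])
        except ValueError as err:
            raise ValueError(f"step-start positions outside the landscape: {err}") from err
        hfi[have] = landscape.footprint[row, col]
        park[have] = landscape.park_mask[row, col].astype(float)
    records["hfi_raw"] = hfi
    records["in_park"] = park
    records["denning"] = denning_indicator(records["t"], denning_window)
    return records


def standardize(records: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationStats]:
    """Z-score the raw footprint covariate over all analyzed records.

    Uses the population SD (divide by n). The returned stats let prediction
    grids be expressed on the same standardized scale.
    """
    records = records.copy()
    raw = records["hfi_raw"].to_numpy(dtype=float)
    obs = raw[np.isfinite(raw)]
    if obs.size < 2 or np.unique(obs).size < 2:
        raise ValueError("need at least two distinct footprint values to standardize")
    stats = StandardizationStats(float(obs.mean()), float(obs.std()))
    records["hfi_std"] = stats.apply(raw)
    return records, stats


def prepare_steps(
    fixes: pd.DataFrame,
    landscape: LandscapeGrid,
    step_minutes: float = 80.0,
    tolerance_minutes: float = 5.0,
    min_step_km: float = MIN_STEP_KM_DEFAULT,
    denning_window: tuple[int, int] = DENNING_WINDOW_DEFAULT,
) -> tuple[pd.DataFrame, StandardizationStats]:
    """Full preparation pipeline: regularize -> steps/angles -> filter -> covariates -> standardize."""
    fixes = regularize(fixes, step_minutes, tolerance_minutes)
    records = steps_and_angles(fixes)
    records = filter_min_step(records, min_step_km)
    records = extract_covariates(records, landscape, denning_window)
    return standardize(records)


def pressure_score(density):
    """Human population pressure score: 3.333 * log10(density + 1).

    ``density`` is people per square km; values above 1000 are capped there,
    so the score saturates near 10 — the convention used when population
    counts are folded into the human footprint index.
    """
    arr = np.asarray(density, dtype=float)
    if np.any(arr < 0):
        raise ValueError("density must be non-negative")
    score = 3.333 * np.log10(np.minimum(arr, 1000.0) + 1.0)
    return float(score) if np.ndim(density) == 0 else score
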