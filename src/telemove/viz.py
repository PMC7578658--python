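"""Figure helpers: state-wise emission distributions, stationary-probability
curves with CI ribbons, decoded maps, residual QQ plots and connectivity panels.

All functions take an optional matplotlib Axes and return the Axes/Figure so
they compose; files are written with the Agg backend.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm, vonmises

STATE_COLORS = ["#d95f02", "#7570b3", "#1b9e77", "#e7298a"]


def plot_state_distributions(fit, records, fig=None):
    """Histograms of observed steps and angles with fitted per-state densities."""
    em = fit.spec.emissions
    n = em.n_states
    if fig is None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    else:
        axes = fig.subplots(1, 2)
    steps = records["step_km"].dropna().to_numpy()
    angles = records["angle_rad"].dropna().to_numpy()

    ax = axes[0]
    ax.hist(steps, bins=40, density=True, color="0.85", edgecolor="0.6")
    x = np.linspace(1e-3, steps.max(), 300)
    for k in range(n):
        pdf = gamma_dist.pdf(x, a=em.gamma_shape[k], scale=em.step_sd[k] ** 2 / em.step_mean[k])
        ax.plot(x, pdf / n, color=STATE_COLORS[k % len(STATE_COLORS)], label=f"state {k + 1}")
    ax.set_xlabel("step length (km)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)

    ax = axes[1]
    ax.hist(angles, bins=36, density=True, color="0.85", edgecolor="0.6")
    th = np.linspace(-np.pi, np.pi, 361)
    for k in range(n):
        ax.plot(th, vonmises.pdf(th, em.angle_conc[k], loc=em.angle_mean[k]) / n,
                color=STATE_COLORS[k % len(STATE_COLORS)])
    ax.set_xlabel("turning angle (rad)")
    fig.tight_layout()
    return fig


def plot_stationary_curve(curve, vary: str, fig=None):
    """Stationary state probabilities vs one covariate, with CI ribbons."""
    if fig is None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
    else:
        ax = fig.subplots()
    table = curve.table
    x = table[vary].to_numpy()
    n = sum(c.startswith("delta") for c in table.columns)
    for k in range(1, n + 1):
        color = STATE_COLORS[(k - 1) % len(STATE_COLORS)]
        ax.plot(x, table[f"delta{k}"], color=color, label=f"state {k}")
        ax.fill_between(x, table[f"lo{k}"], table[f"hi{k}"], color=color, alpha=0.2, lw=0)
    ax.set_xlabel(vary)
    ax.set_ylabel("stationary probability")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_decoded_map(records, states, fig=None):
    """Step-start locations colored by decoded state."""
    if fig is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        ax = fig.subplots()
    states = np.asarray(states)
    for k in np.unique(states):
        sel = states == k
        ax.scatter(records["x_km"].to_numpy()[sel], records["y_km"].to_numpy()[sel],
                   s=4, color=STATE_COLORS[(k - 1) % len(STATE_COLORS)], label=f"state {k}")
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_aspect("equal")
    ax.legend(frameon=False, markerscale=3)
    fig.tight_layout()
    return fig


def plot_qq(residuals, fig=None):
    """QQ plot of step and angle pseudo-residuals against the standard normal."""
    if fig is None:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    else:
        axes = fig.subplots(1, 2)
    for ax, col in zip(axes, ["step_resid", "angle_resid"]):
        r = np.sort(residuals[col].dropna().to_numpy())
        q = norm.ppf((np.arange(r.size) + 0.5) / r.size)
        ax.plot(q, r, ".", ms=2, color="0.3")
        lim = max(3.5, np.abs(r).max() if r.size else 3.5)
        ax.plot([-lim, lim], [-lim, lim], color="crimson", lw=1)
        ax.set_xlabel("normal quantile")
        ax.set_ylabel(col.replace("_", " "))
    fig.tight_layout()
    return fig


def plot_connectivity(trajectories_by_pattern: dict, ring_radius: float, fig=None):
    """Trajectories from a common origin with the connection ring."""
    if fig is None:
        fig, axes = plt.subplots(1, len(trajectories_by_pattern), figsize=(9, 4.5))
    else:
        axes = fig.subplots(1, len(trajectories_by_pattern))
    axes = np.atleast_1d(axes)
    for ax, (name, traj) in zip(axes, trajectories_by_pattern.items()):
        for i in range(min(traj.shape[0], 60)):
            ax.plot(traj[i, :, 0], traj[i, :, 1], lw=0.5, alpha=0.6)
        circle = plt.Circle((0, 0), ring_radius, fill=False, color="0.4", ls="--")
        ax.add_patch(circle)
        ax.plot(0, 0, "r+", ms=10)
        ax.set_title(f"pattern {name}")
        ax.set_aspect("equal")
    fig.tight_layout()
    return fig
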