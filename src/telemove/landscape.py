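"""Synthetic landscapes: a human-footprint-like raster plus a park mask.

The generator emulates the statistical features of a 1-km human-footprint
raster over a protected-area / buffer-zone mosaic: a smooth spatially
autocorrelated field rescaled to a configured value range (default 2-16),
with the protected area occupying the low-footprint side of the grid.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class LandscapeGrid:
    """Footprint raster and park mask on a planar-km grid.

    ``footprint[r, c]`` is the value of the cell whose lower-left corner is at
    (origin_x + c * cell_size, origin_y + r * cell_size); row index increases
    with y.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    footprint: np.ndarray
    park_mask: np.ndarray

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.footprint.shape != self.park_mask.shape:
            raise ValueError("footprint and park_mask must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.footprint.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in km."""
        ny, nx = self.footprint.shape
        return (
            self.origin_x,
            self.origin_x + nx * self.cell_size,
            self.origin_y,
            self.origin_y + ny * self.cell_size,
        )

    def cell_index(self, x, y):
        """Row/column of the cell whose center is nearest each point.

        Points must lie inside the grid extent; points exactly on the upper
        edges are assigned to the last cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, xmax, ymin, ymax = self.extent
        bad = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax) | ~np.isfinite(x) | ~np.isfinite(y)
        if np.any(bad):
            where = np.flatnonzero(np.atleast_1d(bad))
            raise ValueError(f"positions outside landscape extent at indices {where.tolist()}")
        ny, nx = self.footprint.shape
        col = np.clip(((x - xmin) / self.cell_size).astype(int), 0, nx - 1)
        row = np.clip(((y - ymin) / self.cell_size).astype(int), 0, ny - 1)
        return row, col

    def footprint_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.footprint[row, col]

    def park_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.park_mask[row, col]

    def standardization(self) -> tuple[float, float]:
        """Population mean and SD of the footprint field over all cells."""
        return float(self.footprint.mean()), float(self.footprint.std())


def make_landscape(
    seed: int,
    n_cells_x: int = 100,
    n_cells_y: int = 100,
    value_range: tuple[float, float] = (2.0, 16.0),
    park_fraction: float = 0.5,
    cell_size: float = 1.0,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    n_bumps: int = 25,
    bump_sd_cells: float = 12.0,
) -> LandscapeGrid:
    """Generate a seeded, spatially autocorrelated footprint landscape.

    The field is a west-east base gradient plus ``n_bumps`` random Gaussian
    bumps of width ``bump_sd_cells`` (the roughness knob), rescaled affinely
    to ``value_range``. The park mask marks the ``park_fraction`` of cells
    with the lowest footprint, which the gradient keeps spatially coherent on
    the low-footprint side.
    """
    lo, hi = value_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError("value_range must satisfy min < max")
    if not 0.0 < park_fraction < 1.0:
        raise ValueError("park_fraction must lie in (0, 1)")
    if n_cells_x < 2 or n_cells_y < 2:
        raise ValueError("grid must have at least 2 cells per dimension")

    rng = np.random.default_rng(seed)
    cols = np.arange(n_cells_x)
    rows = np.arange(n_cells_y)
    cc, rr = np.meshgrid(cols, rows)
    field = cc / (n_cells_x - 1.0)  # base gradient: footprint rises eastward

    cx = rng.uniform(0, n_cells_x, n_bumps)
    cy = rng.uniform(0, n_cells_y, n_bumps)
    amp = rng.uniform(-1.0, 1.0, n_bumps)
    for k in range(n_bumps):
        d2 = (cc - cx[k]) ** 2 + (rr - cy[k]) ** 2
        field = field + 0.35 * amp[k] * np.exp(-0.5 * d2 / bump_sd_cells**2)

    fmin, fmax = field.min(), field.max()
    footprint = lo + (field - fmin) * (hi - lo) / (fmax - fmin)

    n_park = int(round(park_fraction * footprint.size))
    order = np.argsort(footprint, axis=None, kind="stable")
    mask = np.zeros(footprint.size, dtype=bool)
    mask[order[:n_park]] = True
    park_mask = mask.reshape(footprint.shape)

    return LandscapeGrid(origin_x, origin_y, cell_size, footprint, park_mask)


def _write_asc(path: Path, grid: np.ndarray, origin_x, origin_y, cell_size, fmt="%.6f"):
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {origin_x}\nyllcorner {origin_y}\n"
        f"cellsize {cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid[::-1], fmt=fmt)  # ESRI ASCII stores the top row first


def _read_asc(path: Path) -> tuple[np.ndarray, float, float, float]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    return grid[::-1].copy(), hdr["xllcorner"], hdr["yllcorner"], hdr["cellsize"]


def save_landscape(landscape: LandscapeGrid, directory, value_range=None, seed=None) -> None:
    """Write footprint.asc, park_mask.asc and a JSON sidecar into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_asc(directory / "footprint.asc", landscape.footprint, landscape.origin_x,
               landscape.origin_y, landscape.cell_size)
    _write_asc(directory / "park_mask.asc", landscape.park_mask.astype(int),
               landscape.origin_x, landscape.origin_y, landscape.cell_size, fmt="%d")
    sidecar = {
        "value_range": list(value_range) if value_range is not None else None,
        "seed": seed,
        "cell_size": landscape.cell_size,
    }
    (directory / "landscape.json").write_text(json.dumps(sidecar, indent=2))


def load_landscape(directory) -> LandscapeGrid:
    directory = Path(directory)
    footprint, x0, y0, cs = _read_asc(directory / "footprint.asc")
    mask, *_ = _read_asc(directory / "park_mask.asc")
    return LandscapeGrid(x0, y0, cs, footprint, mask.astype(bool))
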