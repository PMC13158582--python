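"""Shared fixtures: small grids, synthetic fix factories, raster builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proxrange.io_grid import DetectionGrid, Station
from proxrange.localization import Fix
from proxrange.ud_estimation import UDRaster


@pytest.fixture
def grid3x3() -> DetectionGrid:
    stations = [
        Station(f"S{r}{c}", c * 65.0, r * 65.0) for r in range(3) for c in range(3)
    ]
    return DetectionGrid(stations)


def make_gaussian_fixes(
    n: int,
    sigma: float = 50.0,
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
    two_nights: bool = True,
    dt_s: float = 2.0,
) -> list[Fix]:
    """IID Gaussian fixes on a 2-s cadence, split over one or two nights."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(0.0, sigma, (n, 2)) + np.asarray(center)
    base = pd.Timestamp("2024-08-12 22:00:00")
    fixes = []
    for i in range(n):
        day_off = 86400 if (two_nights and i >= n // 2) else 0
        ts = base + pd.Timedelta(seconds=dt_s * i + day_off)
        fixes.append(Fix("bat", ts, float(pts[i, 0]), float(pts[i, 1]), "inner"))
    return fixes


def uniform_raster(
    n_cells_x: int = 10,
    n_cells_y: int = 10,
    cell: float = 5.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> UDRaster:
    """Uniform UD over an n×n block of cells."""
    dens = np.full((n_cells_y, n_cells_x), 1.0 / (n_cells_x * n_cells_y * cell**2))
    return UDRaster(origin[0], origin[1], cell, dens)


def gaussian_raster(
    sigma: float,
    center: tuple[float, float],
    origin: tuple[float, float],
    shape: tuple[int, int],
    cell: float = 5.0,
) -> UDRaster:
    """Discretized isotropic Gaussian UD, renormalized on the grid."""
    ny, nx = shape
    xc = origin[0] + (np.arange(nx) + 0.5) * cell
    yc = origin[1] + (np.arange(ny) + 0.5) * cell
    xx, yy = np.meshgrid(xc, yc)
    dens = np.exp(-((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2))
    dens /= dens.sum() * cell**2
    return UDRaster(origin[0], origin[1], cell, dens)
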