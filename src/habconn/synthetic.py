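"""Neutral-landscape and response-curve simulators.

Every downstream stage of the pipeline (habitat masking, hexagonal landscape
sampling, patch graphs, connectivity indices, breakpoint regression) is
exercised against rasters produced here, so the generators are first-class,
deterministic code: each takes an explicit seed and identical inputs yield
bit-identical outputs.

Habitat rasters use the simplest neutral landscape model with a single
autocorrelation knob: Gaussian smoothing of white noise followed by
rank thresholding, which fixes the realized habitat proportion exactly
(to the nearest whole cell) instead of only in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GridRaster

__all__ = [
    "SimulationSpec",
    "CurveSpec",
    "gen_habitat_raster",
    "gen_landcover",
    "gen_suitability",
    "gen_breakpoint_curve",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Geometry and stochastic parameters of one simulated landscape.

    ``clustering`` is the Gaussian smoothing radius in cells; 0 gives
    spatially independent (salt-and-pepper) habitat, larger values give
    progressively more aggregated patches.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 4.5
    habitat_proportion: float = 0.3
    clustering: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not np.isfinite(self.cell_size_km) or self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive and finite")
        if not np.isfinite(self.habitat_proportion) or not 0 <= self.habitat_proportion <= 1:
            raise ValueError("habitat_proportion must lie in [0, 1]")
        if not np.isfinite(self.clustering) or self.clustering < 0:
            raise ValueError("clustering radius must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class CurveSpec:
    """Piecewise-linear response curve with one breakpoint plus Gaussian noise.

    The noiseless curve is
    ``y = intercept + slope_left*x + (slope_right - slope_left)*max(0, x - psi)``,
    i.e. two line segments joined continuously at ``breakpoint_psi``.
    """

    breakpoint_psi: float
    intercept: float
    slope_left: float
    slope_right: float
    noise_sd: float
    x_values: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x_values, dtype=float)
        object.__setattr__(self, "x_values", tuple(x))
        if x.size == 0:
            raise ValueError("x_values must be non-empty")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x_values must be strictly increasing")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _smoothed_noise(spec: SimulationSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_rows, spec.n_cols))
    if spec.clustering > 0:
        noise = ndimage.gaussian_filter(noise, sigma=spec.clustering, mode="wrap")
    return noise


def gen_habitat_raster(spec: SimulationSpec) -> GridRaster:
    """Binary habitat raster with exact habitat proportion.

    The ``round(p * n_cells)`` highest cells of a (possibly smoothed) noise
    field become habitat, so the realized fraction differs from the request
    by less than one cell count.  Ties in the noise field are broken by
    row-major position, keeping the output deterministic.
    """
    k = int(round(spec.habitat_proportion * spec.n_cells))
    grid = np.zeros((spec.n_rows, spec.n_cols), dtype=int)
    if k > 0:
        noise = _smoothed_noise(spec)
        flat = noise.ravel()
        order = np.lexsort((np.arange(flat.size), -flat))
        grid.ravel()[order[:k]] = 1
    return GridRaster(grid, spec.cell_size_km, kind="binary")


def gen_landcover(spec: SimulationSpec, class_fractions: dict[object, float]) -> GridRaster:
    """Categorical land-cover grid with exact per-class cell counts.

    ``class_fractions`` maps class code (any hashable; integers in practice)
    to its areal fraction; fractions must sum to 1.  Cells are assigned by
    ranking the same smoothed-noise field used for habitat, so clustering
    produces spatially coherent class mosaics.  Rounding residues are
    resolved by largest remainder, ties by insertion order of the mapping.
    """
    classes = list(class_fractions.keys())
    fracs = np.array([class_fractions[c] for c in classes], dtype=float)
    if np.any(~np.isfinite(fracs)) or np.any(fracs < 0):
        raise ValueError("class fractions must be finite and non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {fracs.sum()}, expected 1")

    n = spec.n_cells
    exact = fracs * n
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1

    noise = _smoothed_noise(spec)
    flat = noise.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    grid = np.empty(n, dtype=int)
    start = 0
    for cls, cnt in zip(classes, counts):
        grid[order[start : start + cnt]] = int(cls)
        start += cnt
    return GridRaster(grid.reshape(spec.n_rows, spec.n_cols), spec.cell_size_km, kind="categorical")


def gen_suitability(spec: SimulationSpec, n_centers: int, amplitude: float = 1.0) -> GridRaster:
    """Continuous suitability surface in [0, 1] from Gaussian kernels.

    ``n_centers`` kernels are placed uniformly at random; the surface is the
    maximum over kernels of ``amplitude * a_k * exp(-d² / (2 σ²))`` with
    per-kernel heights ``a_k`` drawn in (0.5, 1] and bandwidth σ set to one
    eighth of the grid diagonal.  Each kernel center is a local maximum; with
    one kernel the maximum cell is globally unique.
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    if not np.isfinite(amplitude) or amplitude < 0 or amplitude > 1:
        raise ValueError("amplitude must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.indices((spec.n_rows, spec.n_cols), dtype=float)
    sigma = max(np.hypot(spec.n_rows, spec.n_cols) / 8.0, 1.0)
    surface = np.zeros((spec.n_rows, spec.n_cols))
    for _ in range(n_centers):
        cr = rng.uniform(0, spec.n_rows)
        cc = rng.uniform(0, spec.n_cols)
        height = rng.uniform(0.5, 1.0)
        kernel = amplitude * height * np.exp(
            -((rows + 0.5 - cr) ** 2 + (cols + 0.5 - cc) ** 2) / (2 * sigma**2)
        )
        np.maximum(surface, kernel, out=surface)
    return GridRaster(np.clip(surface, 0.0, 1.0), spec.cell_size_km, kind="continuous")


def gen_breakpoint_curve(cs: CurveSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample (x, y) from the one-breakpoint piecewise-linear model.

    Returns ``y_i = intercept + slope_left*x_i +
    (slope_right - slope_left)*max(0, x_i - psi) + eps_i`` with
    ``eps_i ~ N(0, noise_sd²)``.
    """
    x = np.asarray(cs.x_values, dtype=float)
    y = (
        cs.intercept
        + cs.slope_left * x
        + (cs.slope_right - cs.slope_left) * np.maximum(0.0, x - cs.breakpoint_psi)
    )
    if cs.noise_sd > 0:
        rng = np.random.default_rng(cs.seed)
        y = y + rng.normal(0.0, cs.noise_sd, size=x.size)
    return x, y
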