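"""Hexagonal landscape samples and habitat-amount scenario filters.

The study region is tessellated into equal-area hexagons (default 1200 km²,
a standard local-landscape extent for amphibian work), each hexagon becomes
a *landscape sample* characterized by its habitat fraction, and a scenario
filter deletes all habitat in hexagons below a minimum fraction — emulating
progressive loss of the most habitat-poor landscapes.

Planar km coordinates only; raster cells are assigned to hexagons by the
cell-center rule (exact partition, no fractional cells), with boundary ties
going to the hexagon with the smaller id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .raster import GridRaster

__all__ = [
    "LandscapeCell",
    "HexGrid",
    "ScenarioSpec",
    "hexagon_side_km",
    "build_hex_grid",
    "habitat_fractions",
    "scenario_spec",
    "apply_scenario",
]


def hexagon_side_km(cell_area_km2: float) -> float:
    """Side length of a regular hexagon of the given area:
    area = (3√3/2)·s², so s = √(2·area/(3√3))."""
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    return math.sqrt(2.0 * cell_area_km2 / (3.0 * math.sqrt(3.0)))


@dataclass
class LandscapeCell:
    """One landscape sample: a hexagon, the raster cells whose centers fall
    in it, and its habitat fraction over in-region cells."""

    id: int
    polygon: Polygon
    covered_cells: set[tuple[int, int]] = field(default_factory=set)
    habitat_fraction: float = 0.0


@dataclass
class HexGrid:
    cells: list[LandscapeCell]
    region_polygon: Polygon
    cell_area_km2: float
    orientation: str = "pointy-top"
    fractions_computed: bool = False

    @property
    def side_km(self) -> float:
        return hexagon_side_km(self.cell_area_km2)

    def fractions(self) -> np.ndarray:
        return np.array([c.habitat_fraction for c in self.cells])

    def to_table(self) -> pd.DataFrame:
        """Delimited-text-friendly view: id, center coordinates, fraction."""
        recs = [
            {
                "id": c.id,
                "center_x_km": c.polygon.centroid.x,
                "center_y_km": c.polygon.centroid.y,
                "habitat_fraction": c.habitat_fraction,
            }
            for c in self.cells
        ]
        return pd.DataFrame(recs)

    def to_wkt(self) -> list[str]:
        return [c.polygon.wkt for c in self.cells]


@dataclass(frozen=True)
class ScenarioSpec:
    """A habitat-amount scenario: hexagons with habitat_fraction >=
    min_fraction are retained, all habitat elsewhere is removed."""

    min_fraction: float
    retained_ids: frozenset[int]


def _pointy_hexagon(cx: float, cy: float, s: float) -> Polygon:
    # vertices of a pointy-top hexagon (top/bottom vertices, flat left/right sides)
    angles = np.deg2rad([30, 90, 150, 210, 270, 330])
    xs = cx + s * np.cos(angles)
    ys = cy + s * np.sin(angles)
    return Polygon(zip(xs, ys))


def build_hex_grid(
    region: Polygon,
    cell_area_km2: float = 1200.0,
    orientation: str = "pointy-top",
) -> HexGrid:
    """Tile the region's bounding box with equal-area hexagons.

    The tiling is anchored at the bounding-box lower-left corner; only
    hexagons intersecting the region are kept, and hexagons straddling the
    region edge are kept whole (their fractions are later computed over
    in-region raster cells only).  Ids run row-major from the anchor, so the
    grid is deterministic for a given region, area and orientation.
    """
    if orientation != "pointy-top":
        raise ValueError("only pointy-top orientation is implemented")
    if region is None or region.is_empty or region.area == 0:
        raise ValueError("region polygon must be non-degenerate")
    s = hexagon_side_km(cell_area_km2)
    minx, miny, maxx, maxy = region.bounds
    dx = math.sqrt(3.0) * s          # horizontal center spacing
    dy = 1.5 * s                     # vertical center spacing
    n_rows = int(math.ceil((maxy - miny) / dy)) + 2
    n_cols = int(math.ceil((maxx - minx) / dx)) + 2
    cells: list[LandscapeCell] = []
    next_id = 1
    for r in range(n_rows):
        cy = miny + r * dy
        offset = 0.5 * dx if r % 2 else 0.0
        for c in range(n_cols):
            cx = minx + offset + (c - 0.5) * dx
            hexagon = _pointy_hexagon(cx, cy, s)
            if hexagon.intersects(region):
                cells.append(LandscapeCell(id=next_id, polygon=hexagon))
                next_id += 1
    return HexGrid(cells=cells, region_polygon=region, cell_area_km2=cell_area_km2, orientation=orientation)


def habitat_fractions(grid: HexGrid, habitat: GridRaster) -> HexGrid:
    """Assign raster cells to hexagons and compute habitat fractions.

    Every in-region raster cell (center inside the region polygon, boundary
    inclusive) is assigned to exactly one hexagon; a center on a shared
    hexagon boundary goes to the smaller id.  Each hexagon's fraction is
    (habitat cells) / (in-region covered cells); hexagons covering no
    in-region cell get fraction 0.  The grid is updated in place and
    returned.
    """
    x, y = habitat.cell_centers_km()
    xf, yf = x.ravel(), y.ravel()
    in_region = shapely.intersects_xy(grid.region_polygon, xf, yf)
    if not in_region.any():
        raise ValueError("raster and region polygon are disjoint")
    assignment = np.full(xf.size, -1, dtype=int)
    for cell in grid.cells:  # ascending id: boundary ties go to smaller id
        unassigned = in_region & (assignment < 0)
        if not unassigned.any():
            break
        idx = np.flatnonzero(unassigned)
        hit = shapely.intersects_xy(cell.polygon, xf[idx], yf[idx])
        assignment[idx[hit]] = cell.id

    hab = (np.asarray(habitat.values).ravel() == 1) & habitat.valid().ravel()
    n_cols = habitat.n_cols
    for cell in grid.cells:
        covered = np.flatnonzero(assignment == cell.id)
        cell.covered_cells = {(int(i // n_cols), int(i % n_cols)) for i in covered}
        n_cov = covered.size
        cell.habitat_fraction = float(hab[covered].sum() / n_cov) if n_cov else 0.0
    grid.fractions_computed = True
    grid._assignment = assignment.reshape(habitat.shape)  # cached for scenarios
    return grid


def scenario_spec(grid: HexGrid, min_fraction: float) -> ScenarioSpec:
    if not grid.fractions_computed:
        raise ValueError("compute habitat_fractions before building scenarios")
    retained = frozenset(c.id for c in grid.cells if c.habitat_fraction >= min_fraction)
    return ScenarioSpec(min_fraction=min_fraction, retained_ids=retained)


def apply_scenario(habitat: GridRaster, grid: HexGrid, min_fraction: float) -> GridRaster:
    """Remove all habitat inside hexagons whose fraction is below the
    scenario threshold ("at least" rule, >=); habitat in retained hexagons
    is untouched, so output habitat area is non-increasing in the
    threshold."""
    if not grid.fractions_computed or getattr(grid, "_assignment", None) is None:
        habitat_fractions(grid, habitat)
    assignment = grid._assignment
    if assignment.shape != habitat.shape:
        raise ValueError("hex-grid assignment was computed on a different raster geometry")
    spec = scenario_spec(grid, min_fraction)
    out = habitat.copy()
    removed_hex = ~np.isin(assignment, sorted(spec.retained_ids))
    out.values[removed_hex & (assignment > 0)] = 0
    return out
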