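"""Priority-area mapping: dIIC importance surfaces, critical-landscape
stacking across species, and protected-area coverage."""

from __future__ import annotations

import numpy as np

from .connectivity import ConnectivityResult
from .patches import PatchSet
from .raster import GridRaster
from .sampling import HexGrid

__all__ = [
    "importance_map",
    "critical_landscapes",
    "critical_landscape_raster",
    "stack_maps",
    "protected_overlap",
    "rasterize_polygon",
]


def importance_map(ps: PatchSet, cr: ConnectivityResult) -> GridRaster:
    """Spread each patch's dIIC% over its cells: every habitat cell carries
    the importance of the patch it belongs to, non-habitat cells are 0."""
    table = cr.nodes.set_index("id")["dIIC_pct"]
    patch_ids = {p.id for p in ps.patches}
    if set(table.index) != patch_ids:
        raise ValueError("connectivity result does not match the patch set's node ids")
    lut = np.zeros(max(patch_ids, default=0) + 1)
    for pid, val in table.items():
        lut[pid] = val
    values = lut[ps.labels]
    return GridRaster(values, ps.cell_size_km, ps.origin_km, kind="continuous")


def critical_landscapes(
    grid: HexGrid,
    rule: str = "min_fraction",
    min_fraction: float = 0.30,
) -> set[int]:
    """Landscape samples considered critical for a species.

    ``min_fraction`` rule (forest guild): hexagons with habitat fraction at
    least the threshold (default 30%, the operational habitat-amount
    threshold).  ``all_habitat`` rule (savanna guild, whose landscapes never
    reach the threshold): every hexagon with any habitat.
    """
    if not grid.fractions_computed:
        raise ValueError("compute habitat_fractions before selecting critical landscapes")
    if rule == "min_fraction":
        return {c.id for c in grid.cells if c.habitat_fraction >= min_fraction}
    if rule == "all_habitat":
        return {c.id for c in grid.cells if c.habitat_fraction > 0}
    raise ValueError("rule must be 'min_fraction' or 'all_habitat'")


def critical_landscape_raster(
    habitat: GridRaster,
    grid: HexGrid,
    critical_ids: set[int],
) -> GridRaster:
    """Binary raster of the habitat lying inside critical landscapes."""
    assignment = getattr(grid, "_assignment", None)
    if assignment is None or assignment.shape != habitat.shape:
        raise ValueError("hex-grid assignment missing or computed on a different raster")
    inside = np.isin(assignment, sorted(critical_ids))
    values = ((np.asarray(habitat.values) == 1) & inside).astype(int)
    return GridRaster(values, habitat.cell_size_km, habitat.origin_km, habitat.mask, kind="binary")


def stack_maps(maps: list[GridRaster]) -> GridRaster:
    """Cell-wise sum of binary critical-area rasters: the overlap (richness)
    map.  Cell values count the species for which the cell is critical."""
    if not maps:
        raise ValueError("at least one map is required")
    ref = maps[0]
    for m in maps[1:]:
        ref.require_same_geometry(m)
    total = np.sum([np.asarray(m.values, dtype=int) for m in maps], axis=0)
    return GridRaster(total, ref.cell_size_km, ref.origin_km, kind="categorical")


def protected_overlap(habitat: GridRaster, protected: GridRaster) -> float:
    """Percentage of habitat cells that fall inside the protected mask."""
    habitat.require_same_geometry(protected)
    hab = (np.asarray(habitat.values) == 1) & habitat.valid()
    n_hab = int(hab.sum())
    if n_hab == 0:
        raise ValueError("protected overlap undefined for empty habitat")
    prot = (np.asarray(protected.values) == 1) & hab
    return 100.0 * int(prot.sum()) / n_hab


def rasterize_polygon(polygon, template: GridRaster) -> GridRaster:
    """Binary mask of template cells whose centers lie in the polygon
    (boundary inclusive) — the cell-center rasterization used throughout."""
    import shapely

    x, y = template.cell_centers_km()
    inside = shapely.intersects_xy(polygon, x.ravel(), y.ravel())
    return GridRaster(
        inside.reshape(template.shape).astype(int),
        template.cell_size_km,
        template.origin_km,
        kind="binary",
    )
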