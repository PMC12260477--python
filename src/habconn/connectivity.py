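"""Integral Index of Connectivity and node-removal importance analysis.

The IIC of a patch graph is

    IIC = [ Σ_i Σ_j  a_i·a_j / (1 + nl_ij) ] / A_L²

summed over *ordered* pairs including i = j (nl_ii = 0, so each patch
contributes its squared area), where a_i is patch area, nl_ij the number of
links on the shortest topological path between patches i and j (a pair in
different components contributes zero, the limit of 1/(1+nl) as nl → ∞),
and A_L the total landscape area — habitat plus matrix.  IIC lies in
(0, 1]; it equals 1 only when the whole landscape is a single patch.

A patch's importance is the relative drop when it is removed,

    dIIC% = 100 · (IIC − IIC_without) / IIC,

which decomposes additively into dIICintra (the patch's own habitat),
dIICflux (its direct connections weighted by both areas) and dIICconnector
(its stepping-stone role on paths between *other* patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patches import PatchGraph, PatchSet, build_graph, label_patches
from .raster import GridRaster
from .sampling import HexGrid, apply_scenario
from .habitat import SpeciesProfile

__all__ = [
    "ConnectivityResult",
    "iic",
    "iic_numerator",
    "diic",
    "diic_components",
    "node_importance_table",
    "connectivity_result",
    "scenario_sweep",
    "dispersal_sensitivity",
]


@dataclass
class ConnectivityResult:
    """IIC plus the per-node dIIC decomposition for one (species, scenario,
    dispersal distance) combination.  ``nodes`` has columns id, area_km2,
    dIIC_pct, dIICintra_pct, dIICflux_pct, dIICconnector_pct."""

    iic: float
    iic_numerator: float
    nodes: pd.DataFrame
    dispersal_distance_km: float
    scenario_min_fraction: float | None = None
    species: str | None = None


def _pair_weights(g: PatchGraph) -> np.ndarray:
    """w_ij = 1/(1 + nl_ij); zero for unreachable pairs."""
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + g.nl)


def iic_numerator(g: PatchGraph) -> float:
    """Σ_i Σ_j a_i a_j / (1 + nl_ij) over ordered pairs, km⁴."""
    if g.n == 0:
        return 0.0
    a = g.node_areas
    return float(a @ _pair_weights(g) @ a)


def iic(g: PatchGraph) -> float:
    """Integral Index of Connectivity of the graph, in (0, 1] for any
    non-empty landscape."""
    return iic_numerator(g) / g.A_L**2


def diic(g: PatchGraph, node_id: int) -> float:
    """Percentage drop in IIC when the given patch is removed (link counts
    are recomputed among the survivors)."""
    total = iic_numerator(g)
    if total == 0:
        raise ValueError("dIIC is undefined when IIC = 0")
    reduced = iic_numerator(g.without_node(node_id))
    return 100.0 * (total - reduced) / total


def diic_components(g: PatchGraph, node_id: int) -> tuple[float, float, float]:
    """(dIICintra, dIICflux, dIICconnector) in percent; the three sum to
    dIIC.

    intra is the patch's own a_k² term; flux the 2·a_k·a_j/(1+nl_kj) terms
    linking it to every other patch; connector the loss on pairs of *other*
    patches whose shortest paths lengthen (or break) once the patch is gone
    — computed directly from the link counts before (nl) and after (nl')
    removal, never as a residual.
    """
    total = iic_numerator(g)
    if total == 0:
        raise ValueError("dIIC components are undefined when IIC = 0")
    ids = g.node_ids.tolist()
    if node_id not in ids:
        raise ValueError(f"unknown node id {node_id}")
    k = ids.index(node_id)
    a = g.node_areas
    w = _pair_weights(g)
    intra = 100.0 * a[k] ** 2 / total
    others = np.arange(g.n) != k
    flux = 100.0 * 2.0 * a[k] * float((a[others] * w[k, others]).sum()) / total
    sub = g.without_node(node_id)
    w_sub = _pair_weights(sub)
    a_o = a[others]
    delta = w[np.ix_(others, others)] - w_sub
    connector = 100.0 * float(a_o @ delta @ a_o) / total
    return intra, flux, connector


def node_importance_table(g: PatchGraph) -> pd.DataFrame:
    """dIIC and its decomposition for every node of the graph."""
    records = []
    for nid, area in zip(g.node_ids, g.node_areas):
        intra, flux, conn = diic_components(g, int(nid))
        records.append(
            {
                "id": int(nid),
                "area_km2": float(area),
                "dIIC_pct": intra + flux + conn,
                "dIICintra_pct": intra,
                "dIICflux_pct": flux,
                "dIICconnector_pct": conn,
            }
        )
    cols = ["id", "area_km2", "dIIC_pct", "dIICintra_pct", "dIICflux_pct", "dIICconnector_pct"]
    return pd.DataFrame(records, columns=cols)


def connectivity_result(
    g: PatchGraph,
    scenario_min_fraction: float | None = None,
    species: str | None = None,
) -> ConnectivityResult:
    return ConnectivityResult(
        iic=iic(g),
        iic_numerator=iic_numerator(g),
        nodes=node_importance_table(g),
        dispersal_distance_km=g.dispersal_distance_km,
        scenario_min_fraction=scenario_min_fraction,
        species=species,
    )


def scenario_sweep(
    habitat: GridRaster,
    grid: HexGrid,
    thresholds,
    profile: SpeciesProfile,
    A_L: float,
    metric: str = "edge",
    connectivity: int = 8,
) -> pd.DataFrame:
    """IIC under each habitat-amount scenario, with a common A_L.

    For every threshold: delete habitat in hexagons below it, re-extract
    patches (deletion can split patches), rebuild the graph at the species'
    dispersal distance, and evaluate IIC.  Because each scenario's habitat
    is a subset of the previous one and A_L is fixed, IIC is non-increasing
    in the threshold.  Returns columns (species, min_fraction, n_patches,
    habitat_area_km2, iic).
    """
    thresholds = list(thresholds)
    if any(t2 < t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        filtered = apply_scenario(habitat, grid, t)
        ps = label_patches(filtered, connectivity=connectivity)
        if len(ps) == 0:
            value, n_patches, area = 0.0, 0, 0.0
        else:
            g = build_graph(ps, profile.dispersal_distance_km, A_L, metric=metric)
            value, n_patches, area = iic(g), len(ps), ps.total_area_km2
        rows.append(
            {
                "species": profile.name,
                "min_fraction": t,
                "n_patches": n_patches,
                "habitat_area_km2": area,
                "iic": value,
            }
        )
    return pd.DataFrame(rows)


def dispersal_sensitivity(
    ps: PatchSet,
    distances,
    A_L: float,
    metric: str = "edge",
) -> pd.DataFrame:
    """IIC of one patch set at several dispersal distances.

    Raising the distance can only add edges, so IIC is non-decreasing along
    the sorted distances.  Returns columns (dispersal_km, n_edges, iic).
    """
    rows = []
    for d in distances:
        g = build_graph(ps, d, A_L, metric=metric)
        rows.append({"dispersal_km": d, "n_edges": len(g.edges), "iic": iic(g)})
    return pd.DataFrame(rows)
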