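"""Tumor-region segmentation from cell centroids.

Tumor cells are grouped by single-linkage at a link distance (~2 cell
diameters), each group is hulled, and hulls are classified by area:
micro-fragments (≤ 0.02 mm²) are discarded, satellites occupy
(0.02, 0.1] mm², nests exceed 0.1 mm² and are split into an edge band and a
core.  Lymphoid aggregates are single-linkage clusters of CD3+ cells outside
nests.  Coordinates are continuous µm in image convention (origin top-left,
y down); areas are mm² (1 mm² = 10⁶ µm²).

The hull is a concave hull computed by morphological closing at the link
distance, dilated by half a mean cell diameter so the boundary clears the
outermost cell bodies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry
from shapely.ops import polylabel

MM2_PER_UM2 = 1e-6

MICROFRAGMENT_MAX_MM2 = 0.02   # clusters at or below this area are discarded
SATELLITE_MAX_MM2 = 0.10       # satellites: (0.02, 0.1]; nests: > 0.1

DEFAULT_LINK_DISTANCE = 30.0   # µm, ~2 cell diameters
DEFAULT_EDGE_BAND = 50.0       # µm
DEFAULT_CELL_DIAMETER = 10.0   # µm
DEFAULT_EDGE_NOS2_CUTOFF = 0.05
DEFAULT_AGGREGATE_MIN_CELLS = 20

REGION_LABELS = ("lymphoid_aggregate", "nos2pos_edge", "nos2neg_edge",
                 "core", "satellite", "stroma")


@dataclass
class NestRegion:
    nest_id: int
    polygon: BaseGeometry
    area_mm2: float
    edge: BaseGeometry
    core: BaseGeometry
    nos2_status: str = "undetermined"   # "NOS2+", "NOS2-", "undetermined"
    nos2_fraction: float = float("nan")
    thin: bool = False


@dataclass
class RegionMap:
    nests: list[NestRegion] = field(default_factory=list)
    satellites: list[BaseGeometry] = field(default_factory=list)
    aggregates: list[BaseGeometry] = field(default_factory=list)
    log: dict = field(default_factory=dict)


def _single_linkage_components(pts: np.ndarray, link_distance: float
                               ) -> np.ndarray:
    """Component label per point under single linkage at link_distance."""
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_distance, output_type="ndarray")
    n = len(pts)
    data = np.ones(len(pairs))
    adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels


#: Interior holes below this area (mm²) are point-sampling artifacts, filled
#: before erosion so they cannot eat into the hull.
_HOLE_FILL_MAX_MM2 = 0.02


def _fill_small_holes(geom: BaseGeometry) -> BaseGeometry:
    from shapely.geometry import Polygon as _Poly
    parts = []
    for g in getattr(geom, "geoms", [geom]):
        rings = [r for r in g.interiors
                 if _Poly(r).area * MM2_PER_UM2 > _HOLE_FILL_MAX_MM2]
        parts.append(_Poly(g.exterior, rings))
    return shapely.unary_union(parts)


def _hull(pts: np.ndarray, link_distance: float,
          cell_diameter: float) -> BaseGeometry:
    """Concave hull by morphological closing at the link distance.

    Union of link_distance disks eroded back by the same radius: the
    boundary interpolates the outermost centroids, bridging gaps up to the
    linkage scale.  The result is dilated by half a cell diameter so the
    boundary clears the outermost cell bodies, and small interior holes
    (point-sampling artifacts) are filled.
    """
    # closing radius 1.5× the link distance: bridges every single-linkage
    # gap with margin while limiting convex-corner rounding loss
    r = 1.5 * link_distance
    buf = _fill_small_holes(
        shapely.unary_union(shapely.buffer(shapely.points(pts), r)))
    closed = buf.buffer(-r)
    if closed.is_empty:          # singleton / near-singleton cluster
        closed = shapely.multipoints(pts)
    return _fill_small_holes(closed.buffer(cell_diameter / 2.0))


def max_inscribed_width(poly: BaseGeometry) -> float:
    """Diameter of the largest inscribed circle (µm)."""
    geoms = getattr(poly, "geoms", [poly])
    best = 0.0
    for g in geoms:
        if g.is_empty:
            continue
        c = polylabel(g, tolerance=1.0)
        best = max(best, 2.0 * g.exterior.distance(c))
    return best


def build_tumor_clusters(cells: pd.DataFrame,
                         link_distance: float = DEFAULT_LINK_DISTANCE,
                         cell_diameter: float = DEFAULT_CELL_DIAMETER,
                         ) -> tuple[list[BaseGeometry], dict]:
    """Single-linkage tumor clusters hulled into polygons.

    Returns (polygons, log); clusters with area ≤ 0.02 mm² are discarded as
    micro-fragments and counted in the log.  With no tumor cells the result
    is empty and the log carries a warning.
    """
    log: dict = {"micro_fragments_discarded": 0, "warnings": []}
    mask = cells["is_tumor"].to_numpy() if "is_tumor" in cells \
        else (cells["phenotype"] == "Tumor").to_numpy()
    pts = cells.loc[mask, ["x_um", "y_um"]].to_numpy()
    if len(pts) == 0:
        log["warnings"].append("no tumor cells; empty region map")
        return [], log
    labels = _single_linkage_components(pts, link_distance)
    polys = []
    for lab in range(labels.max() + 1):
        hull = _hull(pts[labels == lab], link_distance, cell_diameter)
        if hull.area * MM2_PER_UM2 <= MICROFRAGMENT_MAX_MM2:
            log["micro_fragments_discarded"] += 1
        else:
            polys.append(hull)
    return polys, log


def classify_clusters(polys: Sequence[BaseGeometry],
                      cell_diameter: float = DEFAULT_CELL_DIAMETER
                      ) -> pd.DataFrame:
    """Classify hulls as satellite ((0.02, 0.1] mm²) or nest (> 0.1 mm²).

    The thinness attribute flags clusters whose maximum inscribed width is
    below 3 cell diameters (thin satellites are typical but not definitional,
    so it is recorded, never used as a gate).
    """
    rows = []
    for i, p in enumerate(polys):
        area = p.area * MM2_PER_UM2
        kind = "nest" if area > SATELLITE_MAX_MM2 else "satellite"
        rows.append({"cluster_id": i, "area_mm2": area, "kind": kind,
                     "thin": max_inscribed_width(p) < 3.0 * cell_diameter})
    return pd.DataFrame(rows, columns=["cluster_id", "area_mm2", "kind", "thin"])


def split_edge_core(nest: BaseGeometry, edge_band_width: float = DEFAULT_EDGE_BAND
                    ) -> tuple[BaseGeometry, BaseGeometry]:
    """Split a nest into (edge, core) by erosion with the edge band width.

    Erosion that consumes the whole polygon leaves core empty and the whole
    nest as edge; a zero band leaves edge empty.
    """
    if nest.is_empty or not nest.is_valid:
        raise ValueError("invalid nest geometry")
    core = nest.buffer(-edge_band_width)
    edge = nest.difference(core)
    return edge, core


def edge_nos2_status(cells: pd.DataFrame, edge: BaseGeometry,
                     cutoff: float = DEFAULT_EDGE_NOS2_CUTOFF
                     ) -> tuple[str, float]:
    """NOS2 status of a nest edge from its tumor cells.

    NOS2+ iff the fraction of edge tumor cells carrying any NOS2 grade is at
    least the cutoff.  With no edge tumor cells the status is undetermined.
    """
    tum = cells[cells["is_tumor"]]
    inside = shapely.contains_xy(edge, tum["x_um"].to_numpy(),
                                 tum["y_um"].to_numpy())
    n = int(inside.sum())
    if n == 0:
        return "undetermined", float("nan")
    if "nos2_grade" in tum:
        pos = (tum["nos2_grade"].to_numpy() != "")[inside]
    else:
        pos = tum["NOS2_call"].to_numpy()[inside]
    frac = float(pos.sum() / n)
    return ("NOS2+" if frac >= cutoff else "NOS2-"), frac


def detect_lymphoid_aggregates(cells: pd.DataFrame,
                               nest_polys: Sequence[BaseGeometry] = (),
                               min_cells: int = DEFAULT_AGGREGATE_MIN_CELLS,
                               link_distance: float = DEFAULT_LINK_DISTANCE,
                               cell_diameter: float = DEFAULT_CELL_DIAMETER,
                               ) -> list[BaseGeometry]:
    """Single-linkage clusters of ≥ min_cells CD3+ cells outside nests."""
    mask = cells["CD3_call"].to_numpy().copy()
    if mask.any() and len(nest_polys):
        union = shapely.unary_union(list(nest_polys))
        xy = cells.loc[mask, ["x_um", "y_um"]].to_numpy()
        outside = ~shapely.contains_xy(union, xy[:, 0], xy[:, 1])
        idx = np.flatnonzero(mask)
        mask[:] = False
        mask[idx[outside]] = True
    pts = cells.loc[mask, ["x_um", "y_um"]].to_numpy()
    if len(pts) == 0:
        return []
    labels = _single_linkage_components(pts, link_distance)
    out = []
    for lab in range(labels.max() + 1):
        member = pts[labels == lab]
        if len(member) >= min_cells:
            out.append(_hull(member, link_distance, cell_diameter))
    return out


def build_region_map(cells: pd.DataFrame,
                     link_distance: float = DEFAULT_LINK_DISTANCE,
                     edge_band_width: float = DEFAULT_EDGE_BAND,
                     cell_diameter: float = DEFAULT_CELL_DIAMETER,
                     edge_nos2_cutoff: float = DEFAULT_EDGE_NOS2_CUTOFF,
                     aggregate_min_cells: int = DEFAULT_AGGREGATE_MIN_CELLS,
                     ) -> RegionMap:
    """Full segmentation: clusters → satellites/nests → edge/core + NOS2
    status → lymphoid aggregates."""
    polys, log = build_tumor_clusters(cells, link_distance, cell_diameter)
    info = classify_clusters(polys, cell_diameter)
    rm = RegionMap(log=log)
    rm.log["params"] = {
        "link_distance_um": link_distance,
        "edge_band_width_um": edge_band_width,
        "edge_nos2_cutoff": edge_nos2_cutoff,
        "cell_diameter_um": cell_diameter,
    }
    nest_polys = []
    for _, row in info.iterrows():
        p = polys[int(row["cluster_id"])]
        if row["kind"] == "satellite":
            rm.satellites.append(p)
            continue
        edge, core = split_edge_core(p, edge_band_width)
        if core.is_empty:
            log["warnings"].append(
                f"nest {len(rm.nests)}: edge band consumed the whole nest")
        status, frac = edge_nos2_status(cells, edge, edge_nos2_cutoff)
        rm.nests.append(NestRegion(
            nest_id=len(rm.nests), polygon=p, area_mm2=float(row["area_mm2"]),
            edge=edge, core=core, nos2_status=status, nos2_fraction=frac,
            thin=bool(row["thin"])))
        nest_polys.append(p)
    rm.aggregates = detect_lymphoid_aggregates(
        cells, nest_polys, aggregate_min_cells, link_distance, cell_diameter)
    return rm


def assign_cell_regions(cells: pd.DataFrame, region_map: RegionMap
                        ) -> pd.DataFrame:
    """Label each cell with its tissue compartment.

    Precedence: lymphoid aggregate > edge > core > satellite > stroma; a cell
    outside every polygon is stroma.  Edge labels carry the nest's NOS2
    status (undetermined edges are labeled NOS2–, flagged in the map log).
    """
    out = cells.copy()
    x = out["x_um"].to_numpy()
    y = out["y_um"].to_numpy()
    region = np.full(len(out), "stroma", dtype=object)
    nid = np.full(len(out), -1)
    for p in region_map.satellites:
        region[shapely.contains_xy(p, x, y)] = "satellite"
    for nest in region_map.nests:
        if not nest.core.is_empty:
            m = shapely.contains_xy(nest.core, x, y)
            region[m] = "core"
            nid[m] = nest.nest_id
        label = "nos2pos_edge" if nest.nos2_status == "NOS2+" else "nos2neg_edge"
        if nest.nos2_status == "undetermined":
            region_map.log.setdefault("warnings", []).append(
                f"nest {nest.nest_id}: undetermined edge labeled nos2neg_edge")
        m = shapely.contains_xy(nest.edge, x, y)
        region[m] = label
        nid[m] = nest.nest_id
    for p in region_map.aggregates:
        region[shapely.contains_xy(p, x, y)] = "lymphoid_aggregate"
    out["region"] = region
    out["region_nest_id"] = nid
    return out


def regional_fraction_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Lineage composition per region label (fractions of region cells)."""
    from .phenotyping import percent_cells
    rows = {}
    for lab in REGION_LABELS:
        mask = (cells["region"] == lab).to_numpy()
        if mask.any():
            rows[lab] = percent_cells(cells, mask)
    return pd.DataFrame(rows).T
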