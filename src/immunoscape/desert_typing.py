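"""Immune-desert classification of tumor nests.

Each nest is scored on four criteria and routed through a decision table:

* CD8 infiltration index — fraction of nest-core cells that are CD8+ T cells
  (T_Eff or T_Ex); at or above the cutoff the nest is "infiltrated", not a
  desert.
* Edge NOS2 status — from the region map.
* Core COX2+ tumor fraction — "high" at/above the cutoff, else "low sporadic".
* Proximal stromal lymphoid fraction — CD3+ fraction of stromal-compartment
  cells within 500 µm of the nest boundary; < 1% is desert-cold.  The
  distance to the nearest lymphoid aggregate is reported alongside (type II
  deserts typically keep an aggregate < 0.5 mm away; recorded, not gated).

Decision table: infiltrated → NOS2+ edge & high COX2 → type I;
NOS2– edge & high COX2 → type II; NOS2– edge & low COX2 & proximal lymphoid
< 1% → type III; anything else is assigned the nearest type by criterion
mismatch count and flagged atypical.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import shapely

from .regions import RegionMap, NestRegion

DEFAULT_INFILTRATED_CUTOFF = 0.05
DEFAULT_HIGH_COX2_CUTOFF = 0.20
DEFAULT_PROXIMAL_RADIUS_UM = 500.0
DEFAULT_LYMPHOID_DESERT_CUTOFF = 0.01
AGGREGATE_PROXIMAL_UM = 500.0     # "< 0.5 mm" aggregate proximity


@dataclass
class DesertCall:
    """One nest's classification with the criterion values that produced it."""

    nest_id: int
    desert_type: str                  # "I" | "II" | "III" | "infiltrated"
    atypical: bool
    edge_nos2_status: str
    edge_nos2_fraction: float
    core_cox2_fraction: float
    cd8_infiltration_index: float
    proximal_lymphoid_fraction: float
    nearest_aggregate_um: float
    aggregate_proximal: bool


def cd8_infiltration_index(cells: pd.DataFrame, nest: NestRegion) -> float:
    """Fraction of nest-core cells that are T_Eff or T_Ex (NaN if core empty)."""
    if nest.core.is_empty:
        return float("nan")
    inside = shapely.contains_xy(nest.core, cells["x_um"].to_numpy(),
                                 cells["y_um"].to_numpy())
    n = int(inside.sum())
    if n == 0:
        return float("nan")
    ph = cells["phenotype"].to_numpy()[inside]
    return float(np.isin(ph, ("TEff", "TEx")).sum() / n)


def core_cox2_fraction(cells: pd.DataFrame, nest: NestRegion) -> float:
    """COX2+ fraction of tumor cells in the nest core (NaN if none)."""
    if nest.core.is_empty:
        return float("nan")
    tum = cells[cells["is_tumor"]]
    inside = shapely.contains_xy(nest.core, tum["x_um"].to_numpy(),
                                 tum["y_um"].to_numpy())
    n = int(inside.sum())
    if n == 0:
        return float("nan")
    return float(tum["tumor_cox2"].to_numpy()[inside].sum() / n)


def proximal_lymphoid_fraction(cells: pd.DataFrame, nest: NestRegion,
                               region_map: RegionMap,
                               radius_um: float = DEFAULT_PROXIMAL_RADIUS_UM,
                               ) -> tuple[float, float]:
    """(CD3+ fraction of stromal cells within radius of the nest boundary,
    distance to the nearest lymphoid aggregate in µm).

    Stromal compartment = cells labeled stroma or lymphoid_aggregate.  With
    no stromal cell in range the fraction is NaN (sentinel).  The aggregate
    distance is boundary-to-boundary; +inf with no aggregates.
    """
    stromal = cells["region"].isin(["stroma", "lymphoid_aggregate"]).to_numpy()
    sub = cells[stromal]
    d = shapely.distance(
        shapely.points(sub[["x_um", "y_um"]].to_numpy()), nest.polygon.exterior)
    near = d <= radius_um
    if near.sum() == 0:
        frac = float("nan")
    else:
        frac = float(sub["CD3_call"].to_numpy()[near].sum() / near.sum())
    if region_map.aggregates:
        agg_d = min(nest.polygon.distance(a) for a in region_map.aggregates)
    else:
        agg_d = float("inf")
    return frac, float(agg_d)


def classify_desert(nest: NestRegion, *,
                    cd8_index: float,
                    cox2_fraction: float,
                    lymphoid_fraction: float,
                    nearest_aggregate_um: float,
                    infiltrated_cutoff: float = DEFAULT_INFILTRATED_CUTOFF,
                    high_cox2_cutoff: float = DEFAULT_HIGH_COX2_CUTOFF,
                    lymphoid_cutoff: float = DEFAULT_LYMPHOID_DESERT_CUTOFF,
                    ) -> DesertCall:
    """Route one nest's criteria through the decision table."""
    nos2_pos = nest.nos2_status == "NOS2+"
    nos2_neg = nest.nos2_status == "NOS2-"
    cox2_high = np.isfinite(cox2_fraction) and cox2_fraction >= high_cox2_cutoff
    lymph_low = np.isfinite(lymphoid_fraction) and lymphoid_fraction < lymphoid_cutoff

    atypical = False
    if np.isfinite(cd8_index) and cd8_index >= infiltrated_cutoff:
        dtype = "infiltrated"
    elif nos2_pos and cox2_high:
        dtype = "I"
    elif nos2_neg and cox2_high:
        dtype = "II"
    elif nos2_neg and not cox2_high and lymph_low:
        dtype = "III"
    else:
        # nearest type by criterion mismatch count; undetermined edge
        # matches either status
        def mism(want_pos: bool, want_high: bool, want_low: bool | None) -> int:
            m = 0
            if nest.nos2_status != "undetermined":
                m += int(nos2_pos != want_pos)
            m += int(cox2_high != want_high)
            if want_low is not None and np.isfinite(lymphoid_fraction):
                m += int(lymph_low != want_low)
            return m

        scores = {"I": mism(True, True, None),
                  "II": mism(False, True, None),
                  "III": mism(False, False, True)}
        dtype = min(scores, key=lambda k: (scores[k], ("I", "II", "III").index(k)))
        atypical = True

    return DesertCall(
        nest_id=nest.nest_id, desert_type=dtype, atypical=atypical,
        edge_nos2_status=nest.nos2_status,
        edge_nos2_fraction=nest.nos2_fraction,
        core_cox2_fraction=cox2_fraction,
        cd8_infiltration_index=cd8_index,
        proximal_lymphoid_fraction=lymphoid_fraction,
        nearest_aggregate_um=nearest_aggregate_um,
        aggregate_proximal=nearest_aggregate_um < AGGREGATE_PROXIMAL_UM)


def classify_nests(cells: pd.DataFrame, region_map: RegionMap,
                   infiltrated_cutoff: float = DEFAULT_INFILTRATED_CUTOFF,
                   high_cox2_cutoff: float = DEFAULT_HIGH_COX2_CUTOFF,
                   proximal_radius_um: float = DEFAULT_PROXIMAL_RADIUS_UM,
                   lymphoid_cutoff: float = DEFAULT_LYMPHOID_DESERT_CUTOFF,
                   ) -> pd.DataFrame:
    """Classify every nest in a region map; cells must carry region labels."""
    if "region" not in cells.columns:
        raise ValueError("cells lack region labels; run assign_cell_regions")
    calls = []
    for nest in region_map.nests:
        cd8 = cd8_infiltration_index(cells, nest)
        cox2 = core_cox2_fraction(cells, nest)
        lymph, agg_d = proximal_lymphoid_fraction(
            cells, nest, region_map, proximal_radius_um)
        calls.append(asdict(classify_desert(
            nest, cd8_index=cd8, cox2_fraction=cox2,
            lymphoid_fraction=lymph, nearest_aggregate_um=agg_d,
            infiltrated_cutoff=infiltrated_cutoff,
            high_cox2_cutoff=high_cox2_cutoff,
            lymphoid_cutoff=lymphoid_cutoff)))
    cols = [f.name for f in DesertCall.__dataclass_fields__.values()] \
        if calls == [] else None
    return pd.DataFrame(calls, columns=cols)
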