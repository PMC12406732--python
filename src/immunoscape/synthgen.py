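"""Synthetic multiplex-IF landscape and cohort generator.

Emulates ER– breast-tumor tissue as a marked point pattern: stromal cells as a
homogeneous Poisson process, tumor cells uniform inside jittered polygonal
nests, lymphoid aggregates as truncated isotropic Gaussian clusters.  Each
nest is planted with one of four immune contexts:

* ``"I"``   — NOS2+ edge band, high COX2 core, stroma-restricted CD8 T cells
  with a proximal lymphoid aggregate (restricted-inflamed desert);
* ``"II"``  — NOS2– edge, high COX2 core, proximal aggregate, no infiltration;
* ``"III"`` — NOS2– edge, low sporadic COX2, T cells depleted within 500 µm
  of the nest (cold desert);
* ``"infiltrated"`` — CD8 T cells penetrate the nest with density
  ∝ exp(−d/λ) of depth d from the boundary (hot, alive-patient pattern).

Marker intensities follow a two-component Gaussian convention: negative mean
1.0, positive mean 5.0, shared noise SD (NOS2 uses grade-specific positive
means 4/6/8 for weak/medium/strong so grade gates are exercised).  Every cell
carries its ground-truth phenotype; every nest its ground-truth polygon and
desert type, so segmentation and classification can be scored exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.affinity import scale as shp_scale
from shapely.geometry import Point, Polygon

from . import DESERT_TYPES, MARKERS

MM2_PER_UM2 = 1e-6

NEGATIVE_MEAN = 1.0
POSITIVE_MEAN = 5.0
#: NOS2+ tumor cells draw intensity from a grade-specific mean.
NOS2_GRADE_MEANS = {"weak": 4.0, "medium": 6.0, "strong": 8.0}

#: Baseline stromal composition (fractions of stromal cells per phenotype).
#: CD3+ lineages total 15%, typical of inflamed breast-tumor stroma.
DEFAULT_STROMAL_COMPOSITION: Mapping[str, float] = {
    "TEff": 0.04,
    "TEx": 0.02,
    "CD8_TReg": 0.01,
    "CD4_T": 0.06,
    "CD4_TReg": 0.02,
    "Macrophage": 0.08,
    "Other": 0.77,
}

#: Lymphoid aggregates are CD4/CD8 T-cell dense with elevated CD8 T_Regs.
AGGREGATE_COMPOSITION: Mapping[str, float] = {
    "CD4_T": 0.40,
    "TEff": 0.30,
    "TEx": 0.10,
    "CD8_TReg": 0.10,
    "CD4_TReg": 0.10,
}

T_CELL_PHENOTYPES = ("TEff", "TEx", "CD8_TReg", "CD4_T", "CD4_TReg")

PHENOTYPE_MARKERS: Mapping[str, tuple[str, ...]] = {
    "TEff": ("CD3", "CD8"),
    "TEx": ("CD3", "CD8", "PD1"),
    "CD8_TReg": ("CD3", "CD8", "FOXP3"),
    "CD4_T": ("CD3", "CD4"),
    "CD4_TReg": ("CD3", "CD4", "FOXP3"),
    "Macrophage": ("CD68",),
    "Tumor": ("CKSOX10",),
    "Other": (),
}


@dataclass(frozen=True)
class NestSpec:
    """One planted tumor nest."""

    center: tuple[float, float]            # µm
    target_area_mm2: float = 0.15
    desert_type: str = "I"
    shape_jitter: float = 0.15             # radial vertex jitter, fraction of radius
    n_vertices: int = 14

    def __post_init__(self) -> None:
        if self.target_area_mm2 <= 0:
            raise ValueError("nest target_area_mm2 must be > 0")
        if self.desert_type not in DESERT_TYPES:
            raise ValueError(f"unknown desert type {self.desert_type!r}")


@dataclass(frozen=True)
class AggregateSpec:
    """One planted lymphoid aggregate (truncated Gaussian cluster)."""

    center: tuple[float, float]            # µm
    n_cells: int = 80
    radius_um: float = 60.0


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of one synthetic landscape (all lengths µm, areas mm²)."""

    field_width: float = 1600.0
    field_height: float = 1600.0
    cell_density_tumor: float = 4000.0     # cells per mm² inside nests
    cell_density_stroma: float = 1500.0    # cells per mm² outside nests
    nest_specs: tuple[NestSpec, ...] = (NestSpec(center=(800.0, 800.0)),)
    aggregate_specs: tuple[AggregateSpec, ...] = ()
    nos2_edge_fraction: float = 0.30       # NOS2+ fraction in type-I edge bands
    nos2_background_fraction: float = 0.01  # NOS2+ fraction elsewhere in tumors
    cox2_core_fraction: float = 0.50       # COX2+ core fraction, high-COX2 nests
    cox2_low_fraction: float = 0.05        # COX2+ fraction, low-COX2 nests
    cox2_edge_fraction: float = 0.15       # COX2+ edge fraction, high-COX2 nests
    cd8_infiltration_decay_length: float = 100.0   # λ of exp(−d/λ) infiltration
    cd8_infiltration_fraction: float = 0.25  # infiltrating CD8 per tumor cell
    desert_radius_um: float = 500.0        # T-cell depletion radius, type III
    desert_t_cell_keep: float = 0.02       # surviving T-cell fraction near type III
    edge_band_width: float = 50.0          # planted NOS2/COX2 edge-band depth
    marker_noise_sd: float = 0.5           # intensity units
    mean_cell_diameter: float = 10.0       # µm, used for hull buffers downstream
    stromal_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STROMAL_COMPOSITION))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be > 0")
        for name in ("cell_density_tumor", "cell_density_stroma",
                     "cd8_infiltration_decay_length", "edge_band_width",
                     "marker_noise_sd", "desert_radius_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("nos2_edge_fraction", "nos2_background_fraction",
                     "cox2_core_fraction", "cox2_low_fraction",
                     "cox2_edge_fraction", "cd8_infiltration_fraction",
                     "desert_t_cell_keep"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        comp_sum = sum(self.stromal_composition.values())
        if abs(comp_sum - 1.0) > 1e-9:
            raise ValueError(f"stromal_composition sums to {comp_sum}, not 1")


@dataclass
class GroundTruth:
    """Planted structure of one landscape (the test oracle)."""

    nest_polygons: list[Polygon]
    nest_desert_types: list[str]
    nest_target_areas_mm2: list[float]
    aggregate_polygons: list[Polygon]
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# geometry helpers

def _nest_polygon(spec: NestSpec, rng: np.random.Generator) -> Polygon:
    """Jittered regular polygon rescaled to exactly the target area."""
    n = spec.n_vertices
    area_um2 = spec.target_area_mm2 / MM2_PER_UM2
    # regular n-gon of circumradius r has area n r² sin(2π/n) / 2
    r = math.sqrt(2.0 * area_um2 / (n * math.sin(2.0 * math.pi / n)))
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    ang = ang + rng.uniform(0.0, 2.0 * math.pi / n)
    radii = r * rng.uniform(1.0 - spec.shape_jitter, 1.0 + spec.shape_jitter, n)
    xs = spec.center[0] + radii * np.cos(ang)
    ys = spec.center[1] + radii * np.sin(ang)
    poly = Polygon(np.column_stack([xs, ys])).buffer(0)
    f = math.sqrt(area_um2 / poly.area)
    return shp_scale(poly, xfact=f, yfact=f, origin="centroid")


def _uniform_in_polygon(poly: Polygon, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside poly."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(int((n - len(out)) * 2.5), 32)
        pts = np.column_stack([rng.uniform(minx, maxx, m),
                               rng.uniform(miny, maxy, m)])
        keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        out = np.vstack([out, pts[keep]])
    return out[:n]


def _poisson_points(width: float, height: float, density_per_mm2: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(density_per_mm2 * width * height * MM2_PER_UM2)
    return np.column_stack([rng.uniform(0.0, width, n),
                            rng.uniform(0.0, height, n)])


# --------------------------------------------------------------------------
# landscape simulation

def simulate_landscape(config: LandscapeConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one landscape; returns (cell table, ground truth).

    The cell table has one row per cell with columns ``cell_id``, ``x_um``,
    ``y_um``, per-marker ``<M>_int`` (intensity) and ``<M>_pos`` (true call),
    ``true_phenotype``, ``true_nos2_grade``, ``nest_id`` (−1 for stroma) and
    ``compartment_true`` (nest / stroma / aggregate).
    """
    rng = np.random.default_rng(config.seed)

    nest_polys = [_nest_polygon(s, rng) for s in config.nest_specs]
    truth = GroundTruth(
        nest_polygons=nest_polys,
        nest_desert_types=[s.desert_type for s in config.nest_specs],
        nest_target_areas_mm2=[s.target_area_mm2 for s in config.nest_specs],
        aggregate_polygons=[],
    )
    for i in range(len(nest_polys)):
        for j in range(i + 1, len(nest_polys)):
            if nest_polys[i].intersects(nest_polys[j]):
                msg = f"nest specs {i} and {j} overlap and merge into one component"
                truth.warnings.append(msg)
                warnings.warn(msg, stacklevel=2)

    xs: list[np.ndarray] = []
    phenos: list[np.ndarray] = []
    nest_ids: list[np.ndarray] = []
    compartments: list[np.ndarray] = []
    nos2_grade: list[np.ndarray] = []
    cox2_pos: list[np.ndarray] = []

    # --- tumor cells, nest by nest -------------------------------------
    for nid, (spec, poly) in enumerate(zip(config.nest_specs, nest_polys)):
        n_tumor = rng.poisson(config.cell_density_tumor * poly.area * MM2_PER_UM2)
        pts = _uniform_in_polygon(poly, n_tumor, rng)
        core = poly.buffer(-config.edge_band_width)
        in_core = (shapely.contains_xy(core, pts[:, 0], pts[:, 1])
                   if not core.is_empty else np.zeros(n_tumor, bool))

        # NOS2 planting: edge band of type I nests only (plus background)
        p_nos2 = np.where(
            ~in_core if spec.desert_type == "I" else np.zeros(n_tumor, bool),
            config.nos2_edge_fraction, config.nos2_background_fraction)
        nos2 = rng.random(n_tumor) < p_nos2
        grades = np.full(n_tumor, "", dtype=object)
        grades[nos2] = rng.choice(["weak", "medium", "strong"], size=int(nos2.sum()))

        # COX2 planting: high in cores of type I/II, low sporadic otherwise
        if spec.desert_type in ("I", "II"):
            p_cox2 = np.where(in_core, config.cox2_core_fraction,
                              config.cox2_edge_fraction)
        else:
            p_cox2 = np.full(n_tumor, config.cox2_low_fraction)
        cox2 = rng.random(n_tumor) < p_cox2

        xs.append(pts)
        phenos.append(np.full(n_tumor, "Tumor", dtype=object))
        nest_ids.append(np.full(n_tumor, nid))
        compartments.append(np.full(n_tumor, "nest", dtype=object))
        nos2_grade.append(grades)
        cox2_pos.append(cox2)

        # --- infiltrating CD8 T cells for "infiltrated" nests ----------
        if spec.desert_type == "infiltrated":
            lam = config.cd8_infiltration_decay_length
            n_inf = rng.poisson(config.cd8_infiltration_fraction * max(n_tumor, 1))
            acc = np.empty((0, 2))
            boundary = poly.exterior
            while len(acc) < n_inf:
                cand = _uniform_in_polygon(poly, max(4 * (n_inf - len(acc)), 32), rng)
                d = shapely.distance(shapely.points(cand), boundary)
                keep = rng.random(len(cand)) < np.exp(-d / lam)
                acc = np.vstack([acc, cand[keep]])
            acc = acc[:n_inf]
            inf_ph = rng.choice(["TEff", "TEx"], size=n_inf, p=[0.8, 0.2])
            xs.append(acc)
            phenos.append(inf_ph.astype(object))
            nest_ids.append(np.full(n_inf, nid))
            compartments.append(np.full(n_inf, "nest", dtype=object))
            nos2_grade.append(np.full(n_inf, "", dtype=object))
            cox2_pos.append(np.zeros(n_inf, bool))

    # --- stromal cells ---------------------------------------------------
    all_nests = shapely.unary_union(nest_polys) if nest_polys else None
    spts = _poisson_points(config.field_width, config.field_height,
                           config.cell_density_stroma, rng)
    if all_nests is not None and len(spts):
        spts = spts[~shapely.contains_xy(all_nests, spts[:, 0], spts[:, 1])]
    n_stroma = len(spts)
    comp_names = list(config.stromal_composition)
    comp_p = np.array([config.stromal_composition[k] for k in comp_names])
    sph = rng.choice(comp_names, size=n_stroma, p=comp_p).astype(object)

    # type III nests deplete T cells within desert_radius_um of their boundary
    for poly, dtype in zip(nest_polys, truth.nest_desert_types):
        if dtype != "III" or n_stroma == 0:
            continue
        d = shapely.distance(shapely.points(spts), poly.exterior)
        near = d <= config.desert_radius_um
        is_t = np.isin(sph, T_CELL_PHENOTYPES)
        kill = near & is_t & (rng.random(n_stroma) >= config.desert_t_cell_keep)
        sph[kill] = "Other"

    xs.append(spts)
    phenos.append(sph)
    nest_ids.append(np.full(n_stroma, -1))
    compartments.append(np.full(n_stroma, "stroma", dtype=object))
    nos2_grade.append(np.full(n_stroma, "", dtype=object))
    cox2_pos.append(np.zeros(n_stroma, bool))

    # --- lymphoid aggregates --------------------------------------------
    for agg in config.aggregate_specs:
        sd = agg.radius_um / 2.0
        acc = np.empty((0, 2))
        while len(acc) < agg.n_cells:
            cand = rng.normal(0.0, sd, size=(4 * agg.n_cells, 2))
            cand = cand[np.hypot(cand[:, 0], cand[:, 1]) <= agg.radius_um]
            acc = np.vstack([acc, cand])
        acc = acc[:agg.n_cells] + np.asarray(agg.center)
        acc[:, 0] = np.clip(acc[:, 0], 0.0, config.field_width)
        acc[:, 1] = np.clip(acc[:, 1], 0.0, config.field_height)
        aph = rng.choice(list(AGGREGATE_COMPOSITION),
                         size=agg.n_cells,
                         p=list(AGGREGATE_COMPOSITION.values())).astype(object)
        xs.append(acc)
        phenos.append(aph)
        nest_ids.append(np.full(agg.n_cells, -1))
        compartments.append(np.full(agg.n_cells, "aggregate", dtype=object))
        nos2_grade.append(np.full(agg.n_cells, "", dtype=object))
        cox2_pos.append(np.zeros(agg.n_cells, bool))
        truth.aggregate_polygons.append(
            Point(agg.center).buffer(agg.radius_um, quad_segs=16))

    pts = np.vstack(xs)
    if len(pts) == 0:
        raise ValueError("configuration yields zero cells")
    pheno = np.concatenate(phenos)
    grade = np.concatenate(nos2_grade)
    cox2 = np.concatenate(cox2_pos)

    cells = pd.DataFrame({
        "cell_id": np.arange(len(pts)),
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
        "true_phenotype": pheno,
        "true_nos2_grade": grade,
        "nest_id": np.concatenate(nest_ids),
        "compartment_true": np.concatenate(compartments),
    })

    _draw_markers(cells, cox2, config, rng)
    return cells, truth


def _draw_markers(cells: pd.DataFrame, tumor_cox2: np.ndarray,
                  config: LandscapeConfig, rng: np.random.Generator) -> None:
    """Add <M>_pos truth calls and <M>_int intensities in place."""
    n = len(cells)
    pheno = cells["true_phenotype"].to_numpy()
    grade = cells["true_nos2_grade"].to_numpy()
    is_tumor = pheno == "Tumor"
    is_mac = pheno == "Macrophage"

    pos = {m: np.zeros(n, bool) for m in MARKERS}
    for ph, marks in PHENOTYPE_MARKERS.items():
        sel = pheno == ph
        for m in marks:
            pos[m] |= sel

    pos["NOS2"] |= grade != ""
    pos["COX2"] |= tumor_cox2
    pos["COX2"] |= is_mac & (rng.random(n) < 0.20)
    pos["PDL1"] |= is_mac & (rng.random(n) < 0.40)
    pos["PDL1"] |= is_tumor & (rng.random(n) < 0.05)
    # functional markers: IFN-γ mostly on effector T cells, IDO1 on
    # macrophages, B7H4 on tumor cells (background rates elsewhere)
    pos["IFNG"] |= np.where(np.isin(pheno, ("TEff", "TEx")),
                            rng.random(n) < 0.30, rng.random(n) < 0.01)
    pos["IFNG"] |= (pheno == "CD4_T") & (rng.random(n) < 0.10)
    pos["IDO1"] |= np.where(is_mac, rng.random(n) < 0.20,
                            rng.random(n) < 0.005)
    pos["B7H4"] |= is_tumor & (rng.random(n) < 0.05)

    sd = config.marker_noise_sd
    for m in MARKERS:
        mean = np.where(pos[m], POSITIVE_MEAN, NEGATIVE_MEAN)
        if m == "NOS2":
            mean = np.full(n, NEGATIVE_MEAN)
            for g, gm in NOS2_GRADE_MEANS.items():
                mean[grade == g] = gm
            mean[pos["NOS2"] & (grade == "")] = POSITIVE_MEAN
        cells[f"{m}_int"] = mean + rng.normal(0.0, sd, n)
        cells[f"{m}_pos"] = pos[m]


# --------------------------------------------------------------------------
# ready-made layouts

def single_nest_config(desert_type: str = "I", *, seed: int = 0,
                       target_area_mm2: float = 0.15,
                       **overrides) -> LandscapeConfig:
    """One centered nest of the given immune context in a 1.6×1.6 mm field.

    Type I/II nests get one lymphoid aggregate ~250 µm off the nest boundary
    (proximal, <0.5 mm); type III and infiltrated nests get none.
    """
    w = overrides.pop("field_width", 1600.0)
    h = overrides.pop("field_height", 1600.0)
    center = (w / 2.0, h / 2.0)
    nest = NestSpec(center=center, target_area_mm2=target_area_mm2,
                    desert_type=desert_type)
    aggs: tuple[AggregateSpec, ...] = ()
    if desert_type in ("I", "II"):
        r_eff = math.sqrt(target_area_mm2 / MM2_PER_UM2 / math.pi)
        aggs = (AggregateSpec(center=(center[0] + r_eff + 250.0, center[1])),)
    return LandscapeConfig(field_width=w, field_height=h, nest_specs=(nest,),
                           aggregate_specs=aggs, seed=seed, **overrides)


def deceased_like_config(seed: int = 0, **overrides) -> LandscapeConfig:
    """Poor-outcome pattern: type I nest, NOS2+ edge, high COX2 core."""
    return single_nest_config("I", seed=seed, **overrides)


def alive_like_config(seed: int = 0, **overrides) -> LandscapeConfig:
    """Good-outcome pattern: CD8-infiltrated nest, low NOS2/COX2."""
    return single_nest_config("infiltrated", seed=seed, **overrides)


# --------------------------------------------------------------------------
# cohorts

def sample_seed(master_seed: int, index: int) -> int:
    """Deterministic per-sample seed in [0, 2³¹) derived from a master seed."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % 2**31)


def simulate_cohort(
    n_samples: int,
    group_assignments: Sequence[str],
    per_group_config: Mapping[str, LandscapeConfig],
    seed: int,
    *,
    survival_scale_months: Mapping[str, float] | None = None,
    followup_months: float = 60.0,
) -> tuple[list[dict], pd.DataFrame]:
    """Simulate a cohort of landscapes with survival metadata.

    Each sample's landscape is drawn from its group's config with a seed
    derived deterministically from ``seed``.  Deceased samples draw an event
    time from an exponential distribution truncated at follow-up (they died
    within the 5-year window by definition); alive samples are censored at
    follow-up.

    Returns (samples, metadata): samples is a list of dicts with keys
    ``sample_id``, ``group``, ``cells``, ``truth``; metadata has one row per
    sample (sample_id, group, time_months, event).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be ≥ 2")
    if len(group_assignments) != n_samples:
        raise ValueError("group_assignments length must equal n_samples")
    groups = sorted(set(group_assignments))
    if len(groups) < 2:
        raise ValueError("both groups must be represented")
    for g in groups:
        if g not in per_group_config:
            raise ValueError(f"missing config for group {g!r}")
    if survival_scale_months is None:
        # deceased: death within follow-up, Exp(24 mo) truncated; alive:
        # 5-year survivor, censored at follow-up (scale None)
        survival_scale_months = {
            g: (24.0 if g == "deceased" else None) for g in groups}

    meta_rng = np.random.default_rng([seed, 2**20 + 7])
    samples = []
    rows = []
    for i, g in enumerate(group_assignments):
        cfg = replace(per_group_config[g], seed=sample_seed(seed, i))
        cells, truth = simulate_landscape(cfg)
        sid = f"S{i:02d}"
        samples.append({"sample_id": sid, "group": g,
                        "cells": cells, "truth": truth})
        scale = survival_scale_months.get(g)
        if scale is None:
            t, event = followup_months, 0
        elif g == "deceased":
            t = float(meta_rng.exponential(scale))
            while t >= followup_months:
                t = float(meta_rng.exponential(scale))
            event = 1
        else:
            t_raw = float(meta_rng.exponential(scale))
            event = int(t_raw < followup_months)
            t = min(t_raw, followup_months)
        rows.append({"sample_id": sid, "group": g,
                     "time_months": t, "event": event})
    meta = pd.DataFrame(rows)
    return samples, meta


# --------------------------------------------------------------------------
# planted decay profile (for the gradient-estimator oracle)

def simulate_decay_profile(
    decay_length_um: float,
    *,
    n_focal: int = 200,
    amplitude: float = 20.0,
    bin_edges: Sequence[float] = tuple(range(0, 275, 25)),
    focal_phenotype: str = "TEff",
    target_phenotype: str = "Tumor",
    seed: int = 0,
) -> pd.DataFrame:
    """Plant target cells whose expected per-bin neighbor count decays as
    ``amplitude · exp(−midpoint/λ)`` around each focal cell.

    Focal cells sit on a widely spaced grid (no cross-talk between focal
    neighborhoods); per-bin counts are Poisson, radii uniform within the bin.
    Returns a minimal cell table (x_um, y_um, phenotype) for the estimator.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(bin_edges, float)
    mids = (edges[:-1] + edges[1:]) / 2.0
    lam_counts = amplitude * np.exp(-mids / decay_length_um)
    spacing = 4.0 * edges[-1]
    side = math.ceil(math.sqrt(n_focal))
    fx, fy = np.meshgrid(np.arange(side), np.arange(side))
    fpos = np.column_stack([fx.ravel(), fy.ravel()])[:n_focal] * spacing + spacing

    xs, ys = [fpos[:, 0]], [fpos[:, 1]]
    phen = [np.full(n_focal, focal_phenotype, dtype=object)]
    for (lo, hi, lam) in zip(edges[:-1], edges[1:], lam_counts):
        counts = rng.poisson(lam, n_focal)
        tot = int(counts.sum())
        r = rng.uniform(lo, hi, tot)
        r[r == lo] = np.nextafter(lo, hi)  # bins are (lo, hi]
        th = rng.uniform(0.0, 2.0 * math.pi, tot)
        anchor = np.repeat(fpos, counts, axis=0)
        xs.append(anchor[:, 0] + r * np.cos(th))
        ys.append(anchor[:, 1] + r * np.sin(th))
        phen.append(np.full(tot, target_phenotype, dtype=object))
    df = pd.DataFrame({
        "x_um": np.concatenate(xs),
        "y_um": np.concatenate(ys),
        "phenotype": np.concatenate(phen),
    })
    df.insert(0, "cell_id", np.arange(len(df)))
    return df
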