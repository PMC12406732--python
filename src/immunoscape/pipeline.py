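"""End-to-end pipeline: simulate → phenotype → regions → deserts →
neighborhoods → cohort statistics.

Every run writes a report directory whose files are a pure function of
(config, seed): per-sample phenotyped cell tables and region GeoJSONs,
cohort-level desert calls, neighborhood-cluster differential abundance,
the biomarker report and survival analysis, plus a run manifest carrying
the config hash, seed and software version.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import cohort_report, km_survival
from .desert_typing import classify_nests
from .io import (config_hash, region_map_to_geojson, write_cell_table,
                 write_geojson, write_json)
from .phenotyping import MarkerPanel, assign_phenotypes, call_positivity, \
    sample_metrics
from .regions import assign_cell_regions, build_region_map
from .spatial_stats import cluster_neighborhoods, \
    differential_cluster_abundance, neighborhood_features
from .synthgen import LandscapeConfig, alive_like_config, \
    deceased_like_config, simulate_cohort

DEFAULT_METRICS = (
    "frac_TEff", "frac_TEx", "frac_CD4_T", "frac_CD4_TReg", "frac_CD8_TReg",
    "frac_Macrophage", "nos2_tumor_frac", "nos2s_frac", "cox2_tumor_frac",
    "ifng_frac", "ratio_nos2_cd8", "ratio_nos2s_ifng",
    "ratio_teff_cd4treg", "ratio_teff_pdl1mac",
)

DEFAULT_CORRELATIONS = (
    ("nos2s_frac", "cox2_tumor_frac"),
    ("nos2s_frac", "ifng_frac"),
    ("cox2_tumor_frac", "frac_TEff"),
)


@dataclass
class PipelineConfig:
    """Validated parameters of one pipeline run."""

    n_samples: int = 20
    n_deceased: int = 10
    seed: int = 0
    deceased_config: LandscapeConfig | None = None   # default: type I nest
    alive_config: LandscapeConfig | None = None      # default: infiltrated
    link_distance_um: float = 30.0
    edge_band_width_um: float = 50.0
    edge_nos2_cutoff: float = 0.05
    infiltrated_cutoff: float = 0.05
    high_cox2_cutoff: float = 0.20
    lymphoid_desert_cutoff: float = 0.01
    neighborhood_radius_um: float = 50.0
    n_neighborhood_clusters: int = 8
    embed_umap: bool = False
    outlier_q_percent: float | None = None
    metrics: tuple[str, ...] = DEFAULT_METRICS
    correlation_pairs: tuple = DEFAULT_CORRELATIONS
    defaults_used: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.n_samples < 2 or not 0 < self.n_deceased < self.n_samples:
            raise ValueError("need ≥ 2 samples with both groups represented")
        for name in ("edge_nos2_cutoff", "infiltrated_cutoff",
                     "high_cox2_cutoff", "lymphoid_desert_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("link_distance_um", "edge_band_width_um",
                     "neighborhood_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_neighborhood_clusters < 1:
            raise ValueError("n_neighborhood_clusters must be ≥ 1")
        if self.deceased_config is None:
            self.deceased_config = deceased_like_config()
            self.defaults_used.append("deceased_config=type I landscape")
        if self.alive_config is None:
            self.alive_config = alive_like_config()
            self.defaults_used.append("alive_config=infiltrated landscape")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the report directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = {k: v for k, v in asdict(config).items()
                if k != "defaults_used"}
    chash = config_hash(cfg_dict)
    stamp = {"config_hash": chash, "seed": config.seed,
             "version": __version__}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    groups = ["deceased"] * config.n_deceased + \
        ["alive"] * (config.n_samples - config.n_deceased)
    samples, meta = _stage("simulate", simulate_cohort,
                           config.n_samples, groups,
                           {"deceased": config.deceased_config,
                            "alive": config.alive_config},
                           config.seed)
    meta.to_csv(out / "cohort_metadata.csv", index=False)

    panel = MarkerPanel()
    metric_rows = []
    desert_tables = []
    pooled_feats = []
    pooled_groups = []
    for s in samples:
        cells = _stage("phenotype", lambda c: assign_phenotypes(
            call_positivity(c, panel), panel), s["cells"])
        rm = _stage("regions", build_region_map, cells,
                    config.link_distance_um, config.edge_band_width_um)
        cells = assign_cell_regions(cells, rm)
        dcalls = _stage("deserts", classify_nests, cells, rm,
                        config.infiltrated_cutoff, config.high_cox2_cutoff)
        dcalls.insert(0, "sample_id", s["sample_id"])
        desert_tables.append(dcalls)
        write_cell_table(cells, out / "cells" / f"{s['sample_id']}.csv")
        write_geojson(region_map_to_geojson(rm),
                      out / "regions" / f"{s['sample_id']}.geojson")
        m = sample_metrics(cells)
        m["sample_id"] = s["sample_id"]
        metric_rows.append(m)
        feats = _stage("neighborhood", neighborhood_features, cells,
                       config.neighborhood_radius_um)
        pooled_feats.append(feats)
        pooled_groups.append(np.full(len(feats), s["group"], dtype=object))

    pd.concat(desert_tables, ignore_index=True).to_csv(
        out / "desert_calls.csv", index=False)
    metrics = pd.DataFrame(metric_rows).merge(meta, on="sample_id")
    metrics.to_csv(out / "cohort_metrics.csv", index=False)

    feats = pd.concat(pooled_feats, ignore_index=True).fillna(0).astype(int)
    clustering = _stage("neighborhood", cluster_neighborhoods, feats,
                        config.n_neighborhood_clusters, config.seed,
                        config.embed_umap)
    abundance = differential_cluster_abundance(
        clustering.labels, np.concatenate(pooled_groups))
    abundance.to_csv(out / "neighborhood_clusters.csv", index=False)

    report = _stage("cohort", cohort_report, metrics,
                    list(config.metrics), "group",
                    list(config.correlation_pairs),
                    config.outlier_q_percent)
    write_json({"stamp": stamp,
                "results": [asdict(r) for r in report["results"]],
                "correlations": report["correlations"],
                "n_tests": report["n_tests"],
                "multiplicity_correction": report["multiplicity_correction"]},
               out / "biomarker_report.json")

    surv = _stage("survival", km_survival, meta["time_months"],
                  meta["event"], meta["group"])
    write_json({"stamp": stamp,
                "gbw_p": surv.gbw_p, "gbw_statistic": surv.gbw_statistic,
                "hazard_ratio": surv.hazard_ratio, "hr_ci": list(surv.hr_ci),
                "groups": list(surv.groups), "n_events": surv.n_events},
               out / "survival.json")

    write_json({**stamp, "n_samples": config.n_samples,
                "defaults_used": config.defaults_used,
                "config": cfg_dict}, out / "run_info.json")
    return out
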