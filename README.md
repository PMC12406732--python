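# immunoscape

Spatial single-cell analysis of NOS2/COX2-driven immunosuppressive tumor
landscapes in ER-negative breast cancer.

Tumor-cell expression of inducible nitric oxide synthase (NOS2) and
cyclooxygenase-2 (COX2) predicts poor outcome in ER– breast cancer, and the
prediction is spatial: NOS2 concentrates at tumor edges, COX2 deeper in the
tumor core, and together they mark "immune deserts" — tumor nests that
CD8⁺ effector T cells (T_Eff, CD3⁺CD8⁺PD1⁻) cannot penetrate.  This
package implements, as a reusable and fully tested pipeline over
multiplex-immunofluorescence-style cell tables, the measurements behind
that picture:

* **Phenotype gating** — marker thresholds → a fixed-precedence lexicon
  (T_Eff, T_Ex, CD4/CD8 T_Regs, macrophage subsets, tumor cells with a
  weak/medium/strong NOS2 grade, "NOS2s" = strong stratum);
* **Region segmentation** — tumor nests (> 0.1 mm², split into a 50 µm
  edge band and core), satellites (0.02–0.1 mm²), stroma and lymphoid
  aggregates, from cell centroids alone;
* **Immune-desert typing** — each nest classified as type I (NOS2⁺ edge +
  high-COX2 core), type II (NOS2⁻ edge + high COX2), type III (NOS2⁻ edge,
  low sporadic COX2, < 1% proximal stromal lymphoid cells within 500 µm)
  or infiltrated;
* **Neighborhood statistics** — 25 µm distance-binned cross-phenotype
  neighbor counts (exact vs all-pairs), decay-length fits λ = −1/slope of
  log-profile, kernel density heatmaps, k-means clustering of per-cell
  neighborhood composition with %deceased/%alive differential abundance;
* **Cohort statistics** — ratio biomarkers (NOS2/CD8, NOS2s/IFN-γ,
  T_Eff/CD4 T_Reg, T_Eff/PDL1-macrophage), exact Mann-Whitney, within-group
  Pearson correlations, ROUT-style robust outlier exclusion, Kaplan-Meier
  curves with Gehan-Breslow-Wilcoxon tests and Mantel-Haenszel hazard
  ratios HR = exp((O₁−E₁)/V);
* **Synthetic cohorts** — a generator that plants nests, NOS2 edge bands,
  COX2 cores, lymphoid aggregates and all four immune contexts with ground
  truth, standing in for the (non-public) imaging cohort and making every
  recovery claim testable.

See `docs/methods.md` for the model, parameter defaults and limitations,
and `docs/schema.md` for file formats.

## Worked example

```python
from immunoscape import synthgen as sg
from immunoscape.phenotyping import call_positivity, assign_phenotypes
from immunoscape.regions import build_region_map, assign_cell_regions
from immunoscape.desert_typing import classify_nests

cells, truth = sg.simulate_landscape(sg.single_nest_config("I", seed=3))
cells = assign_phenotypes(call_positivity(cells))
rm = build_region_map(cells)
cells = assign_cell_regions(cells, rm)
calls = classify_nests(cells, rm)
print(calls[["desert_type", "edge_nos2_status", "core_cox2_fraction",
             "cd8_infiltration_index", "proximal_lymphoid_fraction"]])
```

prints

```
  desert_type edge_nos2_status  core_cox2_fraction  cd8_infiltration_index  proximal_lymphoid_fraction
0           I            NOS2+              0.5259                     0.0                      0.1773
```

— the planted type-I nest is recovered: its edge is NOS2⁺, 53% of core
tumor cells are COX2⁺ (planted 50%), no CD8 T cell reaches the core, and
18% of proximal stromal cells are CD3⁺ (T cells restricted to the stroma,
not absent — the signature of a *restricted-inflamed* desert, not a cold
type III one).

## The cohort analysis

The numbered scripts under `analysis/` run the full study on a 20-sample
synthetic cohort (10 deceased-pattern / 10 alive-pattern samples, ~86,000
cells), writing tables under `results/cohort/`:

```bash
python analysis/01_simulate_cohort.py      # cohort + ground truth + metadata
python analysis/02_phenotype_gating.py     # gating (accuracy ≥ 0.999 vs truth)
python analysis/03_segment_regions.py      # nests/edges/cores/aggregates
python analysis/04_type_immune_deserts.py  # desert taxonomy (100% recovery)
python analysis/05_neighborhood_analysis.py
python analysis/06_cohort_survival_stats.py
```

Representative output (seed 1): regional composition shows the planted
gradient — lymphoid aggregates are 86% T cells, the tumor core carries
< 8% leukocytes overall and 0% in deceased-pattern samples; neighborhood
enrichment gradients are significant in 43/60 sample-profiles with median
decay length 127 µm; and the cohort report flags the NOS2s fraction,
COX2 tumor fraction and NOS2/CD8 ratio (among others) at P ≈ 1e-05 with
GBW survival P = 2.0e-05 and HR (alive vs deceased) = 0.04.

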